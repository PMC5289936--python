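"""Symmetry elements and operations as orthogonal 3×3 matrices.

An *element* is a geometric locus (axis, plane, centre) with an order; an
*operation* is one concrete orthogonal matrix derived from an element (a
power of a rotation, a reflection, the inversion).  Axis vectors are unit
length and sign-canonicalised (first component of magnitude > 1e-8 made
positive) so detection output is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

PROPER = "proper_axis"
IMPROPER = "improper_axis"
MIRROR = "mirror_plane"
INVERSION = "inversion_centre"
IDENTITY = "identity"

_Z = np.array([0.0, 0.0, 1.0])


def canonical_axis(v: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Normalise and fix the sign of an axis direction."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < tol:
        raise ValueError("cannot canonicalise a null axis")
    v = v / n
    for c in v:
        if abs(c) > tol:
            if c < 0:
                v = -v
            break
    return v


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Proper rotation by ``angle`` about ``axis`` (Rodrigues form)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    c, s = math.cos(angle), math.sin(angle)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return c * np.eye(3) + s * k + (1 - c) * np.outer(a, a)


def reflection_matrix(normal: np.ndarray) -> np.ndarray:
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    return np.eye(3) - 2.0 * np.outer(n, n)


def improper_rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation by ``angle`` about ``axis`` followed by reflection through
    the perpendicular plane."""
    return reflection_matrix(axis) @ rotation_matrix(axis, angle)


@dataclass(frozen=True)
class SymmetryElement:
    """A symmetry element: kind, unit axis (plane normal for mirrors) and
    order (``0`` encodes the infinite order of linear molecules)."""

    kind: str
    axis: tuple[float, float, float]
    order: int = 1

    @staticmethod
    def make(kind: str, axis: np.ndarray | None = None, order: int = 1) -> "SymmetryElement":
        if kind in (INVERSION, IDENTITY):
            ax = (0.0, 0.0, 1.0)
        else:
            ax = tuple(float(x) for x in canonical_axis(axis))
        if kind in (PROPER, IMPROPER) and order == 1:
            raise ValueError("axis order must be >= 2 (or 0 for C_inf)")
        return SymmetryElement(kind, ax, order)

    @property
    def axis_vector(self) -> np.ndarray:
        return np.array(self.axis)

    def operations(self) -> list[np.ndarray]:
        """Concrete matrices generated by this element (identity omitted)."""
        a = self.axis_vector
        if self.kind == IDENTITY:
            return []
        if self.kind == INVERSION:
            return [-np.eye(3)]
        if self.kind == MIRROR:
            return [reflection_matrix(a)]
        if self.kind == PROPER:
            n = self.order if self.order else 2
            return [rotation_matrix(a, 2 * math.pi * k / n) for k in range(1, n)]
        # improper axis S_n: powers 1..n-1 (even powers are proper), plus
        # S_n^n = σ_h when n is odd
        n = self.order
        ops = []
        for k in range(1, n):
            if k % 2:
                ops.append(improper_rotation_matrix(a, 2 * math.pi * k / n))
            else:
                ops.append(rotation_matrix(a, 2 * math.pi * k / n))
        if n % 2:
            ops.append(reflection_matrix(a))
        return ops


@dataclass
class SymmetryOperation:
    """One orthogonal operation with its decomposition bookkeeping.

    ``order``/``power`` describe the rotation angle 2π·power/order (gcd
    reduced); mirrors have order 1, the inversion order 2.  ``orientation``
    tags mirrors and perpendicular C2 axes as horizontal/vertical/dihedral
    once the group frame is known.
    """

    matrix: np.ndarray
    kind: str
    axis: np.ndarray
    order: int
    power: int
    class_id: int = -1
    orientation: str = "none"
    name: str = ""

    @property
    def angle(self) -> float:
        if self.kind in (PROPER, IMPROPER):
            return 2 * math.pi * self.power / self.order
        return 0.0 if self.kind in (MIRROR, IDENTITY) else math.pi

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{self.name or self.kind} axis={np.round(self.axis, 3)}>"


def _proper_axis_angle(m: np.ndarray, tol: float = 1e-9):
    """Axis and angle in (0, 2π) of a proper rotation matrix (not identity)."""
    tr = float(np.trace(m))
    theta = math.acos(min(1.0, max(-1.0, (tr - 1.0) / 2.0)))
    if abs(theta - math.pi) < 1e-7:
        # eigenvector for +1 via the symmetric part
        b = 0.5 * (m + np.eye(3))
        col = b[:, int(np.argmax(np.diag(b)))]
        axis = canonical_axis(col)
        return axis, math.pi
    skew = np.array([m[2, 1] - m[1, 2], m[0, 2] - m[2, 0], m[1, 0] - m[0, 1]])
    axis = skew / (2.0 * math.sin(theta))
    cax = canonical_axis(axis)
    if np.dot(cax, axis) < 0:
        theta = 2 * math.pi - theta
    return cax, theta


def _angle_fraction(theta: float, max_order: int = 2000) -> tuple[int, int]:
    """Express θ/2π as a reduced fraction k/n."""
    frac = Fraction(theta / (2 * math.pi)).limit_denominator(max_order)
    k, n = frac.numerator % frac.denominator, frac.denominator
    if k == 0:
        return 0, 1
    return k, n


def operation_from_matrix(m: np.ndarray, tol: float = 1e-8) -> SymmetryOperation:
    """Classify an orthogonal matrix as E, Cn^k, Sn^k, σ or i."""
    m = np.asarray(m, dtype=float)
    if np.abs(m @ m.T - np.eye(3)).max() > 1e-8:
        raise ValueError("matrix is not orthogonal")
    det = float(np.linalg.det(m))
    if det > 0:
        if np.abs(m - np.eye(3)).max() < tol:
            return SymmetryOperation(m, IDENTITY, _Z.copy(), 1, 0, name="E")
        axis, theta = _proper_axis_angle(m)
        k, n = _angle_fraction(theta)
        name = f"C{n}" + (f"^{k}" if k != 1 else "")
        return SymmetryOperation(m, PROPER, axis, n, k, name=name)
    if np.abs(m + np.eye(3)).max() < tol:
        return SymmetryOperation(m, INVERSION, _Z.copy(), 2, 1, name="i")
    r = -m  # proper complement: m = i ∘ r
    if np.abs(r - np.eye(3)).max() < tol:  # cannot happen (det>0), safety
        raise ValueError("unreachable")
    axis, theta_r = _proper_axis_angle(r)
    theta = (theta_r + math.pi) % (2 * math.pi)
    if theta < tol or 2 * math.pi - theta < tol:
        return SymmetryOperation(m, MIRROR, axis, 1, 0, name="sigma")
    k, n = _angle_fraction(theta)
    name = f"S{n}" + (f"^{k}" if k != 1 else "")
    return SymmetryOperation(m, IMPROPER, axis, n, k, name=name)


def element_of_operation(op: SymmetryOperation) -> SymmetryElement:
    """The generating element of an operation (gcd-reduced order)."""
    if op.kind == IDENTITY:
        return SymmetryElement.make(IDENTITY)
    if op.kind == INVERSION:
        return SymmetryElement.make(INVERSION)
    if op.kind == MIRROR:
        return SymmetryElement.make(MIRROR, op.axis)
    return SymmetryElement.make(op.kind, op.axis, op.order)
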
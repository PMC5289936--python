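"""Geometry data model: XYZ parsing/writing, centre of mass, inertia.

Coordinates are cartesian Å throughout; masses are amu.  Every downstream
algorithm assumes centre-of-mass relative coordinates, so :func:`read_xyz`
recentres immediately after parsing (the original centre is kept on the
molecule for round-tripping).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .masses import mass_of


class XYZParseError(ValueError):
    """Raised when an XYZ block cannot be parsed; names the offending line."""


@dataclass
class Atom:
    """One nucleus: element symbol, mass (amu) and position (Å)."""

    element: str
    mass: float
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")
        if not (self.mass > 0):
            raise ValueError("mass must be positive")


@dataclass
class Molecule:
    """Ordered list of atoms plus a free-text comment."""

    atoms: list[Atom]
    comment: str = ""
    origin_shift: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a molecule needs at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def recentered(self) -> "Molecule":
        """Copy with the centre of mass shifted to the origin."""
        com = center_of_mass(self)
        atoms = [Atom(a.element, a.mass, a.position - com) for a in self.atoms]
        return Molecule(atoms, self.comment, self.origin_shift + com)

    def with_positions(self, positions: np.ndarray) -> "Molecule":
        positions = np.asarray(positions, dtype=float)
        atoms = [Atom(a.element, a.mass, p) for a, p in zip(self.atoms, positions)]
        return Molecule(atoms, self.comment, self.origin_shift.copy())


def center_of_mass(mol: Molecule) -> np.ndarray:
    m = mol.masses
    return m @ mol.positions / m.sum()


def read_xyz(text: str, recenter: bool = True) -> Molecule:
    """Parse a standard XYZ block.

    Line 1: atom count; line 2: comment; then ``symbol x y z [mass]``.
    The optional fifth column overrides the standard atomic weight (useful
    for isotope-broken symmetry).
    """
    lines = text.splitlines()
    if not lines:
        raise XYZParseError("empty input")
    try:
        count = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise XYZParseError(f"line 1: expected an atom count, got {lines[0]!r}")
    if count < 1:
        raise XYZParseError("line 1: atom count must be at least 1")
    comment = lines[1] if len(lines) > 1 else ""
    records = [ln for ln in lines[2:] if ln.strip()]
    if len(records) < count:
        raise XYZParseError(
            f"atom count {count} does not match {len(records)} record lines"
        )
    atoms = []
    for i, line in enumerate(records[:count]):
        parts = line.split()
        lineno = i + 3
        if len(parts) not in (4, 5):
            raise XYZParseError(f"line {lineno}: expected 'symbol x y z [mass]'")
        symbol = parts[0]
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"line {lineno}: non-numeric coordinate")
        if len(parts) == 5:
            try:
                mass = float(parts[4])
            except ValueError:
                raise XYZParseError(f"line {lineno}: non-numeric mass override")
        else:
            try:
                mass = mass_of(symbol)
            except KeyError:
                raise XYZParseError(f"line {lineno}: unknown element {symbol!r}")
        atoms.append(Atom(symbol, mass, np.array(xyz)))
    mol = Molecule(atoms, comment)
    return mol.recentered() if recenter else mol


def write_xyz(mol: Molecule, shift_back: bool = False) -> str:
    """Serialise to the XYZ dialect accepted by :func:`read_xyz`."""
    offset = mol.origin_shift if shift_back else np.zeros(3)
    out = [str(len(mol)), mol.comment]
    for a in mol.atoms:
        x, y, z = a.position + offset
        out.append(f"{a.element:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    return "\n".join(out) + "\n"


def inertial_tensor(positions: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Inertia tensor Σ mᵢ((aᵢ·aᵢ)E − aᵢ⊗aᵢ) about the origin (amu·Å²)."""
    positions = np.asarray(positions, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if len(positions) != len(masses):
        raise ValueError("positions and masses differ in length")
    r2 = np.einsum("ij,ij->i", positions, positions)
    return np.eye(3) * (masses * r2).sum() - np.einsum(
        "i,ij,ik->jk", masses, positions, positions
    )


def jacobi_eigen3(m: np.ndarray, tol: float = 1e-14, max_sweeps: int = 64):
    """Eigen-decomposition of a symmetric 3×3 matrix by cyclic Jacobi rotations.

    Returns (eigenvalues ascending, eigenvectors as columns of a right-handed
    orthonormal matrix).
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("expected a 3x3 matrix")
    scale = max(1.0, float(np.abs(m).max()))
    if np.abs(m - m.T).max() > 1e-10 * scale:
        raise ValueError("matrix is not symmetric")
    a = 0.5 * (m + m.T)
    v = np.eye(3)
    for _ in range(max_sweeps):
        off = math.sqrt(a[0, 1] ** 2 + a[0, 2] ** 2 + a[1, 2] ** 2)
        if off < tol * scale:
            break
        for p, q in ((0, 1), (0, 2), (1, 2)):
            if abs(a[p, q]) < 1e-300:
                continue
            theta = (a[q, q] - a[p, p]) / (2.0 * a[p, q])
            if abs(theta) > 1e150:  # asymptotic form avoids θ² overflow
                t = 0.5 / theta
            else:
                t = math.copysign(1.0, theta) / (
                    abs(theta) + math.sqrt(theta * theta + 1.0))
            c = 1.0 / math.sqrt(t * t + 1.0)
            s = t * c
            rot = np.eye(3)
            rot[p, p] = rot[q, q] = c
            rot[p, q] = s
            rot[q, p] = -s
            a = rot.T @ a @ rot
            v = v @ rot
    vals = np.diag(a).copy()
    order = np.argsort(vals, kind="stable")
    vals = vals[order]
    v = v[:, order]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return vals, v


@dataclass
class InertialFrame:
    """Principal moments (ascending) and right-handed principal axes.

    ``kind`` classifies the moment degeneracy pattern: ``linear``,
    ``spherical`` (all three equal), ``symmetric`` (exactly two equal, the
    distinct axis in ``unique_axis``) or ``asymmetric``.
    """

    moments: np.ndarray
    axes: np.ndarray  # columns are principal axes
    kind: str
    unique_axis: np.ndarray | None = None


def inertial_frame(
    positions: np.ndarray,
    masses: np.ndarray,
    deg_tol: float = 1e-4,
    lin_tol: float = 1e-6,
) -> InertialFrame:
    """Classify the moment-of-inertia pattern of a point set about the origin.

    ``deg_tol`` is the relative tolerance for calling two moments equal and
    ``lin_tol`` the relative tolerance for calling the set linear.
    """
    tensor = inertial_tensor(positions, masses)
    vals, vecs = jacobi_eigen3(tensor)
    top = max(vals[2], 1e-300)
    if vals[0] <= lin_tol * top:
        # the null-moment axis is the molecular line
        return InertialFrame(vals, vecs, "linear", vecs[:, 0])
    eq01 = abs(vals[1] - vals[0]) <= deg_tol * top
    eq12 = abs(vals[2] - vals[1]) <= deg_tol * top
    if eq01 and eq12:
        return InertialFrame(vals, vecs, "spherical", None)
    if eq01:
        return InertialFrame(vals, vecs, "symmetric", vecs[:, 2])
    if eq12:
        return InertialFrame(vals, vecs, "symmetric", vecs[:, 0])
    return InertialFrame(vals, vecs, "asymmetric", None)
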
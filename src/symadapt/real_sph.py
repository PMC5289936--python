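"""Real spherical harmonic transformation matrices and characters.

Convention: real solid harmonics in quantum-chemistry order m = −ℓ..+ℓ
with phase fixed so the ℓ = 1 shell transforms as (y, z, x).  Rotation
matrices are built by the iterative order-raising recursion (the U, V, W
recurrence seeded by the ℓ = 1 block, with the corrected sign in the
V term); improper operations factor through the inversion, which acts on
a shell as (−1)^ℓ.

Characters come in closed form — χ(Cₙ) = sin(θ|Y|/2)/sin(θ/2) and
χ(Sₙ) = cos(θ|Y|/2)/cos(θ/2) with |Y| = 2ℓ+1 — so irrep spans never need
the matrices; agreement of the two routes is itself a consistency check.
"""

from __future__ import annotations

import math

import numpy as np

from .operations import (
    IDENTITY,
    INVERSION,
    MIRROR,
    PROPER,
    SymmetryOperation,
    operation_from_matrix,
)

_YZX = (1, 2, 0)  # cartesian rows giving the (m=-1, 0, +1) = (y, z, x) order

_cache: dict[tuple, np.ndarray] = {}


def shell_size(l: int) -> int:
    return 2 * l + 1


def _seed_block(rotation: np.ndarray) -> np.ndarray:
    r1 = np.empty((3, 3))
    for a, pa in enumerate(_YZX):
        for b, pb in enumerate(_YZX):
            r1[a, b] = rotation[pa, pb]
    return r1


def _raise_order(l: int, r1: np.ndarray, prev: np.ndarray) -> np.ndarray:
    """Order-(ℓ) block from the order-(ℓ−1) block and the ℓ = 1 seed."""
    size = 2 * l + 1
    out = np.empty((size, size))

    def P(i: int, a: int, b: int) -> float:
        ri = r1[i + 1]
        if b == l:
            return (ri[2] * prev[a + l - 1, 2 * l - 2]
                    - ri[0] * prev[a + l - 1, 0])
        if b == -l:
            return (ri[2] * prev[a + l - 1, 0]
                    + ri[0] * prev[a + l - 1, 2 * l - 2])
        return ri[1] * prev[a + l - 1, b + l - 1]

    for m in range(-l, l + 1):
        d0 = 1.0 if m == 0 else 0.0
        am = abs(m)
        for n in range(-l, l + 1):
            denom = ((l + n) * (l - n)) if abs(n) < l else ((2 * l) * (2 * l - 1))
            u = math.sqrt((l + m) * (l - m) / denom)
            v = 0.5 * math.sqrt((1 + d0) * (l + am - 1) * (l + am) / denom) \
                * (1 - 2 * d0)
            w = -0.5 * math.sqrt((l - am - 1) * (l - am) / denom) * (1 - d0)
            val = 0.0
            if u != 0.0:
                val += u * P(0, m, n)
            if v != 0.0:
                if m == 0:
                    pv = P(1, 1, n) + P(-1, -1, n)
                elif m > 0:
                    d1 = 1.0 if m == 1 else 0.0
                    pv = (P(1, m - 1, n) * math.sqrt(1 + d1)
                          - P(-1, -m + 1, n) * (1 - d1))
                else:
                    d1 = 1.0 if m == -1 else 0.0
                    pv = (P(1, m + 1, n) * (1 - d1)
                          + P(-1, -m - 1, n) * math.sqrt(1 + d1))
                val += v * pv
            if w != 0.0:
                if m > 0:
                    pw = P(1, m + 1, n) + P(-1, -m - 1, n)
                else:
                    pw = P(1, m - 1, n) - P(-1, -m + 1, n)
                val += w * pw
            out[m + l, n + l] = val
    return out


def rotation_matrix_real_sh(l: int, rotation: np.ndarray) -> np.ndarray:
    """(2ℓ+1)×(2ℓ+1) orthogonal matrix representing a proper rotation on
    the real spherical harmonics of order ℓ."""
    rotation = np.asarray(rotation, dtype=float)
    if abs(np.linalg.det(rotation) - 1.0) > 1e-10:
        raise ValueError("rotation_matrix_real_sh requires a proper rotation")
    key = ("rot", l, rotation.round(14).tobytes())
    hit = _cache.get(key)
    if hit is not None:
        return hit.copy()
    if l == 0:
        out = np.ones((1, 1))
    elif l == 1:
        out = _seed_block(rotation)
    else:
        r1 = _seed_block(rotation)
        block = r1
        for ll in range(2, l + 1):
            block = _raise_order(ll, r1, block)
        out = block
    _cache[key] = out
    return out.copy()


def operation_matrix(l: int, op) -> np.ndarray:
    """Representation matrix of any orthogonal operation on the ℓ shell:
    proper part by the recursion, inversion as the parity factor (−1)^ℓ."""
    m = op.matrix if isinstance(op, SymmetryOperation) else np.asarray(op, float)
    det = float(np.linalg.det(m))
    if det > 0:
        return rotation_matrix_real_sh(l, m)
    return ((-1.0) ** l) * rotation_matrix_real_sh(l, -m)


def sh_character(l: int, op) -> float:
    """Closed-form character of an operation on the full ℓ shell."""
    if not isinstance(op, SymmetryOperation):
        op = operation_from_matrix(np.asarray(op, float))
    size = 2 * l + 1
    if op.kind == IDENTITY:
        return float(size)
    if op.kind == INVERSION:
        return float((-1) ** l * size)
    if op.kind == MIRROR:
        return 1.0
    tr = float(np.trace(op.matrix))
    if op.kind == PROPER:
        theta = math.acos(min(1.0, max(-1.0, (tr - 1.0) / 2.0)))
        s = math.sin(theta / 2.0)
        if abs(s) < 1e-12:
            return float(size)
        return math.sin(theta * size / 2.0) / s
    theta = math.acos(min(1.0, max(-1.0, (tr + 1.0) / 2.0)))
    c = math.cos(theta / 2.0)
    if abs(c) < 1e-12:  # θ = π: the operation is the inversion
        return float((-1) ** l * size)
    return math.cos(theta * size / 2.0) / c


def irrep_span(l: int, group, table) -> np.ndarray:
    """Multiplicities m_Γ of each irrep of ``table`` in the ℓ shell,
    computed from characters alone (no matrices)."""
    rep_chars = np.array([sh_character(l, group.operations[r])
                          for r in table.class_reps])
    return table.reduce(rep_chars)
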
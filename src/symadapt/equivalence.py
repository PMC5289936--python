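"""Partition atoms into sets of symmetry-equivalent nuclei.

Equivalent nuclei are found *before* any symmetry element is known, by
clustering per-atom quantities that are invariant under every isometry
permuting equal-mass atoms:

* mean and euclidean length of the atom's row of the reduced-mass-weighted
  distance matrix ``D_ij = μ_ij |a_i − a_j|`` (μ the pair reduced mass),
* the norm of the unit-sphere projection  ``s_i = Σ_j μ_ij d_ij/|d_ij|``,
* the norm of the plane projection ``p_i = Σ_j μ_ij (a_j − (a_i·a_j/|a_i|²) a_i)``.

Element symbol and mass are hard keys: clustering only ever runs inside a
(element, mass) block.  The partition is then refined recursively, each
subset re-analysed as its own point set (about the unchanged molecular
centre of mass) until a fixed point is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry_io import Molecule

#: relative clustering tolerance; see cluster_invariants
DEFAULT_REL_TOL = 1e-3


@dataclass(frozen=True)
class InvariantVector:
    """Per-atom symmetry-invariant summary (row mean/norm in amu·Å,
    sphere norm in amu, plane norm in amu·Å).

    ``sphere_bound``/``plane_bound`` are the triangle-inequality maxima of
    the two projection norms (Σμ and Σμ|a|).  The projections cancel to
    zero in highly symmetric arrangements, so their *relative* values are
    noise-dominated there; the bounds give the clustering a meaningful
    scale floor.
    """

    row_mean: float
    row_norm: float
    sphere_norm: float
    plane_norm: float
    at_origin: bool = False  # plane projection dropped for this atom
    sphere_bound: float = 0.0
    plane_bound: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.row_mean, self.row_norm, self.sphere_norm, self.plane_norm]
        )


@dataclass(frozen=True)
class EquivalenceSet:
    """Indices of one orbit of symmetry-equivalent nuclei."""

    indices: tuple[int, ...]
    element: str
    mass: float

    def __len__(self) -> int:
        return len(self.indices)


def weighted_distance_matrix(mol: Molecule) -> np.ndarray:
    """Reduced-mass weighted distance matrix ``D_ij = μ_ij |a_i − a_j|``."""
    pos = mol.positions
    m = mol.masses
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    mu = np.outer(m, m) / (m[:, None] + m[None, :])
    d = mu * dist
    np.fill_diagonal(d, 0.0)
    return d


def invariant_vectors(
    mol: Molecule, indices: list[int] | None = None, origin_tol: float = 1e-8
) -> list[InvariantVector]:
    """Invariant vectors for the atoms in ``indices`` (default: all),
    computed only from the atoms inside that subset.

    For an atom sitting on the centre of mass the plane projection is
    undefined; its projection term is dropped and the atom flagged.
    """
    if indices is None:
        indices = list(range(len(mol)))
    pos = mol.positions[indices]
    m = mol.masses[indices]
    n = len(indices)
    if n == 1:
        return [InvariantVector(0.0, 0.0, 0.0, 0.0, bool(np.linalg.norm(pos[0]) < origin_tol))]
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    mu = np.outer(m, m) / (m[:, None] + m[None, :])
    d = mu * dist
    np.fill_diagonal(d, 0.0)
    out = []
    eye = ~np.eye(n, dtype=bool)
    for i in range(n):
        row = d[i][eye[i]]
        row_mean = float(row.mean())
        row_norm = float(np.linalg.norm(row))
        safe = dist[i].copy()
        safe[i] = 1.0
        s = (mu[i][:, None] * diff[i] / safe[:, None])[eye[i]].sum(axis=0)
        ai = pos[i]
        ai2 = float(ai @ ai)
        at_origin = ai2 < origin_tol**2
        if at_origin:
            proj = pos
        else:
            proj = pos - np.outer(pos @ ai / ai2, ai)
        p = (mu[i][:, None] * proj)[eye[i]].sum(axis=0)
        mu_row = mu[i][eye[i]]
        out.append(
            InvariantVector(
                row_mean,
                row_norm,
                float(np.linalg.norm(s)),
                float(np.linalg.norm(p)),
                at_origin,
                sphere_bound=float(mu_row.sum()),
                plane_bound=float(
                    (mu_row * np.linalg.norm(proj, axis=1)[eye[i]]).sum()),
            )
        )
    return out


def invariant_vector(mol: Molecule, i: int) -> InvariantVector:
    """Invariant vector of atom ``i`` in the context of the whole molecule."""
    return invariant_vectors(mol)[i]


def cluster_invariants(
    vectors: list[InvariantVector],
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = 1e-10,
) -> list[list[int]]:
    """Single-linkage clustering of invariant vectors.

    Two atoms are linked when each of the four components agrees within
    ``rel_tol`` relative to that component's scale — the largest magnitude
    in the batch, floored for the projection norms at a fraction of their
    triangle-inequality bound so that projections which cancel by symmetry
    (and are therefore noise-dominated) do not splinter an orbit.
    Clusters are returned ordered by their lowest member index.
    """
    n = len(vectors)
    if n == 0:
        return []
    arr = np.stack([v.as_array() for v in vectors])
    scale = np.maximum(np.abs(arr).max(axis=0), abs_tol)
    scale[2] = max(scale[2], 0.2 * max(v.sphere_bound for v in vectors))
    scale[3] = max(scale[3], 0.2 * max(v.plane_bound for v in vectors))
    tol = rel_tol * scale + abs_tol
    # union-find single linkage
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if np.all(np.abs(arr[i] - arr[j]) <= tol):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [groups[k] for k in sorted(groups)]


def _initial_partition(mol: Molecule, rel_tol: float) -> list[list[int]]:
    hard: dict[tuple[str, float], list[int]] = {}
    for i, a in enumerate(mol.atoms):
        hard.setdefault((a.element, round(a.mass, 8)), []).append(i)
    parts: list[list[int]] = []
    for key in sorted(hard):
        idx = hard[key]
        vecs = invariant_vectors(mol, idx)
        for local in cluster_invariants(vecs, rel_tol):
            parts.append([idx[k] for k in local])
    parts.sort(key=min)
    return parts


def refine_partition(
    mol: Molecule, partition: list[list[int]], rel_tol: float = DEFAULT_REL_TOL,
    max_rounds: int = 20,
) -> list[list[int]]:
    """Re-cluster each subset in isolation until a fixed point.

    Refinement only ever splits subsets, so it terminates; invariants inside
    a subset are computed from the subset's own atoms about the molecular
    centre.
    """
    current = [sorted(p) for p in partition]
    for _ in range(max_rounds):
        new: list[list[int]] = []
        changed = False
        for part in current:
            if len(part) <= 1:
                new.append(part)
                continue
            vecs = invariant_vectors(mol, part)
            pieces = cluster_invariants(vecs, rel_tol)
            if len(pieces) > 1:
                changed = True
            for local in pieces:
                new.append([part[k] for k in local])
        new.sort(key=min)
        current = new
        if not changed:
            break
    return current


def equivalence_sets(
    mol: Molecule, rel_tol: float = DEFAULT_REL_TOL
) -> list[EquivalenceSet]:
    """Full pipeline: hard-key grouping, invariant clustering, refinement."""
    parts = refine_partition(mol, _initial_partition(mol, rel_tol), rel_tol)
    out = []
    for part in parts:
        a = mol.atoms[part[0]]
        out.append(EquivalenceSet(tuple(part), a.element, a.mass))
    return out
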
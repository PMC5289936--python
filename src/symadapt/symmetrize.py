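"""Symmetrisation of near-symmetric geometries and wavefunctions.

Geometry: atomic displacements stacked as one vector in the
(atom ⊗ cartesian) space are projected onto the totally symmetric
subspace of D^S(R) ⊗ R; the discarded component's mass-weighted norm is
the error indicator (the analogue of a vibrational-mode analysis, hence
the √mass weighting).  Orbitals: each orbital is projected onto the
irrep span where it has its largest squared-norm component; degenerate
multiplets get a common averaged copy-vector and are rotated onto the
symmetry-adapted partner functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry_io import Molecule
from .point_group import PointGroup, permutation_representation
from .salc import SALCSpace


class SymmetryBrokenError(ValueError):
    """An orbital has no majority irrep component."""


class AtomCollapseError(ValueError):
    """The totally symmetric projection merged distinct atoms."""


@dataclass
class OrbitalSet:
    """Orbital coefficient rows over a declared BasisSpec ordering."""

    coefficients: np.ndarray
    occupations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_2d(
            np.asarray(self.coefficients, dtype=float))
        norms = np.linalg.norm(self.coefficients, axis=1)
        if np.abs(norms - 1.0).max() > 1e-8:
            warnings.warn("orbital rows renormalised", stacklevel=2)
            self.coefficients = self.coefficients / norms[:, None]

    def __len__(self) -> int:
        return len(self.coefficients)


@dataclass
class SymmetryReport:
    irrep_names: list[str]
    fractions: np.ndarray          # (n_orbitals, n_irreps)
    assigned: list[str]
    geometry_error: float | None = None      # mass-weighted norm, Å·amu^1/2
    geometry_error_rms: float | None = None  # per-coordinate RMS, Å


@dataclass
class GeometryResult:
    molecule: Molecule
    error: float       # mass-weighted residual norm (Å·amu^1/2)
    error_rms: float   # √(Σm|δ|²/(3Σm)), Å


def symmetrize_molecule(mol: Molecule, group: PointGroup,
                        tol: float = 0.05,
                        collapse_tol: float = 1e-3) -> GeometryResult:
    """Project the geometry onto the totally symmetric space of the group.

    The result is exactly invariant under every operation (to floating
    point); the discarded component is returned as the error indicator,
    both as a mass-weighted norm and as a per-coordinate RMS.
    """
    mol = mol.recentered()
    pos = mol.positions
    n = len(mol)
    perms = permutation_representation(group, pos, tol=tol)
    x = pos.reshape(-1)
    acc = np.zeros_like(x)
    for perm, op in zip(perms, group.operations):
        moved = pos @ op.matrix.T          # R applied to every atom
        target = np.empty_like(pos)
        target[perm.images] = moved        # atom i contributes at its image
        acc += target.reshape(-1)
    xs = acc / len(group)
    new_pos = xs.reshape(n, 3)
    d2 = np.linalg.norm(new_pos[:, None, :] - new_pos[None, :, :], axis=-1)
    np.fill_diagonal(d2, np.inf)
    if d2.min() < collapse_tol:
        raise AtomCollapseError(
            "projection collapsed two atoms; the group is inconsistent "
            "with the geometry")
    delta = (pos - new_pos)
    m = mol.masses
    err = float(np.sqrt((m * (delta**2).sum(axis=1)).sum()))
    rms = float(np.sqrt((m * (delta**2).sum(axis=1)).sum() / (3.0 * m.sum())))
    return GeometryResult(mol.with_positions(new_pos), err, rms)


# ---------------------------------------------------------------------------
# orbitals


def _group_salcs(salcs: list[SALCSpace]):
    """Organise SALC rows: per irrep name, an (n_copies, dim, n_basis)
    stack with copies enumerated across (set, ℓ) blocks."""
    by_irrep: dict[str, dict[int, list[np.ndarray]]] = {}
    order: list[str] = []
    for sp in salcs:
        if sp.irrep not in by_irrep:
            by_irrep[sp.irrep] = {}
            order.append(sp.irrep)
        by_irrep[sp.irrep].setdefault(sp.component, []).append(
            sp.coefficients)
    stacks = {}
    for name in order:
        comps = by_irrep[name]
        dim = max(comps)
        per_comp = [np.vstack(comps[c + 1]) for c in range(dim)]
        stacks[name] = np.stack(per_comp, axis=1)  # (copies, dim, n_basis)
    return order, stacks


def analyze_orbital_symmetry(orbs: OrbitalSet,
                             salcs: list[SALCSpace]) -> SymmetryReport:
    """Squared-norm fraction of every orbital in each irrep's SALC span."""
    names, stacks = _group_salcs(salcs)
    n_basis = salcs[0].coefficients.shape[1]
    if orbs.coefficients.shape[1] != n_basis:
        raise ValueError("orbital basis does not match the SALC basis")
    fr = np.empty((len(orbs), len(names)))
    for j, name in enumerate(names):
        flat = stacks[name].reshape(-1, n_basis)
        fr[:, j] = ((orbs.coefficients @ flat.T) ** 2).sum(axis=1)
    assigned = [names[int(i)] for i in fr.argmax(axis=1)]
    return SymmetryReport(names, fr, assigned)


def symmetrize_wavefunction(
    orbs: OrbitalSet,
    salcs: list[SALCSpace],
    min_component: float = 0.5,
) -> tuple[OrbitalSet, SymmetryReport]:
    """Project each orbital onto its majority irrep and align degenerate
    multiplets with the symmetry-adapted partner functions.

    Orbitals assigned to a degenerate irrep are taken in input order as
    consecutive dim(Γ)-tuples; each tuple's copy-vectors are averaged
    (dominant eigenvector of the accumulated outer products) and the
    tuple is replaced by that common combination over the dim(Γ)
    components, so partner sets transform exactly into one another.
    Raises when an orbital's largest component is ≤ ``min_component`` —
    there is a limit to how symmetry broken the input can be.
    """
    report = analyze_orbital_symmetry(orbs, salcs)
    top = report.fractions.max(axis=1)
    if top.min() <= min_component:
        bad = int(top.argmin())
        raise SymmetryBrokenError(
            f"orbital {bad} has largest irrep component {top[bad]:.3f} <= "
            f"{min_component}; input too symmetry broken")
    names, stacks = _group_salcs(salcs)
    out = np.array(orbs.coefficients, copy=True)
    by_irrep: dict[str, list[int]] = {}
    for i, name in enumerate(report.assigned):
        by_irrep.setdefault(name, []).append(i)
    for name, members in by_irrep.items():
        stack = stacks[name]              # (copies, dim, n_basis)
        n_copies, dim, n_basis = stack.shape
        if dim == 1:
            flat = stack[:, 0, :]
            for i in members:
                proj = (flat @ orbs.coefficients[i]) @ flat
                out[i] = proj / np.linalg.norm(proj)
            continue
        if len(members) % dim:
            warnings.warn(
                f"{len(members)} orbitals assigned to {dim}-dimensional "
                f"{name}; trailing partners projected without averaging",
                stacklevel=2)
        for start in range(0, len(members) - dim + 1, dim):
            tuple_ids = members[start:start + dim]
            m_acc = np.zeros((n_copies, n_copies))
            for i in tuple_ids:
                c = np.einsum("kdn,n->kd", stack, orbs.coefficients[i])
                m_acc += c @ c.T
            w, vecs = np.linalg.eigh(m_acc)
            a = vecs[:, -1]
            peak = int(np.argmax(np.abs(a)))
            if a[peak] < 0:
                a = -a
            for k, i in enumerate(tuple_ids):
                out[i] = np.einsum("k,kn->n", a, stack[:, k, :])
        for i in members[len(members) - len(members) % dim:]:
            flat = stack.reshape(-1, n_basis)
            proj = (flat @ orbs.coefficients[i]) @ flat
            out[i] = proj / np.linalg.norm(proj)
    # Löwdin orthonormalisation within each irrep (order independent)
    for name, members in by_irrep.items():
        block = out[members]
        s = block @ block.T
        evals, evecs = np.linalg.eigh(s)
        if evals.min() < 1e-10:
            raise ValueError(
                f"orbitals assigned to {name} became linearly dependent")
        s_inv_half = evecs @ np.diag(evals**-0.5) @ evecs.T
        out[members] = s_inv_half @ block
    result = OrbitalSet(out, orbs.occupations)
    final = analyze_orbital_symmetry(result, salcs)
    return result, final
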
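"""Symmetry-adapted linear combinations over (equivalence set × shell).

For each equivalence set S and angular momentum ℓ the group acts by the
outer product D^SY(R) = D^S(R) ⊗ D^Y(R) of the nuclear permutation and
the real-spherical-harmonic shell matrices.  The trace projector

    P^Γ = dim(Γ)/|G| · Σ_R χ^Γ(R) D^SY(R)

extracts the Γ-isotypic subspace (m_Γ·dim(Γ) dimensional); an LDLᵀ-style
pivoted factorisation yields an orthonormal spanning set.  Degenerate
irreps are separated into partner components by subduction to a splitting
subgroup chain with all-real characters, and the components are oriented
consistently across every (set, ℓ) block by transferring the first
component with a fixed group operation — the transfer ratio |Γ(R)_{k1}|
is an irrep property, so the construction is block independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .character_tables import CharacterTable, generate_character_table
from .equivalence import EquivalenceSet, equivalence_sets
from .geometry_io import Molecule
from .operations import IDENTITY, PROPER
from .point_group import PointGroup, Subgroup, permutation_representation
from .real_sph import operation_matrix


class NoSplittingSubgroupError(RuntimeError):
    pass


@dataclass(frozen=True)
class BasisFunction:
    atom: int
    l: int
    m: int
    set_id: int = -1


@dataclass
class BasisSpec:
    """Declared shells: ordered (atom index, ℓ) pairs.  The global basis
    ordering is shell order × m = −ℓ..+ℓ."""

    shells: list[tuple[int, int]]

    @staticmethod
    def uniform(n_atoms: int, l_values: tuple[int, ...]) -> "BasisSpec":
        return BasisSpec([(a, l) for a in range(n_atoms) for l in l_values])

    def functions(self, sets: list[EquivalenceSet] | None = None
                  ) -> list[BasisFunction]:
        set_of = {}
        if sets is not None:
            for sid, s in enumerate(sets):
                for a in s.indices:
                    set_of[a] = sid
        out = []
        for a, l in self.shells:
            for m in range(-l, l + 1):
                out.append(BasisFunction(a, l, m, set_of.get(a, -1)))
        return out

    @property
    def size(self) -> int:
        return sum(2 * l + 1 for _, l in self.shells)

    def index(self, atom: int, l: int, m: int) -> int:
        i = 0
        for a, ll in self.shells:
            if a == atom and ll == l:
                return i + (m + l)
            i += 2 * ll + 1
        raise KeyError((atom, l, m))

    @property
    def l_max(self) -> int:
        return max(l for _, l in self.shells)


@dataclass
class SALCSpace:
    """Orthonormal coefficient rows (m_Γ of them) for one partner
    component of one irrep, over the full basis ordering."""

    irrep: str
    irrep_index: int
    component: int          # 1..dim(Γ)
    set_id: int
    l: int
    coefficients: np.ndarray  # (m_Γ, n_basis)


# ---------------------------------------------------------------------------
# representations and projectors


def direct_product_rep(perm_mats: list[np.ndarray],
                       shell_mats: list[np.ndarray]) -> list[np.ndarray]:
    """D^SY(R) = D^S(R) ⊗ D^Y(R), operation by operation."""
    if len(perm_mats) != len(shell_mats):
        raise ValueError("representation lists are indexed by the same "
                         "operation list and must have equal length")
    return [np.kron(p, y) for p, y in zip(perm_mats, shell_mats)]


def trace_projector(table: CharacterTable, irrep: int,
                    rep_mats: list[np.ndarray],
                    op_subset: list[int] | None = None,
                    check: bool = True) -> np.ndarray:
    """Group-averaged trace projector onto the Γ-isotypic subspace.

    Merged complex-pair rows use the halved prefactor dim/(2|G|) — the
    projector onto the real pair space.  ``op_subset`` restricts the sum
    to a subgroup's operations (rep_mats indexed by the parent group).
    """
    ir = table.irreps[irrep]
    ops = range(len(rep_mats)) if op_subset is None else op_subset
    p = np.zeros_like(rep_mats[0])
    count = 0
    for local, g in enumerate(ops):
        chi = table.char(irrep, local if op_subset is not None else g)
        p += chi * rep_mats[g]
        count += 1
    p *= ir.dim / (ir.weight * count)
    if check and np.abs(p @ p - p).max() > 1e-8:
        raise ValueError(
            f"trace projector for {ir.name} is not idempotent; the "
            "representation and table are inconsistent")
    return p


def extract_subspace(p: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Orthonormal rows spanning the image of a symmetric projector.

    Deterministic pivoted factorisation: repeatedly take the column of
    largest diagonal (ties to the lowest index), normalise, deflate; a
    final modified Gram–Schmidt tidies rounding."""
    rank = int(round(float(np.trace(p))))
    if rank == 0:
        return np.zeros((0, p.shape[0]))
    res = p.copy()
    rows = []
    for _ in range(rank):
        d = np.diag(res)
        i = int(np.argmax(np.round(d, 12)))
        if d[i] < tol:
            raise ValueError("projector rank deficient vs its trace")
        v = res[i] / math.sqrt(d[i])
        rows.append(v)
        res = res - np.outer(v, v)
    out = []
    for v in rows:
        for u in out:
            v = v - (v @ u) * u
        n = np.linalg.norm(v)
        if n < 1e-6:
            raise ValueError("extracted vectors degenerate")
        v = v / n
        out.append(_fix_sign(v))
    return np.stack(out)


def _fix_sign(v: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    for c in v:
        if abs(c) > tol:
            return v if c > 0 else -v
    return v


# ---------------------------------------------------------------------------
# subduction and splitting chains


def subduce(irrep: int, table_g: CharacterTable, sub: Subgroup,
            table_h: CharacterTable) -> np.ndarray:
    """Multiplicities of each irrep of H in Γ↓H (reduction formula
    restricted to H's classes)."""
    h_group = sub.group
    chis = np.empty(len(h_group))
    for local, parent in enumerate(sub.in_parent):
        chis[local] = table_g.char(irrep, parent)
    class_chars = np.array([chis[r] for r in table_h.class_reps])
    return table_h.reduce(class_chars)


@dataclass
class SplitStep:
    subgroup: Subgroup
    table: CharacterTable
    h_irrep: int

    @property
    def name(self) -> str:
        return f"{self.subgroup.label}:{self.table.irreps[self.h_irrep].name}"


def choose_splitting_subgroup(group: PointGroup, table: CharacterTable,
                              irrep: int) -> list[list[SplitStep]]:
    """Component paths (one per partner, canonically ordered) splitting a
    degenerate irrep through subgroups with all-real characters.

    Single-step for 2–4 dimensional irreps; the 5-dimensional icosahedral
    irreps need a two-step chain (order-10 dihedral first, then an
    order-2 subgroup of it).  Complex-character subgroups are skipped.
    """
    dim = table.irreps[irrep].dim
    if dim == 1:
        return [[]]
    subs = group.subgroups()
    paths = _split_recursive(group, table, irrep,
                             [s for s in subs if 1 < len(s) < len(group)])
    if paths is None:
        raise NoSplittingSubgroupError(
            f"no real splitting subgroup for {table.irreps[irrep].name} "
            f"of {group.label}")
    return paths


def _split_recursive(group, table, irrep, candidates):
    dim = table.irreps[irrep].dim
    for sub in candidates:
        table_h = _table_cache(sub)
        if any(ir.complex_pair for ir in table_h.irreps):
            continue
        try:
            mult = subduce(irrep, table, sub, table_h)
        except ValueError:
            continue
        if mult.max() > 1 or (mult > 0).sum() < 2:
            continue
        paths: list[list[SplitStep]] = []
        inner_candidates = None
        for hi, m in enumerate(mult):
            if m == 0:
                continue
            step = SplitStep(sub, table_h, hi)
            hdim = table_h.irreps[hi].dim
            if hdim == 1:
                paths.append([step])
                continue
            if inner_candidates is None:
                inner_candidates = [
                    _lift(sub, s) for s in sub.group.subgroups()
                    if 1 < len(s) < len(sub)]
            sub_paths = _split_inner(sub, table_h, hi, inner_candidates)
            if sub_paths is None:
                break
            paths.extend([step] + p for p in sub_paths)
        else:
            if sum(1 for _ in paths) == dim:
                return paths
            continue
    return None


def _split_inner(sub: Subgroup, table_h: CharacterTable, h_irrep: int,
                 candidates: list[Subgroup]):
    """Second chain level: split a degenerate irrep of H via subgroups of
    H expressed in the *parent* group's operation indices."""
    for inner in candidates:
        table_k = _table_cache(inner)
        if any(ir.complex_pair for ir in table_k.irreps):
            continue
        try:
            mult = _subduce_nested(h_irrep, table_h, sub, inner, table_k)
        except ValueError:
            continue
        dim = table_h.irreps[h_irrep].dim
        if mult.max() > 1 or (mult > 0).sum() != dim:
            continue
        return [[SplitStep(inner, table_k, ki)]
                for ki, m in enumerate(mult) if m > 0]
    return None


def _subduce_nested(h_irrep, table_h, sub_h: Subgroup, sub_k: Subgroup,
                    table_k) -> np.ndarray:
    """Γ_H ↓ K where both H and K are given by parent-group indices."""
    pos_in_h = {parent: local for local, parent in
                enumerate(sub_h.in_parent)}
    chis = np.empty(len(sub_k.indices))
    for local, parent in enumerate(sub_k.in_parent):
        chis[local] = table_h.char(h_irrep, pos_in_h[parent])
    class_chars = np.array([chis[r] for r in table_k.class_reps])
    return table_k.reduce(class_chars)


def _lift(sub_h: Subgroup, inner: Subgroup) -> Subgroup:
    """Express a subgroup of H in the parent group's indices."""
    mapping = sub_h.in_parent
    inner.group
    parent_indices = tuple(sorted(mapping[i] for i in inner.indices))
    return Subgroup(sub_h.parent, parent_indices, inner.label)


_tables: dict[tuple, CharacterTable] = {}


def _table_cache(sub: Subgroup) -> CharacterTable:
    key = (id(sub.parent), sub.indices)
    if key not in _tables:
        _tables[key] = generate_character_table(sub.group)
    return _tables[key]


# ---------------------------------------------------------------------------
# partner functions


def partner_functions(
    v_gamma: np.ndarray,
    paths: list[list[SplitStep]],
    rep_mats: list[np.ndarray],
    group: PointGroup,
    p_gamma: np.ndarray,
    transfer_threshold: float = 0.2,
) -> list[np.ndarray]:
    """Split the Γ-isotypic space into canonically oriented partner
    component bases (each m_Γ × n rows).

    Component 1 is extracted from the chain projector; the others are
    images under the first group operation with a non-negligible
    intrinsic transfer amplitude, so every (set, ℓ) block receives the
    same orientation.
    """
    comps: list[np.ndarray] = []
    projs = []
    for path in paths:
        p = p_gamma.copy()
        for step in path:
            p = trace_projector(
                step.table, step.h_irrep, rep_mats,
                op_subset=list(step.subgroup.in_parent), check=False) @ p
        projs.append(0.5 * (p + p.T))
    base = extract_subspace(projs[0])
    comps.append(base)
    for k in range(1, len(paths)):
        pk = projs[k]
        rows = None
        for g, op in enumerate(group.operations):
            cand = base @ rep_mats[g].T @ pk.T
            norms = np.linalg.norm(cand, axis=1)
            if norms.min() > transfer_threshold:
                if norms.max() - norms.min() > 1e-6:
                    continue  # not a clean intrinsic transfer
                rows = cand / norms[0]
                break
        if rows is None:
            raise NoSplittingSubgroupError(
                "no operation connects partner components (degenerate "
                "chain choice)")
        comps.append(rows)
    return comps


def _pair_components_cyclic(v_rows: np.ndarray, d_gen: np.ndarray
                            ) -> list[np.ndarray]:
    """Partner separation for merged complex-pair irreps of purely
    rotational groups: the antisymmetric part of the generator pairs each
    vector v with w ∝ (D−Dᵀ)v, giving rotation-plane partners."""
    a = 0.5 * (d_gen - d_gen.T)
    remaining = [r for r in v_rows]
    v_list, w_list = [], []
    while remaining:
        v = remaining.pop(0)
        n = np.linalg.norm(v)
        if n < 1e-9:
            continue
        v = v / n
        w = a @ v
        wn = np.linalg.norm(w)
        if wn < 1e-9:
            raise ValueError("generator does not rotate the pair space")
        w = w / wn
        v_list.append(v)
        w_list.append(w)
        new_rem = []
        for r in remaining:
            r = r - (r @ v) * v - (r @ w) * w
            new_rem.append(r)
        remaining = [r for r in new_rem if np.linalg.norm(r) > 1e-9]
    return [np.stack(v_list), np.stack(w_list)]


# ---------------------------------------------------------------------------
# orchestration


def build_salcs(
    mol: Molecule,
    group: PointGroup,
    basis_spec: BasisSpec,
    table: CharacterTable | None = None,
    sets: list[EquivalenceSet] | None = None,
    tol: float = 0.05,
) -> list[SALCSpace]:
    """SALCs for every (equivalence set, ℓ) block; the union of all rows
    is a complete orthonormal basis of the declared function space."""
    if table is None:
        table = generate_character_table(group)
    if sets is None:
        sets = equivalence_sets(mol)
    n_basis = basis_spec.size
    pos = mol.positions
    out: list[SALCSpace] = []
    path_cache: dict[int, list[list[SplitStep]]] = {}
    for sid, s in enumerate(sets):
        atoms = list(s.indices)
        l_values = sorted({l for a, l in basis_spec.shells if a in atoms})
        for a in atoms:
            if sorted(l for aa, l in basis_spec.shells if aa == a) != \
                    sorted(l for aa, l in basis_spec.shells if aa == atoms[0]):
                raise ValueError(
                    "atoms of one equivalence set must carry identical "
                    "shell lists")
        if not l_values:
            continue
        perms = permutation_representation(group, pos[atoms], tol=tol)
        perm_mats = []
        for perm in perms:
            m = np.zeros((len(atoms), len(atoms)))
            m[perm.images, np.arange(len(atoms))] = 1.0
            perm_mats.append(m)
        for l in l_values:
            shell_mats = [operation_matrix(l, op) for op in group.operations]
            rep = direct_product_rep(perm_mats, shell_mats)
            cols = [basis_spec.index(a, l, m)
                    for a in atoms for m in range(-l, l + 1)]
            class_chars = np.array([np.trace(rep[r])
                                    for r in table.class_reps])
            mults = table.reduce(class_chars)
            for gi, m_gamma in enumerate(mults):
                if m_gamma == 0:
                    continue
                ir = table.irreps[gi]
                p = trace_projector(table, gi, rep)
                if ir.dim == 1:
                    comps = [extract_subspace(p)]
                elif ir.constituents is not None:
                    comps = []
                    for chis in ir.constituents:
                        pk = sum(c * m for c, m in zip(chis, rep))
                        pk /= len(rep)
                        comps.append(extract_subspace(0.5 * (pk + pk.T)))
                elif ir.complex_pair:
                    gen = _principal_generator(group)
                    v = extract_subspace(p)
                    comps = _pair_components_cyclic(v, rep[gen])
                else:
                    if gi not in path_cache:
                        path_cache[gi] = choose_splitting_subgroup(
                            group, table, gi)
                    comps = partner_functions(
                        extract_subspace(p), path_cache[gi], rep, group, p)
                for ci, rows in enumerate(comps):
                    wide = np.zeros((rows.shape[0], n_basis))
                    wide[:, cols] = rows
                    out.append(SALCSpace(ir.name, gi, ci + 1, sid, l, wide))
    total = sum(sp.coefficients.shape[0] for sp in out)
    if total != n_basis:
        raise RuntimeError(
            f"SALC construction incomplete: {total} rows for "
            f"{n_basis} basis functions")
    return out


def _principal_generator(group: PointGroup) -> int:
    best, key = None, None
    for i, op in enumerate(group.operations):
        if op.kind == IDENTITY:
            continue
        k = (0 if op.kind == PROPER else 1, -op.order, op.power, i)
        if key is None or k < key:
            best, key = i, k
    if best is None:
        raise ValueError("group has no non-identity operation")
    return best


def salc_matrix(salcs: list[SALCSpace]) -> np.ndarray:
    """All SALC rows stacked (irrep-major within each block build order)."""
    return np.vstack([sp.coefficients for sp in salcs])
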
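"""Real character tables, auto-generated for the axial families.

Cyclic and dihedral groups of arbitrary order get their tables generated
from the operation geometry: every operation of an axial group factors
into a 2-D action in the plane perpendicular to the principal axis (a
rotation by φ or a reflection across an azimuth β) times ±1 along the
axis.  One-dimensional irreps are ±1-valued homomorphisms of that
factorisation; two-dimensional irreps have χ(C^k) = 2cos(jkθ) with an
incremental index j, zero on in-plane flips/mirrors, and a ± factor for
the behaviour under σ_h.

Complex-conjugate irrep pairs (purely rotational projections: Cn, Cnh,
S2n, and the cubic-E of T/Th) are merged into real 2-D rows over merged
classes; such rows carry weight 2 in the orthogonality relations and in
the projector prefactor.

Polyhedral tables are static verified data; linear groups get a finite
surrogate (C_2ℓv / D_2ℓh with the vertical and dihedral classes merged)
whose splitting of functions up to ℓ matches the true infinite group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .operations import (
    IDENTITY,
    INVERSION,
    MIRROR,
    PROPER,
    operation_from_matrix,
)
from .point_group import (
    POLYHEDRAL,
    PointGroup,
    generate_group_operations,
    parse_label,
    _in_plane_basis,
)

_GOLDEN = (1.0 + math.sqrt(5.0)) / 2.0


def e_character(j: int, n: int, k: int) -> float:
    """Character of Ĉₙᵏ in the 2-dimensional irrep with index j."""
    return 2.0 * math.cos(2.0 * math.pi * j * k / n)


@dataclass
class Irrep:
    name: str
    dim: int
    e_index: int | None = None
    complex_pair: bool = False
    sub: str = ""
    parity: str = ""
    #: per-operation character rows of the two 1-D constituents, set only
    #: for rows merged from one-dimensional irreps (linear surrogates)
    constituents: tuple | None = None

    @property
    def weight(self) -> int:
        """Frobenius–Schur-style weight: 2 for a merged complex pair."""
        return 2 if self.complex_pair else 1


@dataclass
class CharacterTable:
    label: str
    group: PointGroup
    class_members: list[list[int]]   # op indices per class
    class_reps: list[int]
    irreps: list[Irrep]
    chars: np.ndarray                # (n_irreps, n_classes), real
    class_ids: np.ndarray = field(default=None)  # per-op class index

    def __post_init__(self) -> None:
        if self.class_ids is None:
            ids = np.empty(len(self.group), dtype=np.int64)
            for ci, members in enumerate(self.class_members):
                for m in members:
                    ids[m] = ci
            self.class_ids = ids

    @property
    def class_sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.class_members])

    @property
    def order(self) -> int:
        return int(self.class_sizes.sum())

    def char(self, irrep: int, op_index: int) -> float:
        return float(self.chars[irrep, self.class_ids[op_index]])

    def irrep_index(self, name: str) -> int:
        for i, ir in enumerate(self.irreps):
            if ir.name == name:
                return i
        raise KeyError(name)

    @property
    def totally_symmetric(self) -> int:
        return 0

    def reduce(self, rep_class_chars: np.ndarray, tol: float = 1e-8) -> np.ndarray:
        """Multiplicities of each irrep in a representation given by its
        per-class characters (merged rows count real 2-D blocks)."""
        sizes = self.class_sizes
        out = np.empty(len(self.irreps))
        for i, ir in enumerate(self.irreps):
            val = float(sizes @ (self.chars[i] * rep_class_chars))
            val /= self.order * ir.weight
            if abs(val - round(val)) > tol:
                raise ValueError(
                    f"non-integer multiplicity {val} for {ir.name}")
            out[i] = round(val)
        return out.astype(np.int64)

    def validate(self, tol: float = 1e-10) -> None:
        """Dimension sum and weighted row/column orthogonality."""
        g = self.order
        dims = np.array([ir.dim for ir in self.irreps])
        w = np.array([ir.weight for ir in self.irreps])
        if abs((dims**2 / w).sum() - g) > tol:
            raise AssertionError("dimension sum rule violated")
        if not np.allclose(self.chars[0], 1.0, atol=tol):
            raise AssertionError("first row is not totally symmetric")
        e_col = int(np.where(np.array(self.class_reps) == 0)[0][0]) \
            if 0 in self.class_reps else 0
        if not np.allclose(self.chars[:, e_col], dims, atol=tol):
            raise AssertionError("identity column does not list dimensions")
        sizes = self.class_sizes
        gram = (self.chars * sizes) @ self.chars.T
        if not np.allclose(gram, np.diag(g * w.astype(float)), atol=max(tol, 1e-9 * g)):
            raise AssertionError("row orthogonality violated")
        col = self.chars.T @ (self.chars / w[:, None])
        target = np.diag(g / sizes.astype(float))
        if not np.allclose(col, target, atol=max(tol, 1e-9 * g)):
            raise AssertionError("column orthogonality violated")


# ---------------------------------------------------------------------------
# generic axial generation


def _axial_op_geometry(group: PointGroup):
    """Per-operation 2-D factorisation: (is_reflection, φ or β, ε_z)."""
    p = group.principal_axis
    u, v = _in_plane_basis(p)
    geo = []
    for op in group.operations:
        m = op.matrix
        mp = m @ p
        eps = 1.0 if mp @ p > 0 else -1.0
        if np.linalg.norm(mp - eps * p) > 1e-8:
            raise ValueError("operation does not preserve the principal axis")
        b = np.array([[u @ m @ u, u @ m @ v], [v @ m @ u, v @ m @ v]])
        if np.linalg.det(b) > 0:
            phi = math.atan2(b[1, 0], b[0, 0])
            geo.append((False, phi, eps))
        else:
            beta = 0.5 * math.atan2(b[0, 1], b[0, 0])
            geo.append((True, beta % math.pi, eps))
    return geo


def _projected_order(geo) -> int:
    n = 1
    for refl, phi, _ in geo:
        if not refl:
            frac = Fraction(phi / (2 * math.pi)).limit_denominator(2000)
            n = n * frac.denominator // math.gcd(n, frac.denominator)
    return n


def generate_character_table(group: PointGroup) -> CharacterTable:
    """Real character table of any generated point group."""
    family, _ = parse_label(group.label)
    if family in POLYHEDRAL:
        return _polyhedral_table(group)
    if len(group) == 1:
        return CharacterTable(group.label, group, [[0]], [0],
                              [Irrep("A", 1)], np.array([[1.0]]))
    return _axial_table(group)


def _axial_table(group: PointGroup) -> CharacterTable:
    geo = _axial_op_geometry(group)
    n_proj = _projected_order(geo)
    reps = [c[0] for c in group.classes]
    rep_geo = [geo[r] for r in reps]
    has_refl = any(r for r, _, _ in geo)
    has_eps = any(e < 0 for _, _, e in geo)
    has_inv = any(op.kind == INVERSION for op in group.operations)
    sigma_h_idx = next(
        (i for i, op in enumerate(group.operations)
         if op.kind == MIRROR
         and abs(op.axis @ group.principal_axis) > 1 - 1e-8), None)
    # reference azimuth: first perpendicular C2, else first vertical mirror
    flip_betas = sorted(
        b for (r, b, e), op in zip(geo, group.operations)
        if r and e < 0 and op.kind == PROPER)
    mirror_betas = sorted(
        b for (r, b, e), op in zip(geo, group.operations)
        if r and e > 0 and op.kind == MIRROR)
    beta0 = flip_betas[0] if flip_betas else (
        mirror_betas[0] if mirror_betas else 0.0)

    def one_dim_char(j0: int, vv: float, t: int, g) -> float:
        refl, ang, eps = g
        if refl:
            val = vv * math.cos(2 * j0 * (ang - beta0))
        else:
            val = math.cos(j0 * ang)
        if t and eps < 0:
            val = -val
        r = round(val)
        assert abs(val - r) < 1e-9 and abs(r) == 1
        return float(r)

    j0_values = [0] + ([n_proj // 2] if n_proj % 2 == 0 and n_proj >= 2 else [])
    v_values = [1.0, -1.0] if has_refl else [1.0]
    t_values = [0, 1] if has_eps else [0]
    seen: list[np.ndarray] = []
    irreps: list[Irrep] = []
    charlist: list[np.ndarray] = []
    for j0 in j0_values:
        for vv in v_values:
            for t in t_values:
                row = np.array([one_dim_char(j0, vv, t, g) for g in rep_geo])
                if any(np.allclose(s, row, atol=1e-9) for s in seen):
                    continue
                seen.append(row)
                irreps.append(Irrep("A", 1))  # letter fixed during naming
                charlist.append(row)
    cp = not has_refl  # purely rotational projection ⇒ merged complex pairs
    for j in range(1, (n_proj - 1) // 2 + 1):
        for t in t_values:
            row = np.array([
                ((-1.0) ** t if e < 0 else 1.0) * (0.0 if r else 2 * math.cos(j * a))
                for r, a, e in rep_geo
            ])
            if any(np.allclose(s, row, atol=1e-9) for s in seen):
                continue
            seen.append(row)
            irreps.append(Irrep("E", 2, e_index=j, complex_pair=cp))
            charlist.append(row)

    chars = np.stack(charlist)
    w = np.array([ir.weight for ir in irreps])
    dims = np.array([ir.dim for ir in irreps])
    if abs((dims**2 / w).sum() - len(group)) > 1e-9:
        raise RuntimeError(
            f"irrep enumeration incomplete for {group.label}")
    _assign_names(irreps, chars, group, reps, sigma_h_idx, has_inv, geo)
    order = sorted(range(len(irreps)),
                   key=lambda i: _irrep_sort_key(irreps[i]))
    irreps = [irreps[i] for i in order]
    chars = chars[order]
    table = CharacterTable(group.label, group,
                           [list(c) for c in group.classes], reps,
                           irreps, chars)
    return table


def _assign_names(irreps, chars, group, reps, sigma_h_idx, has_inv,
                  geo) -> None:
    """Mulliken names.

    A/B from the character under the principal rotation — the proper Cn
    when the group is centrosymmetric (S6-style groups keep A labels),
    otherwise the operation carrying the finest projected rotation (the
    S2n axis names the B of S4/D2d).  Subscripts come from the first
    perpendicular C2 (or first σ_v), primes from σ_h, g/u from inversion;
    E irreps are indexed by the j recovered from that same finest
    rotation, shown when more than one E survives per parity.
    """
    inv_idx = next((i for i, op in enumerate(group.operations)
                    if op.kind == INVERSION), None)
    ref_idx = next((i for i, op in enumerate(group.operations)
                    if op.kind == PROPER and op.order == 2
                    and abs(op.axis @ group.principal_axis) < 1e-8), None)
    if ref_idx is None:
        ref_idx = next((i for i, op in enumerate(group.operations)
                        if op.kind == MIRROR
                        and abs(op.axis @ group.principal_axis) < 1e-8), None)
    has_sub = ref_idx is not None
    cid = group.class_ids

    def ch(row: int, op_idx: int) -> float:
        return float(chars[row, _class_col(reps, cid, op_idx)])

    # finest projected rotation (names E indices and, absent inversion, A/B)
    fine_idx, fine_phi = None, math.inf
    for i, (refl, ang, _) in enumerate(geo):
        if not refl and 1e-9 < abs(ang) < fine_phi:
            fine_idx, fine_phi = i, abs(ang)
    if has_inv:
        n_rot = max((op.order for op in group.operations
                     if op.kind == PROPER), default=1)
        letter_idx = next((i for i, op in enumerate(group.operations)
                           if op.kind == PROPER and op.order == n_rot
                           and op.power in (1, n_rot - 1)), None)
    else:
        letter_idx = fine_idx

    for i, ir in enumerate(irreps):
        if inv_idx is not None:
            ir.parity = "g" if ch(i, inv_idx) > 0 else "u"
        elif sigma_h_idx is not None:
            ir.parity = "'" if ch(i, sigma_h_idx) > 0 else "''"
        if ir.dim == 1:
            ir.name = "A" if (letter_idx is None
                              or ch(i, letter_idx) > 0) else "B"
            if has_sub and ir.name in ("A", "B"):
                ir.sub = "1" if ch(i, ref_idx) > 0 else "2"
        elif ir.dim == 2 and fine_idx is not None:
            val = max(-1.0, min(1.0, ch(i, fine_idx) / 2.0))
            ir.e_index = max(1, round(math.acos(val) / fine_phi))
    # the D2/D2h convention: three B irreps numbered by their symmetry axis
    if group.label in ("D2", "D2h"):
        for ir in irreps:
            if ir.dim != 1:
                continue
            if ir.name == "A" and ir.sub == "2":
                ir.name, ir.sub = "B", "1"  # symmetric about the z rotation
            elif ir.name == "B":
                # reference flip is the first perpendicular C2 (the y axis
                # in the canonical frame): symmetric there → B2, else B3
                ir.sub = "2" if ir.sub == "1" else "3"
            elif ir.name == "A":
                ir.sub = ""
    e_by_parity: dict[str, list[Irrep]] = {}
    for ir in irreps:
        if ir.dim == 2:
            e_by_parity.setdefault(ir.parity, []).append(ir)
    for group_list in e_by_parity.values():
        show_index = len(group_list) > 1
        for ir in group_list:
            ir.sub = str(ir.e_index) if show_index else ""
    for ir in irreps:
        ir.name = f"{ir.name}{ir.sub}{ir.parity}"


def _class_col(reps, cid, op_idx) -> int:
    c = int(cid[op_idx])
    for col, r in enumerate(reps):
        if cid[r] == c:
            return col
    raise KeyError


_LETTER_RANK = {"A": 0, "B": 1, "E": 2, "T": 3, "G": 4, "H": 5}
_PARITY_RANK = {"": 0, "'": 0, "g": 0, "''": 1, "u": 1}


def _irrep_sort_key(ir: Irrep):
    base = ir.name[0] if ir.name and ir.name[0] in _LETTER_RANK else "A"
    return (
        _PARITY_RANK.get(ir.parity, 0),
        ir.dim,
        _LETTER_RANK.get(base, 9),
        ir.e_index or 0,
        ir.sub,
    )


# ---------------------------------------------------------------------------
# polyhedral static tables

_PHI = _GOLDEN

# class keys: ('p'|'i', reduced angle fraction, axis shared with a C4 axis)
_BASE_TABLES = {
    "T": (
        [("p", Fraction(0), False), ("p", Fraction(1, 3), False),
         ("p", Fraction(1, 2), False)],
        [("A", 1, False, [1, 1, 1]),
         ("E", 2, True, [2, -1, 2]),
         ("T", 3, False, [3, 0, -1])],
    ),
    "Td": (
        [("p", Fraction(0), False), ("p", Fraction(1, 3), False),
         ("p", Fraction(1, 2), False), ("i", Fraction(1, 4), False),
         ("i", Fraction(1, 2), False)],
        [("A1", 1, False, [1, 1, 1, 1, 1]),
         ("A2", 1, False, [1, 1, 1, -1, -1]),
         ("E", 2, False, [2, -1, 2, 0, 0]),
         ("T1", 3, False, [3, 0, -1, 1, -1]),
         ("T2", 3, False, [3, 0, -1, -1, 1])],
    ),
    "O": (
        [("p", Fraction(0), False), ("p", Fraction(1, 3), False),
         ("p", Fraction(1, 2), False), ("p", Fraction(1, 4), True),
         ("p", Fraction(1, 2), True)],
        [("A1", 1, False, [1, 1, 1, 1, 1]),
         ("A2", 1, False, [1, 1, -1, -1, 1]),
         ("E", 2, False, [2, -1, 0, 0, 2]),
         ("T1", 3, False, [3, 0, -1, 1, -1]),
         ("T2", 3, False, [3, 0, 1, -1, -1])],
    ),
    "I": (
        [("p", Fraction(0), False), ("p", Fraction(1, 5), False),
         ("p", Fraction(2, 5), False), ("p", Fraction(1, 3), False),
         ("p", Fraction(1, 2), False)],
        [("A", 1, False, [1, 1, 1, 1, 1]),
         ("T1", 3, False, [3, _PHI, 1 - _PHI, 0, -1]),
         ("T2", 3, False, [3, 1 - _PHI, _PHI, 0, -1]),
         ("G", 4, False, [4, -1, -1, 1, 0]),
         ("H", 5, False, [5, 0, 0, -1, 1])],
    ),
}


def _poly_class_key(group: PointGroup, op_idx: int):
    op = group.operations[op_idx]
    c4_axes = [o.axis for o in group.operations
               if o.kind == PROPER and o.order == 4]
    if op.kind == IDENTITY:
        return ("p", Fraction(0), False)
    if op.kind == INVERSION:
        return ("i", Fraction(0), False)
    if op.kind == PROPER:
        frac = Fraction(min(op.power, op.order - op.power), op.order)
        axis = op.axis
        par = "p"
    else:
        comp = operation_from_matrix(-op.matrix)
        if comp.kind == IDENTITY:
            frac = Fraction(0)
        else:
            frac = Fraction(min(comp.power, comp.order - comp.power),
                            comp.order)
        axis = comp.axis if comp.kind == PROPER else comp.axis
        par = "i"
    tag = any(abs(abs(axis @ a) - 1.0) < 1e-8 for a in c4_axes)
    return (par, frac, tag)


def _polyhedral_table(group: PointGroup) -> CharacterTable:
    base_label = {"T": "T", "Th": "T", "Td": "Td", "O": "O", "Oh": "O",
                  "I": "I", "Ih": "I"}[group.label]
    centro = group.label in ("Th", "Oh", "Ih")
    keys, data = _BASE_TABLES[base_label]
    reps = [c[0] for c in group.classes]
    rep_keys = [_poly_class_key(group, r) for r in reps]
    irreps: list[Irrep] = []
    charlist: list[np.ndarray] = []
    parities = ("g", "u") if centro else ("",)
    for par in parities:
        for name, dim, cp, vals in data:
            row = np.empty(len(reps))
            for col, key in enumerate(rep_keys):
                kpar, frac, tag = key
                try:
                    base_col = (keys.index(("p", frac, tag)) if centro
                                else keys.index(key))
                except ValueError:
                    raise KeyError(
                        f"unmatched class key {key} in {group.label}")
                val = vals[base_col]
                if kpar == "i" and centro and par == "u":
                    val = -val
                row[col] = val
            irreps.append(Irrep(name + par, dim, complex_pair=cp,
                                sub=name[1:], parity=par))
            charlist.append(row)
    chars = np.stack(charlist)
    return CharacterTable(group.label, group,
                          [list(c) for c in group.classes], reps,
                          irreps, chars)


# ---------------------------------------------------------------------------
# linear-group surrogates

_GREEK = ["Sigma", "Pi", "Delta", "Phi", "Gamma", "H", "I", "K"]


def linear_group_table(label: str, l_max: int,
                       transform: np.ndarray | None = None,
                       ) -> tuple[PointGroup, CharacterTable]:
    """Finite surrogate for C∞v / D∞h: the subgroup C_(2ℓ)v or D_(2ℓ)h with
    vertical and dihedral C2/σ operations merged into shared classes, so
    functions up to angular momentum ℓ split exactly as in the linear
    group.  Returns the surrogate group and its table."""
    if label not in ("Cinfv", "Dinfh"):
        raise ValueError("linear surrogate applies to Cinfv / Dinfh only")
    ell = max(l_max, 1)
    n = 2 * ell
    sub_label = f"C{n}v" if label == "Cinfv" else f"D{n}h"
    group = generate_group_operations(sub_label, transform=transform)
    base = generate_character_table(group)

    # merge classes of vertical/dihedral partners with equal ε_z behaviour
    merged: list[list[int]] = []
    key_to_slot: dict[tuple, int] = {}
    for ci, members in enumerate(base.class_members):
        op = group.operations[members[0]]
        if op.orientation in ("vertical", "dihedral") and op.kind in (
                PROPER, MIRROR):
            key = ("vd", op.kind)
        else:
            key = ("class", ci)
        if key in key_to_slot:
            merged[key_to_slot[key]].extend(members)
        else:
            key_to_slot[key] = len(merged)
            merged.append(list(members))
    reps = [c[0] for c in merged]
    cid = np.empty(len(group), dtype=np.int64)
    for ci, members in enumerate(merged):
        for m in members:
            cid[m] = ci

    # 1-D rows that are not class functions on the merged classes pair up
    # (same parity) into 2-D Λ = ℓ rows; all other rows stay
    def constant_on_merged(i: int) -> bool:
        return all(
            abs(base.char(i, m) - base.char(i, members[0])) < 1e-9
            for members in merged for m in members)

    rows: list[np.ndarray] = []
    irreps: list[Irrep] = []
    used = [False] * len(base.irreps)
    for i, ir in enumerate(base.irreps):
        if used[i]:
            continue
        used[i] = True
        vals = np.array([base.char(i, base.class_members[
            base.class_ids[r]][0]) for r in reps])
        if ir.dim == 1 and not constant_on_merged(i):
            j = next(k for k, o in enumerate(base.irreps)
                     if not used[k] and o.dim == 1
                     and o.parity == ir.parity and not constant_on_merged(k))
            used[j] = True
            vals = np.array([base.char(i, r) + base.char(j, r) for r in reps])
            per_op = tuple(
                np.array([base.char(k, o) for o in range(len(group))])
                for k in (i, j))
            irreps.append(Irrep(_lin_name(ell, ir.parity, label), 2,
                                e_index=ell, complex_pair=True,
                                parity=ir.parity, constituents=per_op))
            rows.append(vals)
            continue
        if ir.dim == 1:
            sign = "+" if vals[_sigma_col(group, reps)] > 0 else "-"
            name = _lin_name(0, ir.parity, label) + sign
        else:
            name = _lin_name(ir.e_index, ir.parity, label)
        irreps.append(Irrep(name, ir.dim, e_index=ir.e_index,
                            complex_pair=ir.complex_pair, parity=ir.parity))
        rows.append(vals)
    table = CharacterTable(label, group, merged, reps, irreps,
                           np.stack(rows), cid)
    return group, table


def _lin_name(lam: int, parity: str, label: str) -> str:
    greek = _GREEK[lam] if lam < len(_GREEK) else f"Lambda{lam}"
    if label == "Dinfh" and parity:
        return f"{greek}_{parity}"
    return greek


def _sigma_col(group: PointGroup, reps) -> int:
    for col, r in enumerate(reps):
        op = group.operations[r]
        if op.kind == MIRROR and op.orientation in ("vertical", "dihedral"):
            return col
    raise KeyError("no vertical mirror class")
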
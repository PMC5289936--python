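"""Point groups: Schoenflies labels, exact operation sets, conjugacy
classes, multiplication tables, subgroups and permutation representations.

Groups are generated exactly from their canonical frame (principal axis z,
first perpendicular C2 / first σ_v trace along x) and optionally conjugated
into a molecule's frame by an orthogonal alignment transform.  Conjugacy
classes of mutually inverse rotations are merged, matching the real-valued
character convention used for real spherical harmonic basis functions.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .operations import (
    IDENTITY,
    IMPROPER,
    INVERSION,
    MIRROR,
    PROPER,
    SymmetryOperation,
    improper_rotation_matrix,
    operation_from_matrix,
    reflection_matrix,
    rotation_matrix,
)

_Z = np.array([0.0, 0.0, 1.0])

POLYHEDRAL = ("T", "Td", "Th", "O", "Oh", "I", "Ih")
LINEAR = ("Cinfv", "Dinfh")

_GOLDEN = (1.0 + math.sqrt(5.0)) / 2.0


class UnknownLabelError(ValueError):
    pass


def parse_label(label: str) -> tuple[str, int]:
    """Split a Schoenflies label into (family, n); n = 0 for the fixed
    groups (Cs, Ci, polyhedral, linear)."""
    if label in ("Cs", "Ci") + POLYHEDRAL + LINEAR:
        return label, 0
    m = re.fullmatch(r"(C|S|D)(\d+)(v|h|d)?", label)
    if not m:
        raise UnknownLabelError(f"unknown point group label {label!r}")
    family = m.group(1) + (m.group(3) or "")
    n = int(m.group(2))
    if family == "S":
        if n < 4 or n % 2:
            raise UnknownLabelError(
                f"S{n} is not a valid group label (odd S_n groups are C_nh, "
                "S2 is Ci)"
            )
    elif n < 1 or (n < 2 and family != "C"):
        raise UnknownLabelError(f"unsupported order in label {label!r}")
    return family, n


def group_order(label: str) -> int:
    family, n = parse_label(label)
    sizes = {"Cs": 2, "Ci": 2, "T": 12, "Td": 24, "Th": 24, "O": 24,
             "Oh": 48, "I": 60, "Ih": 120}
    if family in sizes:
        return sizes[family]
    if family in LINEAR:
        raise UnknownLabelError("linear groups are infinite; use a surrogate")
    return {"C": n, "S": n, "Cv": 2 * n, "Ch": 2 * n,
            "D": 2 * n, "Dh": 4 * n, "Dd": 4 * n}[family]


# ---------------------------------------------------------------------------
# canonical matrices per family


def _axial_matrices(family: str, n: int) -> list[np.ndarray]:
    rots = [rotation_matrix(_Z, 2 * math.pi * k / n) for k in range(n)]
    flips = [
        rotation_matrix(np.array([math.cos(k * math.pi / n),
                                  math.sin(k * math.pi / n), 0.0]), math.pi)
        for k in range(n)
    ]
    mirrors_v = [
        reflection_matrix(np.array([-math.sin(k * math.pi / n),
                                    math.cos(k * math.pi / n), 0.0]))
        for k in range(n)
    ]
    sig_h = reflection_matrix(_Z)
    if family == "C":
        return rots
    if family == "Cv":
        return rots + mirrors_v
    if family == "Ch":
        return rots + [sig_h @ r for r in rots]
    if family == "S":
        out = []
        for k in range(n):
            ang = 2 * math.pi * k / n
            out.append(rotation_matrix(_Z, ang) if k % 2 == 0
                       else improper_rotation_matrix(_Z, ang))
        return out
    if family == "D":
        return rots + flips
    if family == "Dh":
        return rots + flips + [sig_h @ m for m in rots + flips]
    if family == "Dd":
        s2n = [improper_rotation_matrix(_Z, (2 * k + 1) * math.pi / n)
               for k in range(n)]
        mirrors_d = [
            reflection_matrix(np.array([
                -math.sin((k + 0.5) * math.pi / n),
                math.cos((k + 0.5) * math.pi / n), 0.0]))
            for k in range(n)
        ]
        return rots + flips + s2n + mirrors_d
    raise UnknownLabelError(family)


def _closure(generators: list[np.ndarray]) -> list[np.ndarray]:
    mats = [np.eye(3)]
    frontier = list(generators)
    while frontier:
        m = frontier.pop()
        if min(np.abs(np.stack(mats) - m).max(axis=(1, 2))) < 1e-8:
            continue
        mats.append(m)
        for g in generators:
            frontier.append(g @ m)
            frontier.append(m @ g)
    return mats


@lru_cache(maxsize=None)
def _canonical_matrices_cached(label: str) -> tuple[bytes, int]:
    family, n = parse_label(label)
    if family == "C" and n == 1:
        mats = [np.eye(3)]
    elif family == "Cs":
        mats = [np.eye(3), reflection_matrix(_Z)]
    elif family == "Ci":
        mats = [np.eye(3), -np.eye(3)]
    elif family in POLYHEDRAL:
        c3 = rotation_matrix(np.array([1.0, 1.0, 1.0]) / math.sqrt(3),
                             2 * math.pi / 3)
        c2z = rotation_matrix(_Z, math.pi)
        gens = {
            "T": [c2z, c3],
            "Td": [c2z, c3, reflection_matrix(np.array([1.0, -1.0, 0.0]))],
            "Th": [c2z, c3, -np.eye(3)],
            "O": [rotation_matrix(_Z, math.pi / 2), c3],
            "Oh": [rotation_matrix(_Z, math.pi / 2), c3, -np.eye(3)],
            "I": [c2z, c3,
                  rotation_matrix(np.array([0.0, 1.0, _GOLDEN]), 2 * math.pi / 5)],
            "Ih": [c2z, c3,
                   rotation_matrix(np.array([0.0, 1.0, _GOLDEN]), 2 * math.pi / 5),
                   -np.eye(3)],
        }[family]
        mats = _closure(gens)
    elif family in LINEAR:
        raise UnknownLabelError(
            f"{label} is infinite; build a finite surrogate via "
            "character_tables.linear_group_table"
        )
    else:
        mats = _axial_matrices(family, n)
    arr = np.stack(mats)
    return arr.tobytes(), len(mats)


def canonical_matrices(label: str) -> np.ndarray:
    buf, count = _canonical_matrices_cached(label)
    return np.frombuffer(buf, dtype=float).reshape(count, 3, 3).copy()


# ---------------------------------------------------------------------------
# the PointGroup container


@dataclass
class Permutation:
    images: np.ndarray

    def cycles(self, keep_fixed: bool = True) -> list[tuple[int, ...]]:
        seen = set()
        out = []
        for start in range(len(self.images)):
            if start in seen:
                continue
            cyc = [start]
            seen.add(start)
            nxt = int(self.images[start])
            while nxt != start:
                cyc.append(nxt)
                seen.add(nxt)
                nxt = int(self.images[nxt])
            if keep_fixed or len(cyc) > 1:
                out.append(tuple(cyc))
        return out

    def __mul__(self, other: "Permutation") -> "Permutation":
        # (self ∘ other)(i) = self[other[i]]
        return Permutation(self.images[other.images])


@dataclass
class PointGroup:
    label: str
    operations: list[SymmetryOperation]
    table: np.ndarray
    classes: list[list[int]]
    class_ids: np.ndarray
    inverse: np.ndarray
    principal_axis: np.ndarray
    transform: np.ndarray
    generators: list[int] = field(default_factory=list)
    _subgroups: list["Subgroup"] | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.operations)

    @property
    def order(self) -> int:
        return len(self.operations)

    def matrices(self) -> np.ndarray:
        return np.stack([op.matrix for op in self.operations])

    def op_index(self, matrix: np.ndarray, tol: float = 1e-6) -> int:
        d = np.abs(self.matrices() - matrix).max(axis=(1, 2))
        i = int(np.argmin(d))
        if d[i] > tol:
            raise ValueError("matrix is not an operation of this group")
        return i

    def subgroups(self, cap: int = 240) -> list["Subgroup"]:
        if self._subgroups is None:
            self._subgroups = enumerate_subgroups(self, cap=cap)
        return self._subgroups


@dataclass
class Subgroup:
    """A concrete (oriented) subgroup: operation indices into the parent."""

    parent: PointGroup
    indices: tuple[int, ...]
    label: str
    _group: PointGroup | None = field(default=None, repr=False)
    sorted_indices: tuple[int, ...] | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def group(self) -> PointGroup:
        """The subgroup as a standalone PointGroup (canonically re-sorted);
        ``group.operations[k]`` corresponds to parent index
        ``self.sorted_indices[k]``."""
        if self._group is None:
            mats = [self.parent.operations[i].matrix for i in self.indices]
            g = group_from_matrices(mats, label=self.label)
            order = [self.parent.op_index(op.matrix) for op in g.operations]
            self._group = g
            self.sorted_indices = tuple(order)
        return self._group

    @property
    def in_parent(self) -> tuple[int, ...]:
        """Parent-group index of each operation, in the subgroup's own
        canonical operation order."""
        self.group
        return self.sorted_indices


# ---------------------------------------------------------------------------
# assembling a group from matrices


def _in_plane_basis(principal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ principal) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ principal) * principal
    u /= np.linalg.norm(u)
    return u, np.cross(principal, u)


def _principal_axis(ops: list[SymmetryOperation]) -> tuple[np.ndarray, int]:
    """Highest-order axis (proper first, improper tie-break) and its proper
    order (1 when the group has no rotation)."""
    best = None
    for op in ops:
        # ties (e.g. the three C2 of D2) resolve toward the z axis so the
        # canonical generation frame keeps its conventional orientation
        zdot = round(abs(float(op.axis[2])), 9)
        if op.kind == PROPER:
            key = (op.order, 1, zdot, tuple(np.round(op.axis, 9)))
        elif op.kind == IMPROPER:
            key = (op.order, 0, zdot, tuple(np.round(op.axis, 9)))
        else:
            continue
        if best is None or key > best[0]:
            best = (key, op)
    if best is None:
        for op in ops:
            if op.kind == MIRROR:
                return op.axis.copy(), 1
        return _Z.copy(), 1
    op = best[1]
    axis = op.axis.copy()
    n_proper = max(
        (o.order for o in ops
         if o.kind == PROPER and abs(o.axis @ axis) > 1 - 1e-6),
        default=1,
    )
    return axis, n_proper


def _classify_orientations(ops: list[SymmetryOperation],
                           principal: np.ndarray, n: int,
                           axial: bool) -> None:
    """Tag mirrors and perpendicular C2 axes as horizontal/vertical/dihedral.

    The reference azimuth is the first perpendicular C2 (or, lacking flips,
    the first vertical mirror); families alternate on the π/n azimuth grid
    when n is even, merge into one when n is odd, and off-grid mirrors
    (bisecting the C2 axes, as in Dnd) are dihedral.
    """
    if not axial:
        return
    u, v = _in_plane_basis(principal)

    def azimuth(direction: np.ndarray) -> float:
        return math.atan2(direction @ v, direction @ u) % math.pi

    flips = [op for op in ops
             if op.kind == PROPER and op.order == 2
             and abs(op.axis @ principal) < 1e-6]
    vmirrors = [op for op in ops
                if op.kind == MIRROR and abs(op.axis @ principal) < 1e-6]
    flip_az = sorted(azimuth(op.axis) for op in flips)
    mirror_az = sorted(azimuth(np.cross(op.axis, principal)) for op in vmirrors)
    beta0 = flip_az[0] if flip_az else (mirror_az[0] if mirror_az else None)
    step = math.pi / max(n, 1)

    def family(beta: float) -> int:
        if beta0 is None or n < 2:
            return 0
        offset = (beta - beta0) / step
        k = round(offset)
        if abs(offset - k) > 1e-5:
            return 2  # bisects the reference grid
        if n % 2:
            return 0  # one conjugate family under odd C_n
        return k % 2

    flip_ids = {id(f) for f in flips}
    for op in ops:
        if id(op) in flip_ids:
            op.orientation = ("vertical" if family(azimuth(op.axis)) == 0
                              else "dihedral")
        elif op.kind == MIRROR:
            dot = abs(op.axis @ principal)
            if dot > 1 - 1e-6:
                op.orientation = "horizontal"
            elif dot < 1e-6:
                f = family(azimuth(np.cross(op.axis, principal)))
                op.orientation = "vertical" if f == 0 else "dihedral"


_KIND_RANK = {IDENTITY: 0, PROPER: 1, IMPROPER: 2, MIRROR: 3, INVERSION: 5}
_MIRROR_RANK = {"horizontal": 0, "vertical": 1, "dihedral": 2, "none": 3}


def _sort_key(op: SymmetryOperation):
    axis_key = tuple(np.round(op.axis, 9))
    if op.kind == MIRROR:
        return (3, _MIRROR_RANK[op.orientation], 0, axis_key)
    if op.kind in (PROPER, IMPROPER):
        return (_KIND_RANK[op.kind], -op.order, op.power, axis_key)
    return (_KIND_RANK[op.kind], 0, 0, axis_key)


def _op_name(op: SymmetryOperation) -> str:
    if op.kind == MIRROR:
        suffix = {"horizontal": "_h", "vertical": "_v", "dihedral": "_d"}.get(
            op.orientation, "")
        return "sigma" + suffix
    if op.kind == PROPER and op.orientation == "dihedral":
        return op.name + "'"
    return op.name


def group_from_matrices(
    matrices, label: str | None = None, transform: np.ndarray | None = None
) -> PointGroup:
    """Build a fully decorated PointGroup from a closed set of matrices."""
    mats = [np.asarray(m, dtype=float) for m in matrices]
    if transform is not None:
        mats = [transform @ m @ transform.T for m in mats]
    ops = [operation_from_matrix(m) for m in mats]
    if label is None:
        from .elements import determine_point_group  # cycle-free at runtime

        label = determine_point_group(
            [op for op in ops], from_operations=True)
    family, _ = parse_label(label)
    axial = family not in POLYHEDRAL
    principal, n = _principal_axis(ops)
    _classify_orientations(ops, principal, n, axial)
    ops.sort(key=_sort_key)
    for op in ops:
        op.name = _op_name(op)

    stack = np.stack([op.matrix for op in ops])
    size = len(ops)
    table = np.empty((size, size), dtype=np.int64)
    for i in range(size):
        prods = np.einsum("ab,nbc->nac", stack[i], stack)
        d = np.abs(prods[:, None, :, :] - stack[None, :, :, :]).max(axis=(2, 3))
        idx = d.argmin(axis=1)
        if d[np.arange(size), idx].max() > 1e-6:
            raise ValueError("operation set is not closed under multiplication")
        table[i] = idx
    inverse = np.empty(size, dtype=np.int64)
    for i in range(size):
        inverse[i] = int(np.where(table[i] == 0)[0][0])

    classes = _conjugacy_classes(table, inverse)
    class_ids = np.empty(size, dtype=np.int64)
    for ci, members in enumerate(classes):
        for m in members:
            class_ids[m] = ci

    group = PointGroup(label, ops, table, classes, class_ids, inverse,
                       principal, np.eye(3) if transform is None else transform)
    for op, ci in zip(ops, class_ids):
        op.class_id = int(ci)
    group.generators = _minimal_generators(table)
    return group


def _conjugacy_classes(table: np.ndarray, inverse: np.ndarray) -> list[list[int]]:
    """Matrix-conjugation classes, merged pairwise with the inverse class so
    that complex-conjugate character pairs share a class (real convention)."""
    size = len(table)
    assigned = -np.ones(size, dtype=np.int64)
    classes: list[list[int]] = []
    for r in range(size):
        if assigned[r] >= 0:
            continue
        orbit = set()
        for g in range(size):
            orbit.add(int(table[g, table[r, inverse[g]]]))
        orbit |= {int(inverse[x]) for x in orbit}
        members = sorted(orbit)
        for m in members:
            assigned[m] = len(classes)
        classes.append(members)
    classes.sort(key=lambda c: c[0])
    return classes


def conjugacy_classes(group: PointGroup) -> list[list[int]]:
    """The group's class partition (computed at construction)."""
    return [list(c) for c in group.classes]


def classify_orientation(op: SymmetryOperation, group: PointGroup) -> str:
    """Orientation of a mirror or perpendicular C2 relative to the group
    frame (assigned during construction)."""
    return group.operations[group.op_index(op.matrix)].orientation


def _closure_indices(table: np.ndarray, seed) -> frozenset[int]:
    cur = np.unique(np.asarray(sorted(set(seed) | {0}), dtype=np.int64))
    while True:
        prods = np.unique(table[np.ix_(cur, cur)])
        if len(prods) == len(cur):
            return frozenset(int(x) for x in cur)
        cur = prods


def _minimal_generators(table: np.ndarray) -> list[int]:
    size = len(table)
    if size == 1:
        return []
    # op order = cyclic subgroup size; try high-order ops first
    cyc = {i: _closure_indices(table, [i]) for i in range(1, size)}
    cand = sorted(cyc, key=lambda i: (-len(cyc[i]), i))
    gens: list[int] = []
    current: frozenset[int] = frozenset({0})
    for i in cand:
        if i in current:
            continue
        gens.append(i)
        current = _closure_indices(table, list(current) + [i])
        if len(current) == size:
            break
    # prune redundant generators
    for g in list(gens):
        rest = [x for x in gens if x != g]
        if rest and len(_closure_indices(table, rest)) == size:
            gens = rest
    return gens


# ---------------------------------------------------------------------------
# subgroups


def _divisors(n: int) -> list[int]:
    return [d for d in range(1, n + 1) if n % d == 0]


def expected_subgroup_count(label: str) -> int | None:
    """Closed-form subgroup counts for families where they are known.

    Counts include all conjugates (subgroups are kept oriented, not merged
    up to conjugacy).
    """
    family, n = parse_label(label)
    if family == "C" and n >= 1:
        return len(_divisors(n))
    if family == "S":
        return len(_divisors(n))
    if family in ("Cs", "Ci"):
        return 2
    if family in ("D", "Cv"):
        # d(n) rotation subgroups + sum over d|n of n/d dihedral-type ones
        return len(_divisors(n)) + sum(n // d for d in _divisors(n))
    return {"T": 10, "Td": 30, "O": 30, "I": 59}.get(family)


def enumerate_subgroups(group: PointGroup, cap: int = 240) -> list[Subgroup]:
    """Exhaustive subgroup enumeration from the multiplication table.

    Every subgroup of a finite O(3) group is cyclic, dihedral or polyhedral
    and hence generated by at most two elements ... except the rank-3
    abelian D2h; iterating joins with cyclic subgroups until a fixed point
    covers every rank.
    """
    if len(group) > cap:
        raise ValueError(f"group order {len(group)} exceeds cap {cap}")
    table = group.table
    cyclic = {_closure_indices(table, [i]) for i in range(len(group))}
    known = set(cyclic) | {frozenset({0})}
    frontier = set(known)
    while frontier:
        new = set()
        for sub in frontier:
            for cyc in cyclic:
                if cyc <= sub:
                    continue
                joined = _closure_indices(table, sub | cyc)
                if joined not in known:
                    new.add(joined)
        known |= new
        frontier = new
    subs = sorted(known, key=lambda s: (len(s), sorted(s)))
    out = []
    from .elements import determine_point_group

    for s in subs:
        ops = [group.operations[i] for i in sorted(s)]
        label = determine_point_group(ops, from_operations=True)
        out.append(Subgroup(group, tuple(sorted(s)), label))
    expected = expected_subgroup_count(group.label)
    if expected is not None and len(out) != expected:
        raise RuntimeError(
            f"subgroup search found {len(out)} subgroups of {group.label}, "
            f"expected {expected}"
        )
    return out


# ---------------------------------------------------------------------------
# permutation representations


def permutation_representation(
    group: PointGroup,
    points: np.ndarray | None = None,
    tol: float = 0.05,
) -> list[Permutation]:
    """One permutation per operation.

    With ``points`` given, each operation must map every point onto a point
    within ``tol`` (bijectively); without, the left regular action of the
    group on its own operations is returned.
    """
    if points is None:
        return [Permutation(group.table[g].copy()) for g in range(len(group))]
    points = np.asarray(points, dtype=float)
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    perms = []
    for op in group.operations:
        moved = points @ op.matrix.T
        dist, idx = tree.query(moved)
        if dist.max() > tol or len(set(idx)) != len(points):
            raise ValueError(
                f"operation {op.name} does not permute the ground set "
                f"(max residual {dist.max():.3g} Å)"
            )
        perms.append(Permutation(np.asarray(idx, dtype=np.int64)))
    return perms


def generate_group_operations(
    label: str, transform: np.ndarray | None = None
) -> PointGroup:
    """All |G| operations of ``label`` as exact matrices, conjugated into
    the frame given by ``transform`` (columns = image of the canonical
    x, y, z axes)."""
    mats = canonical_matrices(label)
    g = group_from_matrices(mats, label=label, transform=transform)
    expected = group_order(label)
    if len(g) != expected:
        raise RuntimeError(
            f"generated {len(g)} operations for {label}, expected {expected}")
    return g
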
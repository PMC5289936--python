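"""Candidate symmetry-element detection from equivalence-set geometry.

Strategy: each equivalence set proposes candidate elements from its own
inertial frame — principal axes carry rotation candidates whose order is
read off ring populations (no upper bound on the order), degenerate frames
get an in-plane azimuth analysis for perpendicular C2 axes and vertical
mirrors, triply degenerate frames get the polyhedral equidistant-pair
search.  Every candidate is only kept if it actually permutes the point
set within the geometric tolerance; validation is mandatory, candidates
are cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from .geometry_io import InertialFrame, inertial_frame
from .operations import (
    IDENTITY,
    IMPROPER,
    INVERSION,
    MIRROR,
    PROPER,
    SymmetryElement,
    SymmetryOperation,
    canonical_axis,
    element_of_operation,
    improper_rotation_matrix,
    operation_from_matrix,
    reflection_matrix,
    rotation_matrix,
)

DEFAULT_TOL_GEOM = 0.05  # Å; an operation matches if every atom maps this close


class InconsistentElementsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# validation


def _permutes(matrix: np.ndarray, points: np.ndarray, tree: cKDTree,
              tol: float) -> bool:
    moved = points @ matrix.T
    dist, idx = tree.query(moved, distance_upper_bound=max(tol * 4, 1e-6))
    if not np.all(np.isfinite(dist)) or dist.max() > tol:
        return False
    return len(np.unique(idx)) == len(points)


def element_generator_matrix(elem: SymmetryElement) -> np.ndarray:
    """The single generating matrix of an element (validating the generator
    validates every power)."""
    a = elem.axis_vector
    if elem.kind == IDENTITY:
        return np.eye(3)
    if elem.kind == INVERSION:
        return -np.eye(3)
    if elem.kind == MIRROR:
        return reflection_matrix(a)
    if elem.kind == PROPER:
        n = elem.order if elem.order else 2
        return rotation_matrix(a, 2 * math.pi / n)
    return improper_rotation_matrix(a, 2 * math.pi / elem.order)


def validate_element(
    elem: SymmetryElement,
    point_sets: list[np.ndarray],
    tol: float = DEFAULT_TOL_GEOM,
    trees: list[cKDTree] | None = None,
) -> bool:
    """True when the element's generator permutes every point set."""
    if trees is None:
        trees = [cKDTree(p) for p in point_sets]
    m = element_generator_matrix(elem)
    return all(_permutes(m, p, t, tol) for p, t in zip(point_sets, trees))


# ---------------------------------------------------------------------------
# per-set candidate generation


def _divisors_desc(n: int) -> list[int]:
    return [d for d in range(n, 1, -1) if n % d == 0]


def _ring_sizes(points: np.ndarray, axis: np.ndarray, width: float) -> list[int]:
    """Populations of the (height, radius) rings about ``axis``; on-axis
    points are excluded."""
    z = points @ axis
    r = np.linalg.norm(points - np.outer(z, axis), axis=1)
    off = r > width
    if not np.any(off):
        return []
    keys = np.stack([z[off], r[off]], axis=1)
    order = np.lexsort((keys[:, 1], keys[:, 0]))
    keys = keys[order]
    sizes = []
    count = 1
    for prev, cur in zip(keys[:-1], keys[1:]):
        if np.abs(cur - prev).max() <= width:
            count += 1
        else:
            sizes.append(count)
            count = 1
    sizes.append(count)
    return sizes


def _dedupe(elements: list[SymmetryElement],
            angle_tol: float = 2e-3) -> list[SymmetryElement]:
    """Drop repeated elements; axes closer than ``angle_tol`` radians with
    equal kind and order count as the same element (first occurrence wins,
    so the earliest — typically most accurate — candidate survives)."""
    cos_tol = math.cos(angle_tol)
    kept: list[SymmetryElement] = []
    for e in elements:
        dup = False
        for k in kept:
            if k.kind != e.kind or k.order != e.order:
                continue
            if e.kind in (INVERSION, IDENTITY):
                dup = True
                break
            if abs(float(k.axis_vector @ e.axis_vector)) >= cos_tol:
                dup = True
                break
        if not dup:
            kept.append(e)
    return kept


def _axis_candidates_for_direction(
    points: np.ndarray, axis: np.ndarray, tol: float
) -> list[SymmetryElement]:
    """Rotation/improper/mirror candidates about one direction."""
    cands = [SymmetryElement.make(MIRROR, axis)]
    sizes = _ring_sizes(points, axis, tol)
    if sizes:
        g = 0
        for s in sizes:
            g = math.gcd(g, s)
        for n in _divisors_desc(g):
            cands.append(SymmetryElement.make(PROPER, axis, n))
        for n in _divisors_desc(2 * g):
            if n >= 3:  # S2 is the inversion, handled separately
                cands.append(SymmetryElement.make(IMPROPER, axis, n))
    return cands


def _in_plane_candidates(
    points: np.ndarray, axis: np.ndarray, tol: float
) -> list[SymmetryElement]:
    """Perpendicular C2 and vertical-mirror candidates: directions of the
    projected set members and their pairwise bisectors."""
    z = points @ axis
    w = points - np.outer(z, axis)
    r = np.linalg.norm(w, axis=1)
    off = r > tol
    if not np.any(off):
        return []
    dirs = w[off] / r[off][:, None]
    az = np.arctan2(dirs @ _perp(axis, 1), dirs @ _perp(axis, 0)) % math.pi
    unique_az = _merge_close(np.sort(az), 1e-9)
    angles = list(unique_az)
    for b1, b2 in combinations(unique_az, 2):
        angles.append((b1 + b2) / 2.0)
        angles.append(((b1 + b2) / 2.0 + math.pi / 2) % math.pi)
    angles = _merge_close(np.sort(np.asarray(angles)), 1e-9)
    u0, u1 = _perp(axis, 0), _perp(axis, 1)
    out = []
    for beta in angles:
        d = math.cos(beta) * u0 + math.sin(beta) * u1
        out.append(SymmetryElement.make(PROPER, d, 2))
        out.append(SymmetryElement.make(MIRROR, np.cross(axis, d)))
    return out


def _merge_close(sorted_values: np.ndarray, tol: float) -> list[float]:
    out: list[float] = []
    for v in sorted_values:
        if not out or v - out[-1] > tol:
            out.append(float(v))
    return out


def _perp(axis: np.ndarray, which: int) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ axis) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ axis) * axis
    u /= np.linalg.norm(u)
    return u if which == 0 else np.cross(axis, u)


def detect_elements_for_set(
    points: np.ndarray,
    frame: InertialFrame | None = None,
    tol: float = DEFAULT_TOL_GEOM,
    deg_tol: float = 0.02,
) -> list[SymmetryElement]:
    """Validated symmetry elements of one equivalence set (centred on the
    molecular centre of mass, which need not be the set centroid).

    A C∞ element (order 0) is emitted for collinear sets; singleton sets
    return no constraints (they restrict other sets' candidates only
    through global validation).
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return []
    if frame is None:
        frame = inertial_frame(points, np.ones(len(points)),
                               deg_tol=deg_tol, lin_tol=max(1e-8, (tol / 4) ** 2))
    tree = cKDTree(points)

    def ok(elem: SymmetryElement) -> bool:
        return _permutes(element_generator_matrix(elem), points, tree, tol)

    found: list[SymmetryElement] = []
    inv = SymmetryElement.make(INVERSION)
    if ok(inv):
        found.append(inv)

    if frame.kind == "linear":
        axis = canonical_axis(frame.unique_axis)
        found.append(SymmetryElement.make(PROPER, axis, 0))
        sig = SymmetryElement.make(MIRROR, axis)
        if ok(sig):
            found.append(sig)
        return _dedupe(found)

    cands: list[SymmetryElement] = []
    top = frame.moments[2]
    for i in range(3):
        axis = canonical_axis(frame.axes[:, i])
        cands.extend(_axis_candidates_for_direction(points, axis, tol))
        others = [frame.moments[j] for j in range(3) if j != i]
        if abs(others[0] - others[1]) <= deg_tol * top:
            cands.extend(_in_plane_candidates(points, axis, tol))
    if frame.kind == "spherical":
        return _dedupe(found + detect_polyhedral(points, frame, tol))

    for c in _dedupe(cands):
        if ok(c):
            found.append(c)
    return _dedupe(found)


def detect_polyhedral(
    points: np.ndarray,
    frame: InertialFrame | None = None,
    tol: float = DEFAULT_TOL_GEOM,
) -> list[SymmetryElement]:
    """Polyhedral-group element search for a triply degenerate set.

    σ, C2 (upgraded to C4 where valid) candidates come from equidistant
    point pairs; higher-order axes are implied, either as products of the
    found operations or — for the tetrahedral C3 case — from the angle
    relations of the three mutually perpendicular C2 axes, and validated.
    """
    points = np.asarray(points, dtype=float)
    if frame is None:
        frame = inertial_frame(points, np.ones(len(points)), deg_tol=0.02)
    if frame.kind != "spherical":
        raise ValueError("polyhedral search requires a spherical inertial frame")
    tree = cKDTree(points)

    def ok(elem: SymmetryElement) -> bool:
        return _permutes(element_generator_matrix(elem), points, tree, tol)

    cands: list[SymmetryElement] = []
    for i, j in combinations(range(len(points)), 2):
        s = points[i] + points[j]
        d = points[i] - points[j]
        if np.linalg.norm(s) > tol:
            cands.append(SymmetryElement.make(PROPER, s, 2))
        if np.linalg.norm(d) > tol:
            cands.append(SymmetryElement.make(MIRROR, d))
    # vertex directions can carry any order up to 5
    for p in points:
        for n in (5, 4, 3, 2):
            cands.append(SymmetryElement.make(PROPER, p, n))
    validated: list[SymmetryElement] = []
    for c in _dedupe(cands):
        if ok(c):
            validated.append(c)
    inv = SymmetryElement.make(INVERSION)
    if ok(inv):
        validated.append(inv)
    # C4 upgrades on validated C2 axes
    for e in list(validated):
        if e.kind == PROPER and e.order == 2:
            up = SymmetryElement.make(PROPER, e.axis_vector, 4)
            if ok(up):
                validated.append(up)
    validated = _dedupe(validated)

    # implied elements: close the found operations under products (products
    # of approximately valid operations drift, so they are re-validated)
    elems = _element_closure(validated, ok)
    # tetrahedral case: C3 axes are the diagonals of the C2 frame
    if not any(e.kind == PROPER and e.order >= 3 for e in elems):
        c2 = [e.axis_vector for e in elems if e.kind == PROPER and e.order == 2]
        if len(c2) == 3:
            for s1, s2 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                diag = c2[0] + s1 * c2[1] + s2 * c2[2]
                cand = SymmetryElement.make(PROPER, diag, 3)
                if ok(cand):
                    elems.append(cand)
            elems = _element_closure(elems, ok)
    return _dedupe(elems)


def _element_closure(elements: list[SymmetryElement], validator,
                     cap: int = 130) -> list[SymmetryElement]:
    """Elements generated by products of the given elements' operations,
    each kept only if ``validator`` accepts it."""
    mats = [np.eye(3)]
    out: list[SymmetryElement] = []

    def add(m: np.ndarray) -> SymmetryElement | None:
        if min(np.abs(np.stack(mats) - m).max(axis=(1, 2))) < 1e-6:
            return None
        try:
            elem = element_of_operation(operation_from_matrix(m))
        except ValueError:
            return None  # drifted to a near-identity / unclassifiable product
        if not validator(elem):
            return None
        mats.append(m)
        out.append(elem)
        return elem

    frontier = []
    for e in elements:
        if add(element_generator_matrix(e)) is not None:
            frontier.append(mats[-1])
    while frontier and len(mats) <= cap:
        m = frontier.pop()
        for g in list(mats):
            for prod in (g @ m, m @ g):
                if add(prod) is not None:
                    frontier.append(mats[-1])
    return _dedupe(out)


# ---------------------------------------------------------------------------
# intersection across sets


def _same_axis(a: SymmetryElement, b: SymmetryElement, angle_tol: float) -> bool:
    return abs(float(a.axis_vector @ b.axis_vector)) >= math.cos(angle_tol)


def intersect_element_sets(
    per_set_elements: list[list[SymmetryElement]],
    angle_tol: float = 2e-3,
) -> list[SymmetryElement]:
    """Keep elements present in every per-set list.

    Axis orders reconcile through their gcd; a C∞ (order 0) intersected
    with a finite order yields the finite order, so a linear set never
    blocks the finite rotations proposed by the others.
    """
    if not per_set_elements:
        return []
    result = list(per_set_elements[0])
    for other in per_set_elements[1:]:
        merged = []
        for e in result:
            for o in other:
                if e.kind != o.kind:
                    continue
                if e.kind in (INVERSION, IDENTITY):
                    merged.append(e)
                    break
                if not _same_axis(e, o, angle_tol):
                    continue
                if e.kind == MIRROR:
                    merged.append(e)
                    break
                if e.order == 0 and o.order == 0:
                    merged.append(e)
                    break
                if e.order == 0:
                    merged.append(SymmetryElement.make(e.kind, o.axis_vector, o.order))
                    break
                if o.order == 0:
                    merged.append(e)
                    break
                g = math.gcd(e.order, o.order)
                if g >= 2:
                    merged.append(
                        e if g == e.order
                        else SymmetryElement.make(e.kind, e.axis_vector, g))
                    break
        result = _dedupe(merged)
    return result


# ---------------------------------------------------------------------------
# Schoenflies decision tree


def determine_point_group(
    items,
    from_operations: bool = False,
    angle_tol: float = 0.02,
) -> str:
    """Schoenflies label from a validated element list.

    Follows the standard decision procedure (linear → polyhedral →
    dihedral/cyclic discrimination), with the relaxation that a single
    perpendicular C2 or single vertical mirror suffices, the rest being
    implied.  ``from_operations`` accepts SymmetryOperation lists (as in
    subgroup labelling).
    """
    elements: list[SymmetryElement] = []
    if from_operations:
        for op in items:
            if isinstance(op, SymmetryOperation):
                if op.kind != IDENTITY:
                    elements.append(element_of_operation(op))
        elements = _dedupe(elements)
    else:
        elements = _dedupe(list(items))

    cos_par = math.cos(angle_tol)
    proper: dict[tuple, int] = {}
    proper_axes: list[tuple[np.ndarray, int]] = []
    improper_axes: list[tuple[np.ndarray, int]] = []
    mirrors: list[np.ndarray] = []
    inversion = False
    has_inf = False
    for e in elements:
        if e.kind == PROPER:
            if e.order == 0:
                has_inf = True
                proper_axes.append((e.axis_vector, 0))
                continue
            merged = False
            for idx, (ax, n) in enumerate(proper_axes):
                if abs(ax @ e.axis_vector) >= cos_par:
                    proper_axes[idx] = (ax, max(n, e.order) if n else 0)
                    merged = True
                    break
            if not merged:
                proper_axes.append((e.axis_vector, e.order))
        elif e.kind == IMPROPER:
            improper_axes.append((e.axis_vector, e.order))
        elif e.kind == MIRROR:
            mirrors.append(e.axis_vector)
        elif e.kind == INVERSION:
            inversion = True

    if has_inf:
        return "Dinfh" if inversion else "Cinfv"

    high = [(ax, n) for ax, n in proper_axes if n >= 3]
    if len(high) >= 2:
        orders = [n for _, n in high]
        if max(orders) >= 5:
            return "Ih" if inversion else "I"
        if max(orders) >= 4:
            return "Oh" if inversion else "O"
        if inversion:
            return "Th"
        return "Td" if mirrors else "T"

    finite = [(ax, n) for ax, n in proper_axes if n >= 2]
    if finite:
        finite.sort(key=lambda t: (-t[1], tuple(np.round(t[0], 9))))
        principal, n = finite[0]
        flips = [ax for ax, m in finite[1:]
                 if m == 2 and abs(ax @ principal) < angle_tol]
        sigma_h = any(abs(nm @ principal) >= cos_par for nm in mirrors)
        sigma_v = any(abs(nm @ principal) < angle_tol for nm in mirrors)
        if flips:
            if sigma_h:
                return f"D{n}h"
            return f"D{n}d" if sigma_v else f"D{n}"
        if sigma_h:
            return f"C{n}h"
        if sigma_v:
            return f"C{n}v"
        for ax, m in improper_axes:
            if m == 2 * n and abs(ax @ principal) >= cos_par:
                return f"S{2 * n}"
        return f"C{n}"

    if mirrors:
        return "Cs"
    return "Ci" if inversion else "C1"


# ---------------------------------------------------------------------------
# symmetrisation / alignment of detected elements


@dataclass
class Alignment:
    elements: list[SymmetryElement]
    transform: np.ndarray
    residual: float


def _element_axes(elements) -> list[tuple[str, int, np.ndarray]]:
    out = []
    for e in elements:
        if e.kind in (PROPER, IMPROPER, MIRROR):
            out.append((e.kind, e.order, e.axis_vector))
    return out


def _frame_from_pair(p: np.ndarray, s: np.ndarray) -> np.ndarray | None:
    w = p / np.linalg.norm(p)
    u = s - (s @ w) * w
    nu = np.linalg.norm(u)
    if nu < 1e-6:
        return None
    u = u / nu
    return np.stack([u, np.cross(w, u), w], axis=1)


def symmetrize_and_align(
    detected: list[SymmetryElement],
    label: str,
    point_sets: list[np.ndarray] | None = None,
    tol: float = DEFAULT_TOL_GEOM,
    angle_window: float = 0.2,
    max_residual: float = 0.1,
) -> Alignment:
    """Replace detected elements by the exact ideal element geometry of
    ``label``, aligned to the detection by an orthogonal transform.

    A provisional rotation is built from a primary/secondary axis match and
    screened (against the molecule's point sets when given, else against
    the detected axes), then refined by an orthogonal Procrustes fit over
    all matched axis pairs.  Raises when no alignment reproduces the
    detected elements within ``max_residual`` radians.
    """
    from .point_group import generate_group_operations

    ideal_group = generate_group_operations(label)
    ideal_elems = _dedupe(
        [element_of_operation(op) for op in ideal_group.operations
         if op.kind != IDENTITY]
    )
    det_axes = _element_axes(detected)
    ide_axes = _element_axes(ideal_elems)
    if not ide_axes:  # C1 / Ci
        return Alignment(ideal_elems, np.eye(3), 0.0)

    trees = [cKDTree(p) for p in point_sets] if point_sets is not None else None

    def screen(t: np.ndarray) -> bool:
        if point_sets is None:
            for kind, order, axis in ide_axes:
                tx = t @ axis
                if not any(k == kind and o == order
                           and abs(tx @ ax) >= math.cos(angle_window)
                           for k, o, ax in det_axes):
                    return False
            return True
        for op in ideal_group.operations:
            m = t @ op.matrix @ t.T
            if not all(_permutes(m, p, tr, tol)
                       for p, tr in zip(point_sets, trees)):
                return False
        return True

    # choose the primary axis class: highest proper order, improper, mirror
    def class_key(item):
        kind, order, _ = item
        rank = {PROPER: 2, IMPROPER: 1, MIRROR: 0}[kind]
        return (rank, order)

    primary_i = max(ide_axes, key=class_key)
    p_kind, p_order, p_axis = primary_i
    det_primary = [ax for k, o, ax in det_axes if k == p_kind and o == p_order]
    if not det_primary:
        raise InconsistentElementsError(
            f"detected elements lack the principal {p_kind} of {label}")

    secondary = [
        (k, o, ax) for k, o, ax in ide_axes
        if abs(ax @ p_axis) < 1 - 1e-9
    ]
    candidates: list[np.ndarray] = []
    if secondary:
        s_kind, s_order, s_axis = max(secondary, key=class_key)
        gamma = abs(float(s_axis @ p_axis))
        bi = _frame_from_pair(p_axis, s_axis)
        det_secondary = [ax for k, o, ax in det_axes
                         if k == s_kind and o == s_order]
        for dp in det_primary:
            for sp_p in (dp, -dp):
                for ds in det_secondary:
                    for sp_s in (ds, -ds):
                        if abs(abs(float(sp_s @ sp_p)) - gamma) > angle_window:
                            continue
                        if float(sp_s @ sp_p) * float(s_axis @ p_axis) < 0 and gamma > 1e-9:
                            continue
                        bd = _frame_from_pair(sp_p, sp_s)
                        if bd is None:
                            continue
                        candidates.append(bd @ bi.T)
    else:
        for dp in det_primary:
            for sp in (dp, -dp):
                v = np.cross(p_axis, sp)
                s = np.linalg.norm(v)
                c = float(p_axis @ sp)
                if s < 1e-12:
                    candidates.append(np.eye(3) if c > 0
                                      else rotation_matrix(_any_perp(p_axis), math.pi))
                else:
                    candidates.append(rotation_matrix(v / s, math.atan2(s, c)))

    chosen = None
    for t in candidates:
        if screen(t):
            chosen = t
            break
    if chosen is None:
        raise InconsistentElementsError(
            f"no orthogonal alignment reproduces the detected elements of {label}")

    # Procrustes refinement over all matched axis pairs
    m = np.zeros((3, 3))
    for kind, order, axis in ide_axes:
        tx = chosen @ axis
        best = None
        for k, o, ax in det_axes:
            if k != kind or o != order:
                continue
            d = float(tx @ ax)
            if best is None or abs(d) > abs(best[0]):
                best = (d, ax)
        if best is not None and abs(best[0]) >= math.cos(angle_window):
            sign = 1.0 if best[0] >= 0 else -1.0
            m += np.outer(sign * best[1], axis)
    if np.linalg.norm(m) > 1e-12:
        u, _, vt = np.linalg.svd(m)
        d = np.sign(np.linalg.det(u @ vt))
        refined = u @ np.diag([1.0, 1.0, d]) @ vt
        if screen(refined):
            chosen = refined

    residual = 0.0
    for kind, order, axis in ide_axes:
        tx = chosen @ axis
        best = None
        for k, o, ax in det_axes:
            if k != kind or o != order:
                continue
            d = abs(float(tx @ ax))
            if best is None or d > abs(float(tx @ best)):
                best = ax
        if best is not None:
            sgn = 1.0 if float(tx @ best) >= 0 else -1.0
            ang = math.atan2(float(np.linalg.norm(np.cross(tx, sgn * best))),
                             abs(float(tx @ best)))
            residual = max(residual, ang)
    if residual > max_residual:
        raise InconsistentElementsError(
            f"alignment residual {residual:.3g} rad exceeds {max_residual}")

    aligned = [
        SymmetryElement.make(e.kind, chosen @ e.axis_vector, e.order)
        if e.kind in (PROPER, IMPROPER, MIRROR) else e
        for e in ideal_elems
    ]
    return Alignment(aligned, chosen, residual)


def _any_perp(a: np.ndarray) -> np.ndarray:
    return _perp(a, 0)
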
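"""End-to-end point-group detection for a molecule.

Wires the stages together: equivalence-set partitioning, per-set element
candidates, global validation (an element must permute *every* set),
Schoenflies classification, and alignment of the exact ideal group onto
the detected frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .equivalence import EquivalenceSet, equivalence_sets
from .geometry_io import Molecule, inertial_frame
from .operations import (
    INVERSION,
    MIRROR,
    PROPER,
    SymmetryElement,
    canonical_axis,
)
from .elements import (
    DEFAULT_TOL_GEOM,
    _dedupe,
    _permutes,
    detect_elements_for_set,
    element_generator_matrix,
    symmetrize_and_align,
)
from .point_group import PointGroup, generate_group_operations


@dataclass
class Detection:
    """Result of point-group detection.

    ``group`` carries the exact aligned operations (None for the infinite
    linear groups, which have no finite operation list; SALC construction
    substitutes a surrogate there).
    """

    label: str
    group: PointGroup | None
    sets: list[EquivalenceSet]
    elements: list[SymmetryElement]
    transform: np.ndarray
    residual: float = 0.0


def detect(
    mol: Molecule,
    tol: float = DEFAULT_TOL_GEOM,
    rel_tol: float = 1e-3,
    deg_tol: float = 0.02,
) -> Detection:
    """Detect the molecular point group.

    ``tol`` (Å) is the geometric matching tolerance, ``rel_tol`` the
    relative clustering tolerance for equivalence sets and ``deg_tol`` the
    relative moment-degeneracy tolerance.
    """
    mol = mol.recentered()
    # near-symmetric coordinates perturb the invariants by roughly the
    # geometric tolerance over the molecular size; the clustering tolerance
    # must cover that or noise splinters the orbits (merging two true
    # orbits is harmless — validation only requires each set be permuted)
    r_rms = float(np.sqrt((mol.positions**2).sum(axis=1).mean()))
    rel_eff = max(rel_tol, min(0.1, 2.0 * tol / max(r_rms, 1e-6)))
    sets = equivalence_sets(mol, rel_eff)
    pos = mol.positions
    point_sets = [pos[list(s.indices)] for s in sets]
    trees = [cKDTree(p) for p in point_sets]

    def valid(elem: SymmetryElement) -> bool:
        m = element_generator_matrix(elem)
        return all(_permutes(m, p, t, tol) for p, t in zip(point_sets, trees))

    # linear molecule: every atom on one line through the centre of mass
    mol_frame = inertial_frame(pos, mol.masses, deg_tol=deg_tol,
                               lin_tol=max(1e-10, (tol / 4) ** 2))
    if len(mol) == 1:
        return Detection("spherical", None, sets, [], np.eye(3))
    if mol_frame.kind == "linear":
        axis = canonical_axis(mol_frame.unique_axis)
        elements = [SymmetryElement.make(PROPER, axis, 0)]
        inv = SymmetryElement.make(INVERSION)
        label = "Cinfv"
        if valid(inv):
            elements += [inv, SymmetryElement.make(MIRROR, axis)]
            label = "Dinfh"
        transform = _axis_to_z_transform(axis)
        return Detection(label, None, sets, elements, transform)

    candidates: list[SymmetryElement] = []
    for s, pts in zip(sets, point_sets):
        if len(pts) >= 2:
            candidates.extend(
                detect_elements_for_set(pts, tol=tol, deg_tol=deg_tol))
    # molecule-level candidates cover all-singleton cases (at most Cs there)
    candidates.append(SymmetryElement.make(INVERSION))
    for i in range(3):
        axis = canonical_axis(mol_frame.axes[:, i])
        candidates.append(SymmetryElement.make(MIRROR, axis))
        candidates.append(SymmetryElement.make(PROPER, axis, 2))

    elements = [e for e in _dedupe(candidates)
                if e.order != 0 and valid(e)]
    from .elements import determine_point_group

    label = determine_point_group(elements)
    alignment = symmetrize_and_align(elements, label,
                                     point_sets=point_sets, tol=tol)
    group = generate_group_operations(label, alignment.transform)
    return Detection(label, group, sets, alignment.elements,
                     alignment.transform, alignment.residual)


def _axis_to_z_transform(axis: np.ndarray) -> np.ndarray:
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    s = float(np.linalg.norm(v))
    c = float(z @ axis)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    from .operations import rotation_matrix
    import math

    return rotation_matrix(v / s, math.atan2(s, c))
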
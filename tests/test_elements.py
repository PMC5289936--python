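import math

import numpy as np
import pytest

from symadapt.elements import (
    InconsistentElementsError,
    detect_elements_for_set,
    detect_polyhedral,
    intersect_element_sets,
    symmetrize_and_align,
    validate_element,
)
from symadapt.operations import (
    INVERSION,
    MIRROR,
    PROPER,
    SymmetryElement,
    rotation_matrix,
)

Z = np.array([0.0, 0.0, 1.0])


def ring(n, radius=1.0, z=0.0, offset=0.0):
    return np.array([
        [radius * math.cos(2 * math.pi * k / n + offset),
         radius * math.sin(2 * math.pi * k / n + offset), z]
        for k in range(n)
    ])


def count(elements, kind, order=None):
    return sum(1 for e in elements
               if e.kind == kind and (order is None or e.order == order))


class TestAxialDetection:
    def test_linear_pair(self):
        pts = np.array([[0.0, 0, 1.0], [0.0, 0, -1.0]])
        els = detect_elements_for_set(pts)
        kinds = {e.kind for e in els}
        assert kinds == {PROPER, MIRROR, INVERSION}
        assert any(e.kind == PROPER and e.order == 0 for e in els)  # C∞

    def test_regular_pentagon(self):
        els = detect_elements_for_set(ring(5))
        assert count(els, PROPER, 5) == 1
        assert count(els, PROPER, 2) == 5        # in-plane C2
        assert count(els, MIRROR) == 6           # 5 σ_v + σ_h

    @pytest.mark.parametrize("n", [3, 5, 8, 13, 21, 34, 47, 50])
    def test_prism_order_inference_is_unbounded(self, n):
        # two eclipsed rings: principal order must be exactly n with no
        # search-field ceiling
        pts = np.vstack([ring(n, z=0.8), ring(n, z=-0.8)])
        els = detect_elements_for_set(pts)
        orders = [e.order for e in els if e.kind == PROPER
                  and abs(abs(e.axis_vector @ Z) - 1) < 1e-9]
        assert max(orders) == n

    def test_every_element_permutes_the_set(self):
        pts = np.vstack([ring(4, z=0.5), ring(4, z=-0.5, offset=math.pi / 4)])
        for e in detect_elements_for_set(pts):
            assert validate_element(e, [pts])


class TestPolyhedralDetection:
    def test_tetrahedron(self):
        pts = np.array([[1.0, 1, 1], [1, -1, -1], [-1, 1, -1],
                        [-1, -1, 1]]) / math.sqrt(3)
        els = detect_polyhedral(pts)
        assert count(els, PROPER, 3) == 4
        assert count(els, PROPER, 2) == 3
        assert count(els, MIRROR) == 6
        assert count(els, "improper_axis", 4) == 3

    def test_octahedron(self):
        pts = np.array([[1.0, 0, 0], [-1, 0, 0], [0, 1, 0],
                        [0, -1, 0], [0, 0, 1], [0, 0, -1]])
        els = detect_polyhedral(pts)
        assert count(els, PROPER, 4) == 3
        assert count(els, PROPER, 3) == 4
        assert count(els, MIRROR) == 9
        assert count(els, INVERSION) == 1

    def test_icosahedron_c5_axes_via_implied_generation(self):
        phi = (1 + math.sqrt(5)) / 2
        pts = []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            for s1 in (1, -1):
                for s2 in (1, -1):
                    v = np.zeros(3)
                    v[a] = s1
                    v[b] = s2 * phi
                    pts.append(v)
        pts = np.array(pts) / math.sqrt(1 + phi * phi)
        els = detect_polyhedral(pts)
        assert count(els, PROPER, 5) == 6
        assert count(els, PROPER, 3) == 10
        assert count(els, PROPER, 2) == 15

    def test_non_spherical_frame_rejected(self):
        with pytest.raises(ValueError):
            detect_polyhedral(ring(6))


class TestIntersection:
    def test_identical_lists_unchanged(self):
        els = [SymmetryElement.make(PROPER, Z, 4),
               SymmetryElement.make(MIRROR, np.array([1.0, 0, 0]))]
        assert intersect_element_sets([els, list(els)]) == els

    def test_infinite_order_reduces_to_finite(self):
        inf = [SymmetryElement.make(PROPER, Z, 0)]
        five = [SymmetryElement.make(PROPER, Z, 5)]
        out = intersect_element_sets([inf, five])
        assert [(e.kind, e.order) for e in out] == [(PROPER, 5)]

    def test_orders_reconcile_through_gcd(self):
        a = [SymmetryElement.make(PROPER, Z, 6)]
        b = [SymmetryElement.make(PROPER, Z, 4)]
        out = intersect_element_sets([a, b])
        assert [e.order for e in out] == [2]

    def test_disjoint_axes_keep_only_shared_elements(self):
        a = [SymmetryElement.make(PROPER, Z, 3),
             SymmetryElement.make(INVERSION)]
        b = [SymmetryElement.make(PROPER, np.array([1.0, 0, 0]), 3),
             SymmetryElement.make(INVERSION)]
        out = intersect_element_sets([a, b])
        assert [(e.kind) for e in out] == [INVERSION]


class TestAlignment:
    def test_ideal_elements_give_identity_transform(self):
        els = detect_elements_for_set(ring(3, z=0.0))
        res = symmetrize_and_align(els, "D3h")
        assert res.residual < 1e-10
        np.testing.assert_allclose(res.transform @ res.transform.T,
                                   np.eye(3), atol=1e-12)

    def test_tilted_axis_recovered_to_exact_relations(self):
        tilt = rotation_matrix(np.array([1.0, 0.2, 0]), 1e-4)
        els = [
            SymmetryElement.make(PROPER, tilt @ Z, 3),
            SymmetryElement.make(MIRROR, np.array([0.0, 1.0, 0.0])),
            SymmetryElement.make(
                MIRROR, rotation_matrix(Z, math.pi / 3) @ np.array([0.0, 1, 0])),
            SymmetryElement.make(
                MIRROR, rotation_matrix(Z, -math.pi / 3) @ np.array([0.0, 1, 0])),
        ]
        res = symmetrize_and_align(els, "C3v")
        axes = [e.axis_vector for e in res.elements
                if e.kind == PROPER and e.order == 3]
        normals = [e.axis_vector for e in res.elements if e.kind == MIRROR]
        for nm in normals:
            assert abs(nm @ axes[0]) < 1e-12  # exact verticality restored

    def test_alignment_is_idempotent(self):
        els = detect_elements_for_set(ring(4))
        first = symmetrize_and_align(els, "D4h")
        second = symmetrize_and_align(first.elements, "D4h")
        ax1 = sorted(tuple(np.round(e.axis, 8)) for e in first.elements)
        ax2 = sorted(tuple(np.round(e.axis, 8)) for e in second.elements)
        assert ax1 == ax2

    def test_inconsistent_elements_raise(self):
        els = [SymmetryElement.make(PROPER, Z, 3)]
        with pytest.raises(InconsistentElementsError):
            symmetrize_and_align(els, "Oh")

    def test_group_closure_after_alignment(self, ammonia):
        from symadapt.pipeline import detect

        det = detect(ammonia)
        mats = det.group.matrices()
        for a in mats:
            for b in mats:
                prod = a @ b
                assert min(np.abs(mats - prod).max(axis=(1, 2))) < 1e-10
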
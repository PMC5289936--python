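import numpy as np
import pytest

from symadapt.elements import determine_point_group
from symadapt.operations import (
    INVERSION,
    MIRROR,
    PROPER,
    SymmetryElement,
    operation_from_matrix,
    rotation_matrix,
)
from symadapt.point_group import (
    enumerate_subgroups,
    expected_subgroup_count,
    generate_group_operations,
    group_order,
    permutation_representation,
)

Z = np.array([0.0, 0.0, 1.0])


class TestDetermineLabel:
    def test_no_elements_is_c1(self):
        assert determine_point_group([]) == "C1"

    def test_inversion_only_is_ci(self):
        assert determine_point_group(
            [SymmetryElement.make(INVERSION)]) == "Ci"

    def test_c3_plus_one_vertical_mirror_is_c3v(self):
        elems = [
            SymmetryElement.make(PROPER, Z, 3),
            SymmetryElement.make(MIRROR, np.array([0.0, 1.0, 0.0])),
        ]
        assert determine_point_group(elems) == "C3v"

    def test_single_perpendicular_c2_suffices_for_d_family(self):
        elems = [
            SymmetryElement.make(PROPER, Z, 5),
            SymmetryElement.make(PROPER, np.array([1.0, 0, 0]), 2),
        ]
        assert determine_point_group(elems) == "D5"


class TestGroupGeneration:
    @pytest.mark.parametrize("label", [
        "C1", "Cs", "Ci", "C2", "C7", "C3v", "C6h", "S4", "S10",
        "D2", "D5", "D6h", "D4d", "T", "Td", "Th", "O", "Oh", "I", "Ih",
    ])
    def test_order_and_closure(self, label):
        g = generate_group_operations(label)
        assert len(g) == group_order(label)
        # closure and unique inverse are table properties
        assert sorted(set(g.table.ravel().tolist())) == list(range(len(g)))
        assert (g.table[np.arange(len(g)), g.inverse] == 0).all()

    def test_c3v_has_the_six_textbook_operations(self):
        g = generate_group_operations("C3v")
        names = [op.name for op in g.operations]
        assert names[0] == "E"
        assert sum(n.startswith("C3") for n in names) == 2
        assert sum(n.startswith("sigma") for n in names) == 3

    def test_operation_matrices_are_orthogonal_with_correct_determinant(self):
        for label in ("D3d", "Oh"):
            for op in generate_group_operations(label).operations:
                m = op.matrix
                assert np.abs(m @ m.T - np.eye(3)).max() < 1e-12
                want = -1.0 if op.kind in ("mirror_plane", "improper_axis",
                                           "inversion_centre") else 1.0
                assert np.linalg.det(m) == pytest.approx(want)

    def test_odd_s_labels_rejected(self):
        with pytest.raises(ValueError):
            generate_group_operations("S3")
        with pytest.raises(ValueError):
            generate_group_operations("S2")


class TestClasses:
    def test_c2v_all_singleton_classes(self):
        g = generate_group_operations("C2v")
        assert [len(c) for c in g.classes] == [1, 1, 1, 1]

    def test_c3v_three_classes(self):
        g = generate_group_operations("C3v")
        assert sorted(len(c) for c in g.classes) == [1, 2, 3]

    def test_c3_inverse_pair_merged(self):
        g = generate_group_operations("C3")
        assert sorted(len(c) for c in g.classes) == [1, 2]

    def test_class_sizes_divide_group_order(self):
        for label in ("D4h", "Td", "I"):
            g = generate_group_operations(label)
            assert sum(len(c) for c in g.classes) == len(g)
            assert all(len(g) % len(c) == 0 for c in g.classes)


class TestOrientations:
    def test_sigma_h_is_horizontal(self):
        g = generate_group_operations("C3h")
        mirrors = [op for op in g.operations if op.kind == MIRROR]
        assert [m.orientation for m in mirrors] == ["horizontal"]

    def test_c3v_mirrors_vertical(self):
        g = generate_group_operations("C3v")
        assert all(op.orientation == "vertical"
                   for op in g.operations if op.kind == MIRROR)

    def test_d4h_has_two_distinct_perpendicular_c2_families(self):
        g = generate_group_operations("D4h")
        flips = [op for op in g.operations
                 if op.kind == PROPER and op.order == 2
                 and abs(op.axis @ Z) < 1e-9]
        tags = sorted(op.orientation for op in flips)
        assert tags == ["dihedral", "dihedral", "vertical", "vertical"]

    def test_dnd_mirrors_are_dihedral(self):
        g = generate_group_operations("D3d")
        assert all(op.orientation == "dihedral"
                   for op in g.operations if op.kind == MIRROR)


class TestPermutations:
    def test_regular_action_of_c3v_reproduces_published_cycles(self):
        # canonical order: E, C3, C3^2, sigma, sigma', sigma''
        g = generate_group_operations("C3v")
        perms = permutation_representation(g)
        by_cycles = [sorted(p.cycles(keep_fixed=False)) for p in perms]
        assert by_cycles[0] == []
        assert by_cycles[1] == [(0, 1, 2), (3, 4, 5)]          # C3 row
        assert by_cycles[2] == [(0, 2, 1), (3, 5, 4)]          # C3^2 row
        assert by_cycles[3] == [(0, 3), (1, 5), (2, 4)]        # sigma row
        assert by_cycles[4] == [(0, 4), (1, 3), (2, 5)]        # sigma' row
        assert by_cycles[5] == [(0, 5), (1, 4), (2, 3)]        # sigma'' row

    def test_regular_action_is_a_homomorphism(self):
        g = generate_group_operations("D3")
        perms = permutation_representation(g)
        for a in range(len(g)):
            for b in range(len(g)):
                prod = perms[a] * perms[b]
                np.testing.assert_array_equal(
                    prod.images, perms[g.table[a, b]].images)

    def test_point_action_on_orbit(self, ammonia):
        from symadapt.pipeline import detect

        det = detect(ammonia)
        perms = permutation_representation(det.group, ammonia.recentered()
                                           .positions)
        ident = perms[0]
        assert all(len(c) == 1 for c in ident.cycles())

    def test_unmatched_points_raise(self):
        g = generate_group_operations("C4")
        pts = np.array([[1.0, 0, 0], [0.5, 0.5, 0.0]])
        with pytest.raises(ValueError, match="does not permute"):
            permutation_representation(g, pts)


class TestSubgroups:
    def test_c1_only_itself(self):
        subs = enumerate_subgroups(generate_group_operations("C1"))
        assert [s.label for s in subs] == ["C1"]

    def test_c3v_has_six_subgroups(self):
        subs = enumerate_subgroups(generate_group_operations("C3v"))
        labels = sorted(s.label for s in subs)
        assert labels == ["C1", "C3", "C3v", "Cs", "Cs", "Cs"]

    @pytest.mark.parametrize("label", ["C6", "C4v", "D4", "S8", "Td"])
    def test_lagrange_and_precalculated_counts(self, label):
        g = generate_group_operations(label)
        subs = enumerate_subgroups(g)
        assert all(len(g) % len(s) == 0 for s in subs)
        expected = expected_subgroup_count(label)
        assert expected is not None and len(subs) == expected

    def test_d2h_rank_three_subgroup_found(self):
        # D2h itself is not 2-generated; the join iteration must reach it
        g = generate_group_operations("Oh")
        subs = g.subgroups()
        assert any(s.label == "D2h" for s in subs)

    def test_cap(self):
        g = generate_group_operations("Ih")
        with pytest.raises(ValueError):
            enumerate_subgroups(g, cap=60)


def test_operation_from_matrix_round_trips_improper_rotation():
    m = generate_group_operations("S8").operations[4].matrix
    op = operation_from_matrix(m)
    assert op.kind in ("improper_axis", "proper_axis")
    r = rotation_matrix(np.array([0.3, -1.0, 0.2]), 2 * np.pi / 7)
    op = operation_from_matrix(r)
    assert (op.order, op.power) == (7, 1)
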
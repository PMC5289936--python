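import numpy as np
import pytest

from symadapt.character_tables import (
    generate_character_table,
    linear_group_table,
)
from symadapt.pipeline import detect
from symadapt.point_group import (
    generate_group_operations,
    permutation_representation,
)
from symadapt.real_sph import operation_matrix
from symadapt.salc import (
    BasisSpec,
    build_salcs,
    choose_splitting_subgroup,
    direct_product_rep,
    extract_subspace,
    salc_matrix,
    subduce,
    trace_projector,
)


def perm_matrices(group, points, tol=0.05):
    mats = []
    for perm in permutation_representation(group, points, tol=tol):
        m = np.zeros((len(points), len(points)))
        m[perm.images, np.arange(len(points))] = 1.0
        mats.append(m)
    return mats


@pytest.fixture(scope="module")
def c3v():
    g = generate_group_operations("C3v")
    return g, generate_character_table(g)


@pytest.fixture(scope="module")
def h3_rep(h3_module):
    g, t, mol = h3_module
    pm = perm_matrices(g, mol.recentered().positions)
    return direct_product_rep(pm, [np.eye(1)] * len(g))


@pytest.fixture(scope="module")
def h3_module():
    from symadapt.synthetic import h3_triangle

    mol = h3_triangle()
    det = detect(mol)
    return det.group, generate_character_table(det.group), mol


class TestDirectProduct:
    def test_s_shell_gives_permutation_matrices(self, h3_module):
        g, _, mol = h3_module
        pm = perm_matrices(g, mol.recentered().positions)
        rep = direct_product_rep(pm, [np.eye(1)] * len(g))
        for a, b in zip(rep, pm):
            np.testing.assert_array_equal(a, b)

    def test_single_atom_reduces_to_shell_rep(self):
        g = generate_group_operations("C2v")
        shells = [operation_matrix(1, op) for op in g.operations]
        rep = direct_product_rep([np.eye(1)] * len(g), shells)
        for a, b in zip(rep, shells):
            np.testing.assert_array_equal(a, b)

    def test_trace_is_product_of_traces(self, benzene):
        det = detect(benzene)
        carbons = list(next(s for s in det.sets if s.element == "C").indices)
        pm = perm_matrices(det.group,
                           benzene.recentered().positions[carbons])
        shells = [operation_matrix(2, op) for op in det.group.operations]
        rep = direct_product_rep(pm, shells)
        for r, p, y in zip(rep, pm, shells):
            assert np.trace(r) == pytest.approx(np.trace(p) * np.trace(y))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            direct_product_rep([np.eye(1)], [np.eye(1)] * 2)


class TestTraceProjector:
    def test_h3_totally_symmetric_projector_by_brute_force(self, h3_module,
                                                           h3_rep):
        g, t, _ = h3_module
        # brute-force: average the six 3x3 permutation matrices
        expect = sum(h3_rep) / len(h3_rep)
        p = trace_projector(t, t.irrep_index("A1'"), h3_rep)
        np.testing.assert_allclose(p, expect, atol=1e-12)
        np.testing.assert_allclose(p, np.full((3, 3), 1 / 3), atol=1e-12)

    def test_absent_irrep_projects_to_zero(self, h3_module, h3_rep):
        g, t, _ = h3_module
        p = trace_projector(t, t.irrep_index("A2'"), h3_rep)
        np.testing.assert_allclose(p, 0.0, atol=1e-12)

    def test_projector_completeness(self, h3_module, h3_rep):
        g, t, _ = h3_module
        total = sum(trace_projector(t, i, h3_rep)
                    for i in range(len(t.irreps)))
        np.testing.assert_allclose(total, np.eye(3), atol=1e-10)

    def test_idempotency_check_fires_on_inconsistent_rep(self, h3_module,
                                                         h3_rep):
        g, t, _ = h3_module
        broken = list(h3_rep)
        broken[1] = np.eye(3) * 0.5
        with pytest.raises(ValueError, match="idempotent"):
            trace_projector(t, 0, broken)


class TestExtractSubspace:
    def test_rank_one_factorisation(self):
        p = np.full((3, 3), 1 / 3)
        rows = extract_subspace(p)
        assert rows.shape == (1, 3)
        np.testing.assert_allclose(np.abs(rows[0]),
                                   np.full(3, 1 / np.sqrt(3)), atol=1e-12)

    def test_zero_projector_gives_empty_basis(self):
        assert extract_subspace(np.zeros((4, 4))).shape == (0, 4)

    def test_rows_lie_in_the_image(self, h3_module, h3_rep):
        g, t, _ = h3_module
        for name in ("A1'", "E'"):
            p = trace_projector(t, t.irrep_index(name), h3_rep)
            for v in extract_subspace(p):
                np.testing.assert_allclose(p @ v, v, atol=1e-9)


class TestSubduction:
    def test_c3v_to_cs_reproduces_published_species(self, c3v):
        g, t = c3v
        cs = next(s for s in g.subgroups() if s.label == "Cs")
        tcs = generate_character_table(cs.group)
        def species(name):
            mult = subduce(t.irrep_index(name), t, cs, tcs)
            return {tcs.irreps[i].name: int(v)
                    for i, v in enumerate(mult) if v}
        assert species("A1") == {"A'": 1}
        assert species("A2") == {"A''": 1}
        assert species("E") == {"A'": 1, "A''": 1}

    def test_c3v_to_c3_merges_the_complex_pair(self, c3v):
        g, t = c3v
        c3 = next(s for s in g.subgroups() if s.label == "C3")
        tc3 = generate_character_table(c3.group)
        mult = subduce(t.irrep_index("E"), t, c3, tc3)
        got = {tc3.irreps[i].name: int(v) for i, v in enumerate(mult) if v}
        assert got == {"E": 1}  # the merged e-pair, complex characters

    def test_dimensions_are_preserved(self, c3v):
        g, t = c3v
        for sub in g.subgroups():
            if len(sub) in (1, len(g)):
                continue
            tsub = generate_character_table(sub.group)
            for gi, ir in enumerate(t.irreps):
                mult = subduce(gi, t, sub, tsub)
                assert sum(int(m) * jr.dim for m, jr in
                           zip(mult, tsub.irreps)) == ir.dim


class TestSplittingSubgroup:
    def test_e_of_c3v_splits_through_a_mirror_subgroup(self, c3v):
        g, t = c3v
        paths = choose_splitting_subgroup(g, t, t.irrep_index("E"))
        assert [[s.subgroup.label for s in p] for p in paths] == \
            [["Cs"], ["Cs"]]
        assert [[s.table.irreps[s.h_irrep].name for s in p]
                for p in paths] == [["A'"], ["A''"]]
        # the lowest canonical mirror subgroup is chosen
        cs_subs = [s for s in g.subgroups() if s.label == "Cs"]
        assert paths[0][0].subgroup.indices == cs_subs[0].indices

    def test_complex_character_subgroups_are_avoided(self, c3v):
        g, t = c3v
        paths = choose_splitting_subgroup(g, t, t.irrep_index("E"))
        assert all(step.subgroup.label != "C3"
                   for p in paths for step in p)

    def test_icosahedral_five_dim_chain(self):
        g = generate_group_operations("I")
        t = generate_character_table(g)
        paths = choose_splitting_subgroup(g, t, t.irrep_index("H"))
        assert [len(p) for p in paths] == [1, 2, 2, 2, 2]
        assert paths[0][0].subgroup.label == "D5"
        assert {p[1].subgroup.label for p in paths[1:]} == {"C2"}
        names = [[s.name for s in p] for p in paths]
        assert names[1][0].startswith("D5:E1")
        assert names[3][0].startswith("D5:E2")


class TestBuildSalcs:
    def test_h3_s_basis_spans_a1_plus_e(self, h3_module):
        g, t, mol = h3_module
        salcs = build_salcs(mol, g, BasisSpec.uniform(3, (0,)))
        got = sorted((sp.irrep, sp.component) for sp in salcs)
        assert got == [("A1'", 1), ("E'", 1), ("E'", 2)]

    def test_total_salc_count_equals_basis_size(self, ammonia):
        det = detect(ammonia)
        spec = BasisSpec.uniform(len(ammonia), (0, 1, 2))
        salcs = build_salcs(ammonia, det.group, spec, sets=det.sets)
        c = salc_matrix(salcs)
        assert c.shape == (spec.size, spec.size)
        np.testing.assert_allclose(c @ c.T, np.eye(spec.size), atol=1e-10)

    def test_central_atom_d_shell_in_octahedral_field(self):
        from symadapt.geometry_io import Atom, Molecule
        from symadapt.masses import mass_of

        # central atom + octahedron of ligands
        atoms = [Atom("S", mass_of("S"), np.zeros(3))]
        for k in range(3):
            for s in (1.0, -1.0):
                p = np.zeros(3)
                p[k] = 2.0 * s
                atoms.append(Atom("F", mass_of("F"), p))
        mol = Molecule(atoms).recentered()
        det = detect(mol)
        assert det.label == "Oh"
        spec = BasisSpec([(0, 2)])   # d shell on the centre only
        salcs = build_salcs(mol, det.group, spec, sets=det.sets)
        got = sorted({(sp.irrep) for sp in salcs})
        assert got == ["Eg", "T2g"]

    def test_block_diagonalisation(self, ammonia):
        det = detect(ammonia)
        spec = BasisSpec.uniform(len(ammonia), (0, 1, 2))
        salcs = build_salcs(ammonia, det.group, spec, sets=det.sets)
        t = generate_character_table(det.group)
        c = salc_matrix(salcs)
        pos = ammonia.recentered().positions
        # assemble the full-space rep op by op and conjugate by the SALCs
        sizes = [sp.coefficients.shape[0] for sp in salcs]
        keys = [(sp.set_id, sp.l, sp.irrep_index) for sp in salcs]
        for g_idx in (1, len(det.group) - 1):
            op = det.group.operations[g_idx]
            full = np.zeros((spec.size, spec.size))
            perms = permutation_representation(det.group, pos, tol=0.05)
            images = perms[g_idx].images
            for a, l in spec.shells:
                y = operation_matrix(l, op)
                b = spec.index(a, l, -l)
                tgt = spec.index(int(images[a]), l, -l)
                full[tgt:tgt + 2 * l + 1, b:b + 2 * l + 1] = y
            m = c @ full @ c.T
            i0 = 0
            for size, key in zip(sizes, keys):
                # off-diagonal coupling only allowed inside one
                # (set, l, irrep) group of rows
                j0 = 0
                for size2, key2 in zip(sizes, keys):
                    if key2 != key:
                        block = m[i0:i0 + size, j0:j0 + size2]
                        assert np.abs(block).max() < 1e-8
                    j0 += size2
                i0 += size

    def test_partner_action_identical_across_sets_and_shells(self, ammonia):
        det = detect(ammonia)
        spec = BasisSpec.uniform(len(ammonia), (0, 1))
        salcs = build_salcs(ammonia, det.group, spec, sets=det.sets)
        t = generate_character_table(det.group)
        gi = t.irrep_index("E")
        # gather E blocks: (set, l, copy) -> component rows
        blocks = {}
        for sp in salcs:
            if sp.irrep != "E":
                continue
            for copy in range(sp.coefficients.shape[0]):
                blocks.setdefault((sp.set_id, sp.l, copy), {})[
                    sp.component] = sp.coefficients[copy]
        pos = ammonia.recentered().positions
        perms = permutation_representation(det.group, pos, tol=0.05)
        op_idx = 1  # a C3 rotation
        op = det.group.operations[op_idx]
        images = perms[op_idx].images
        full = np.zeros((spec.size, spec.size))
        for a, l in spec.shells:
            y = operation_matrix(l, op)
            b = spec.index(a, l, -l)
            tgt = spec.index(int(images[a]), l, -l)
            full[tgt:tgt + 2 * l + 1, b:b + 2 * l + 1] = y
        actions = []
        for key, comps in sorted(blocks.items()):
            basis = np.stack([comps[1], comps[2]])
            actions.append(basis @ full @ basis.T)
        for act in actions[1:]:
            np.testing.assert_allclose(act, actions[0], atol=1e-8)

    def test_linear_molecule_shells_split_by_angular_momentum(self):
        from symadapt.geometry_io import Atom, Molecule
        from symadapt.masses import mass_of

        mol = Molecule([
            Atom("C", mass_of("C"), np.zeros(3)),
            Atom("O", mass_of("O"), np.array([0.0, 0, 1.16])),
            Atom("O", mass_of("O"), np.array([0.0, 0, -1.16])),
        ]).recentered()
        det = detect(mol)
        assert det.label == "Dinfh"
        group, table = linear_group_table(det.label, 2,
                                          transform=det.transform)
        spec = BasisSpec.uniform(3, (0, 1, 2))
        salcs = build_salcs(mol, group, spec, table=table, sets=det.sets)
        assert sum(sp.coefficients.shape[0] for sp in salcs) == spec.size
        # the central atom's p shell: z → Sigma_u+, (x, y) → Pi_u
        central = [sp for sp in salcs if sp.set_id == 0 and sp.l == 1]
        names = sorted({sp.irrep for sp in central})
        assert names == ["Pi_u", "Sigma_u+"]
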
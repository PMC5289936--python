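import numpy as np
import pytest

from symadapt.pipeline import detect
from symadapt.point_group import permutation_representation
from symadapt.salc import BasisSpec, build_salcs
from symadapt.symmetrize import (
    OrbitalSet,
    SymmetryBrokenError,
    analyze_orbital_symmetry,
    symmetrize_molecule,
    symmetrize_wavefunction,
)
from symadapt.synthetic import generate_test_orbitals


@pytest.fixture(scope="module")
def nh3_salcs():
    from symadapt.synthetic import ammonia

    mol = ammonia()
    det = detect(mol)
    spec = BasisSpec.uniform(len(mol), (0, 1))
    return build_salcs(mol, det.group, spec, sets=det.sets), det, mol


class TestGeometry:
    def test_symmetric_molecule_unchanged(self, benzene):
        det = detect(benzene)
        res = symmetrize_molecule(benzene, det.group)
        assert res.error == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.molecule.positions,
                                   benzene.recentered().positions,
                                   atol=1e-12)

    def test_noisy_geometry_restored_to_exact_invariance(self, ammonia):
        rng = np.random.default_rng(7)
        noisy = ammonia.with_positions(
            ammonia.positions + rng.normal(0, 1e-3, (len(ammonia), 3)))
        det = detect(noisy)
        assert det.label == "C3v"
        res = symmetrize_molecule(noisy, det.group)
        pos = res.molecule.positions
        perms = permutation_representation(det.group, pos, tol=0.05)
        for perm, op in zip(perms, det.group.operations):
            assert np.abs(pos @ op.matrix.T - pos[perm.images]).max() < 1e-12

    def test_error_scales_with_noise(self, ammonia):
        rng = np.random.default_rng(3)
        sigma = 1e-3
        noisy = ammonia.with_positions(
            ammonia.positions + rng.normal(0, sigma, (len(ammonia), 3)))
        det = detect(noisy)
        res = symmetrize_molecule(noisy, det.group)
        assert 0.0 < res.error_rms < 3 * sigma

    def test_idempotency(self, ammonia):
        rng = np.random.default_rng(11)
        noisy = ammonia.with_positions(
            ammonia.positions + rng.normal(0, 1e-3, (len(ammonia), 3)))
        det = detect(noisy)
        once = symmetrize_molecule(noisy, det.group)
        twice = symmetrize_molecule(once.molecule, det.group)
        assert twice.error == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(twice.molecule.positions,
                                   once.molecule.positions, atol=1e-12)

    def test_error_equals_mass_weighted_distance(self, ammonia):
        rng = np.random.default_rng(5)
        noisy = ammonia.with_positions(
            ammonia.positions + rng.normal(0, 1e-3, (len(ammonia), 3)))
        det = detect(noisy)
        res = symmetrize_molecule(noisy, det.group)
        delta = noisy.recentered().positions - res.molecule.positions
        m = noisy.masses
        expect = np.sqrt((m * (delta**2).sum(axis=1)).sum())
        assert res.error == pytest.approx(expect, rel=1e-10)


class TestOrbitalAnalysis:
    def test_pure_salc_row_has_unit_fraction(self, nh3_salcs):
        salcs, det, mol = nh3_salcs
        row = salcs[0].coefficients[0]
        rep = analyze_orbital_symmetry(OrbitalSet(row[None, :]), salcs)
        assert rep.fractions.max() == pytest.approx(1.0)
        assert rep.assigned == [salcs[0].irrep]

    def test_equal_mixture_splits_half_half(self, nh3_salcs):
        salcs, det, mol = nh3_salcs
        a1 = next(sp for sp in salcs if sp.irrep == "A1")
        e = next(sp for sp in salcs if sp.irrep == "E")
        mix = (a1.coefficients[0] + e.coefficients[0]) / np.sqrt(2)
        rep = analyze_orbital_symmetry(OrbitalSet(mix[None, :]), salcs)
        top_two = sorted(rep.fractions[0])[-2:]
        np.testing.assert_allclose(top_two, [0.5, 0.5], atol=1e-10)

    def test_fractions_sum_to_one_for_random_orbitals(self, nh3_salcs, rng):
        salcs, det, mol = nh3_salcs
        n = salcs[0].coefficients.shape[1]
        raw = rng.normal(size=(4, n))
        raw /= np.linalg.norm(raw, axis=1)[:, None]
        rep = analyze_orbital_symmetry(OrbitalSet(raw), salcs)
        np.testing.assert_allclose(rep.fractions.sum(axis=1), 1.0,
                                   atol=1e-8)


class TestWavefunctionSymmetrisation:
    def test_adapted_input_returned_unchanged_up_to_sign(self, nh3_salcs):
        salcs, det, mol = nh3_salcs
        coeffs, truth = generate_test_orbitals(salcs, 0.0)
        out, rep = symmetrize_wavefunction(OrbitalSet(coeffs), salcs)
        assert rep.assigned == truth
        for a, b in zip(out.coefficients, coeffs):
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    @pytest.mark.parametrize("contamination", [0.01, 0.25, 0.49])
    def test_contamination_removed(self, nh3_salcs, contamination):
        salcs, det, mol = nh3_salcs
        coeffs, truth = generate_test_orbitals(salcs, contamination,
                                               rng_seed=5)
        out, rep = symmetrize_wavefunction(OrbitalSet(coeffs), salcs)
        assert rep.assigned == truth
        assert rep.fractions.max(axis=1).min() > 1 - 1e-8
        # P^Γ ψ = ψ for the assigned irrep
        for i, name in enumerate(rep.assigned):
            rows = np.vstack([sp.coefficients for sp in salcs
                              if sp.irrep == name])
            psi = out.coefficients[i]
            np.testing.assert_allclose(rows.T @ (rows @ psi), psi,
                                       atol=1e-8)

    def test_norms_preserved(self, nh3_salcs):
        salcs, det, mol = nh3_salcs
        coeffs, _ = generate_test_orbitals(salcs, 0.2, rng_seed=9)
        out, _ = symmetrize_wavefunction(OrbitalSet(coeffs), salcs)
        np.testing.assert_allclose(
            np.linalg.norm(out.coefficients, axis=1), 1.0, atol=1e-9)

    def test_fifty_fifty_orbital_rejected(self, nh3_salcs):
        salcs, det, mol = nh3_salcs
        a1 = next(sp for sp in salcs if sp.irrep == "A1")
        e = next(sp for sp in salcs if sp.irrep == "E")
        mix = (a1.coefficients[0] + e.coefficients[0]) / np.sqrt(2)
        with pytest.raises(SymmetryBrokenError):
            symmetrize_wavefunction(OrbitalSet(mix[None, :]), salcs)

    def test_idempotent(self, nh3_salcs):
        salcs, det, mol = nh3_salcs
        coeffs, _ = generate_test_orbitals(salcs, 0.1, rng_seed=2)
        once, _ = symmetrize_wavefunction(OrbitalSet(coeffs), salcs)
        twice, _ = symmetrize_wavefunction(once, salcs)
        for a, b in zip(once.coefficients, twice.coefficients):
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-9
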
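import numpy as np
import pytest

from eemcc.constants import KB_SI, PLANCK_SI, R_J
from eemcc.hierarchy import build_hierarchy
from eemcc.synthetic import (HarmonicSpec, dipeptide_topology,
                             make_toy_dipeptide, sample_harmonic)
from eemcc.vibrational import (CovarianceAccumulator, ModeSpectrum,
                               accumulate_covariance, build_frames,
                               principal_frame, qho_entropy, residue_frame,
                               spectrum_from_covariance, ua_frame,
                               vibrational_entropy_molecule)


def nu_at(x, temperature=298.0):
    """Frequency with h nu / kB T = x."""
    return x * KB_SI * temperature / PLANCK_SI


class TestQhoEntropy:
    def test_matches_closed_form(self):
        for x in (0.1, 1.0, 10.0):
            expected = R_J * (x / (np.exp(x) - 1) - np.log(1 - np.exp(-x)))
            assert qho_entropy([nu_at(x)], 298.0) == pytest.approx(
                expected, abs=1e-10)

    def test_reference_value_at_x_equal_one(self):
        assert qho_entropy([nu_at(1.0)], 298.0) == pytest.approx(
            8.652, abs=5e-4)

    def test_frozen_mode_limit(self):
        assert qho_entropy([1e18], 298.0) == 0.0

    def test_zero_frequency_contributes_nothing(self):
        assert qho_entropy([0.0, nu_at(1.0)], 298.0) == \
            qho_entropy([nu_at(1.0)], 298.0)

    def test_classical_limit(self):
        x = 1e-4
        expected = R_J * (1.0 - np.log(x))
        assert qho_entropy([nu_at(x)], 298.0) == pytest.approx(
            expected, rel=1e-4)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            qho_entropy([1e12], 0.0)


class TestSpectrum:
    def test_harmonic_identity(self):
        # lambda = k kB T / m  ->  nu = sqrt(k/m)/2pi
        from eemcc.constants import KB_KJ, OMEGA_SQ_TO_SI
        k, m, T = 250.0, 12.0, 298.0
        lam = k * KB_KJ * T / m
        sp = spectrum_from_covariance(np.diag([lam] * 3), T)
        expected = np.sqrt(k / m * OMEGA_SQ_TO_SI) / (2 * np.pi)
        np.testing.assert_allclose(sp.frequencies, expected, rtol=1e-12)

    def test_six_smallest_removed_at_monomer_level(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(9, 9))
        sp = spectrum_from_covariance(a @ a.T, 298.0, n_remove=6)
        assert sp.frequencies.size == 3
        assert sp.n_removed == 6

    def test_negative_eigenvalues_clamped_and_counted(self):
        sp = spectrum_from_covariance(np.diag([-1.0, 2.0]), 298.0)
        assert sp.n_clamped == 1
        assert sp.n_kept == 1

    def test_zero_matrix_has_no_kept_modes(self):
        sp = spectrum_from_covariance(np.zeros((3, 3)), 298.0)
        assert sp.n_kept == 0
        assert qho_entropy(sp, 298.0) == 0.0


class TestHarmonicPipeline:
    def test_equipartition_of_force_covariance(self):
        k, m = 400.0, 18.0
        spec = HarmonicSpec([k] * 3, [m], n_samples=100_000, seed=2)
        batch = sample_harmonic(spec)
        from eemcc.constants import KB_KJ
        c = np.einsum("fi,fj->ij", batch.forces[:, 0, :],
                      batch.forces[:, 0, :]) / batch.n_frames
        target = k * KB_KJ * 298.0
        np.testing.assert_allclose(np.diag(c), target, rtol=0.02)

    def test_recovers_analytic_entropy_within_two_percent(self):
        spec = HarmonicSpec([300.0, 300.0, 300.0], [16.0],
                            n_samples=100_000, seed=3)
        batch = sample_harmonic(spec)
        v = batch.forces[:, 0, :] / np.sqrt(16.0)
        acc = CovarianceAccumulator(3)
        for row in v[:0]:
            acc.add(row)
        cov = v.T @ v / v.shape[0]
        sp = spectrum_from_covariance(cov, 298.0)
        s = qho_entropy(sp, 298.0)
        assert s == pytest.approx(spec.analytic_entropy, rel=0.02)

    def test_stiffer_trap_has_lower_entropy(self):
        entropies = []
        for k in (100.0, 400.0, 1600.0):
            spec = HarmonicSpec([k] * 3, [16.0], n_samples=20_000, seed=4)
            batch = sample_harmonic(spec)
            v = batch.forces[:, 0, :] / np.sqrt(16.0)
            sp = spectrum_from_covariance(v.T @ v / len(v), 298.0)
            entropies.append(qho_entropy(sp, 298.0))
        assert entropies[0] > entropies[1] > entropies[2]

    def test_independent_units_have_vanishing_cross_block(self):
        spec = HarmonicSpec([200.0] * 6, [16.0, 16.0],
                            n_samples=50_000, seed=5)
        batch = sample_harmonic(spec)
        v = batch.forces.reshape(batch.n_frames, 6) / np.sqrt(16.0)
        c = v.T @ v / len(v)
        cross = np.abs(c[:3, 3:]).max()
        assert cross < 0.02 * np.abs(np.diag(c)).min()


class TestLocalFrames:
    def test_residue_frame_matches_hand_geometry(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 1.0, 0]])
        fr = residue_frame(coords, 0, 1, 2)
        np.testing.assert_allclose(fr.origin, [2 / 3, 1 / 3, 0])
        np.testing.assert_allclose(fr.axes[0], [1, 1, 0] / np.sqrt(2),
                                   atol=1e-12)
        np.testing.assert_allclose(np.abs(fr.axes[1]), [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(fr.axes @ fr.axes.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(fr.axes) == pytest.approx(1.0)

    def test_collinear_backbone_raises_for_fallback(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            residue_frame(coords, 0, 1, 2)

    def test_point_ua_gets_identity_axes(self):
        coords = np.array([[1.0, 2.0, 3.0]])
        fr = ua_frame(coords, 0, [], [])
        np.testing.assert_allclose(fr.axes, np.eye(3))

    def test_water_principal_axes_are_symmetry_adapted(self):
        # planar symmetric water: one axis normal to the plane
        coords = np.array([[0.0, 0, 0], [0.76, 0.59, 0], [-0.76, 0.59, 0]])
        masses = np.array([15.9994, 1.008, 1.008])
        fr = principal_frame(coords, masses)
        normals = np.abs(fr.axes @ np.array([0.0, 0, 1.0]))
        assert np.isclose(normals.max(), 1.0, atol=1e-10)

    def test_frames_exist_for_all_levels(self, dipeptide):
        top, hier = dipeptide
        from eemcc.synthetic import dipeptide_coordinates
        frames = build_frames(hier, dipeptide_coordinates(-80, 150))
        assert set(frames) == {"polymer", "monomer", "ua"}
        assert len(frames["ua"]) == 10
        for fr in frames["ua"].values():
            np.testing.assert_allclose(fr.axes @ fr.axes.T, np.eye(3),
                                       atol=1e-10)


@pytest.fixture(scope="module")
def toy_batch():
    top, batch, _ = make_toy_dipeptide(40, seed=9)
    return build_hierarchy(top), batch


class TestMoleculeEntropy:
    def test_zero_forces_give_zero_matrix(self, toy_batch):
        hier, batch = toy_batch
        import copy
        silent = copy.deepcopy(batch)
        silent.forces = np.zeros_like(batch.forces)
        f_acc, t_acc = accumulate_covariance(silent, hier, "polymer",
                                             polymer=0)
        assert np.allclose(f_acc.matrix, 0) and np.allclose(t_acc.matrix, 0)

    def test_mode_bookkeeping(self, toy_batch):
        hier, batch = toy_batch
        f_acc, t_acc = accumulate_covariance(batch, hier, "monomer",
                                             polymer=0)
        assert f_acc.dim == 9                      # 3 residues
        assert t_acc.dim == 9                      # nonlinear residues
        f_acc, t_acc = accumulate_covariance(batch, hier, "ua", monomer=1)
        assert f_acc.dim == 15                     # 5 UAs in ALA
        # ALA UAs: N (linear, 2) CA (linear, 2) CB (nonlinear, 3)
        # C (point, 0) O (point, 0)
        assert t_acc.dim == 7

    def test_rigid_rotation_leaves_entropy_invariant(self, toy_batch):
        hier, batch = toy_batch
        before = vibrational_entropy_molecule(batch, hier, 0)
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("zyx", [40.0, -25.0, 100.0],
                                  degrees=True).as_matrix()
        import copy
        rotated = copy.deepcopy(batch)
        center = batch.box[0] / 2.0
        rotated.coordinates = (batch.coordinates - center) @ rot.T + center
        rotated.forces = batch.forces @ rot.T
        after = vibrational_entropy_molecule(rotated, hier, 0)
        for key, val in before.terms.items():
            assert after.terms[key] == pytest.approx(val, abs=1e-8), key

    def test_ledger_totals_sum_terms(self, toy_batch):
        hier, batch = toy_batch
        ledger = vibrational_entropy_molecule(batch, hier, 0)
        assert ledger.total == pytest.approx(sum(ledger.terms.values()))
        assert set(ledger.terms) >= {"S_P_transvib", "S_P_rovib",
                                     "S_M_transvib", "S_M_rovib",
                                     "S_UA_transvib", "S_UA_rovib"}
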
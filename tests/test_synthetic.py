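"""Generator contracts: determinism, nonnegativity, perturbation behavior."""

import numpy as np
import pytest

import synkit as sk
from synkit.datatypes import ConfigurationError
from synkit.preprocessing import ensure_scaled


class TestMakeGroundTruth:
    def test_shapes_and_nonnegativity(self):
        gt = sk.make_ground_truth(8, 3, seed=1)
        assert gt.W_true.shape == (8, 3)
        assert gt.H_true_profile.shape == (3, 101)
        assert np.all(gt.W_true >= 0) and np.all(gt.H_true_profile >= 0)

    def test_profiles_peak_normalized(self):
        gt = sk.make_ground_truth(8, 4, seed=2)
        np.testing.assert_allclose(gt.H_true_profile.max(axis=1), 1.0)

    @pytest.mark.parametrize("n_syn", [2, 3, 4, 8])
    def test_weight_columns_distinct(self, n_syn):
        gt = sk.make_ground_truth(8, n_syn, seed=7)
        corr = np.corrcoef(gt.W_true.T)
        off_diag = corr[~np.eye(n_syn, dtype=bool)]
        assert np.all(off_diag < 0.9)

    def test_two_muscle_two_synergy_columns_distinct(self):
        gt = sk.make_ground_truth(2, 2, seed=7)
        assert np.corrcoef(gt.W_true[:, 0], gt.W_true[:, 1])[0, 1] < 0.9

    def test_deterministic_given_seed(self):
        a = sk.make_ground_truth(8, 3, seed=1)
        b = sk.make_ground_truth(8, 3, seed=1)
        np.testing.assert_array_equal(a.W_true, b.W_true)
        np.testing.assert_array_equal(a.H_true_profile, b.H_true_profile)

    def test_rank_exceeding_muscles_rejected(self):
        with pytest.raises(ConfigurationError):
            sk.make_ground_truth(4, 5, seed=0)

    def test_peak_phases_spread_over_cycle(self):
        gt = sk.make_ground_truth(8, 4, seed=3)
        peaks = np.sort(gt.H_true_profile.argmax(axis=1)) / 100.0
        gaps = np.diff(np.concatenate([peaks, [peaks[0] + 1.0]]))
        assert gaps.max() < 0.75  # bursts not all clumped in one phase region


class TestSimulateEnvelope:
    def test_noiseless_is_exact_product(self, gt3):
        cfg = sk.SimulationConfig(envelope_noise_sd=0.0, seed=5)
        env = sk.simulate_envelope(gt3, cfg)
        expected = gt3.W_true @ np.tile(gt3.H_true_profile, (1, cfg.n_cycles))
        np.testing.assert_allclose(env.data, expected)

    def test_noise_magnitude_matches_requested_fraction(self):
        # element-wise residual SD ~ noise_sd * envelope SD, averaged over seeds
        gt = sk.make_ground_truth(8, 3, seed=11)
        clean = sk.simulate_envelope(gt, sk.SimulationConfig(envelope_noise_sd=0.0, seed=0))
        ratios = []
        for s in range(30):
            noisy = sk.simulate_envelope(gt, sk.SimulationConfig(envelope_noise_sd=0.1, seed=s))
            ratios.append((noisy.data - clean.data).std() / (0.1 * clean.data.std()))
        assert abs(np.mean(ratios) - 1.0) < 0.2

    def test_nonnegative_under_heavy_noise(self, gt3):
        env = sk.simulate_envelope(gt3, sk.SimulationConfig(envelope_noise_sd=1.0, seed=3))
        assert np.all(env.data >= 0)

    def test_deterministic(self, gt3):
        cfg = sk.SimulationConfig(envelope_noise_sd=0.2, seed=9)
        np.testing.assert_array_equal(
            sk.simulate_envelope(gt3, cfg).data, sk.simulate_envelope(gt3, cfg).data
        )


class TestSimulateRaw:
    def test_zero_envelope_gives_zero_signal(self, gt3):
        cfg = sk.SimulationConfig(envelope_noise_sd=0.0, seed=1)
        env = sk.simulate_envelope(gt3, cfg)
        env.data[:] = 0.0
        raw = sk.simulate_raw(env, cfg)
        np.testing.assert_array_equal(raw.signals, 0.0)

    def test_event_count_is_cycles_plus_one(self, clean_env3):
        raw = sk.simulate_raw(clean_env3, sk.SimulationConfig(seed=2))
        assert raw.heel_strikes.size == clean_env3.n_cycles + 1

    def test_constant_envelope_yields_flat_recovered_envelope(self):
        # CV of the recovered envelope < 0.1 away from the edges
        cfg = sk.SimulationConfig(seed=4)
        flat = sk.GaitCycleMatrix(
            data=np.ones((8, 5 * 101)),
            n_cycles=5,
            n_samples_per_cycle=101,
            channel_names=sk.DEFAULT_MUSCLES,
        )
        raw = sk.simulate_raw(flat, cfg)
        env = sk.envelope(raw)
        sl = slice(int(raw.sampling_rate), -int(raw.sampling_rate))
        inner = env.signals[:, sl]
        cv = inner.std(axis=1) / inner.mean(axis=1)
        assert cv.mean() < 0.1 and cv.max() < 0.15

    def test_invalid_carrier_band_rejected(self, clean_env3):
        with pytest.raises(ConfigurationError):
            sk.SimulationConfig(carrier_band=(20.0, 1500.0), sampling_rate=2000.0)


class TestPerturbGroundTruth:
    def test_zero_perturbation_is_identity(self, gt3):
        out = sk.perturb_ground_truth(gt3, 0.0, 0.0, seed=5)
        np.testing.assert_array_equal(out.W_true, gt3.W_true)
        np.testing.assert_array_equal(out.H_true_profile, gt3.H_true_profile)

    def test_weight_perturbation_monotone_in_magnitude(self):
        def mean_corr(mag):
            vals = []
            for s in range(20):
                gt = sk.make_ground_truth(8, 3, seed=s)
                pert = sk.perturb_ground_truth(gt, mag, 0.0, seed=s + 100)
                vals.extend(
                    np.corrcoef(gt.W_true[:, k], pert.W_true[:, k])[0, 1] for k in range(3)
                )
            return np.mean(vals)

        assert mean_corr(0.5) < mean_corr(0.1)

    def test_profile_perturbation_monotone_in_magnitude(self):
        def mean_rmse(mag):
            vals = []
            for s in range(20):
                gt = sk.make_ground_truth(8, 3, seed=s)
                pert = sk.perturb_ground_truth(gt, 0.0, mag, seed=s + 100)
                vals.append(
                    np.sqrt(np.mean((gt.H_true_profile - pert.H_true_profile) ** 2))
                )
            return np.mean(vals)

        assert mean_rmse(0.5) > mean_rmse(0.1)

    def test_output_stays_valid_ground_truth(self, gt3):
        out = sk.perturb_ground_truth(gt3, 0.7, 0.7, seed=1)
        assert np.all(out.W_true >= 0)
        np.testing.assert_allclose(out.H_true_profile.max(axis=1), 1.0)


class TestSimulateTdLike:
    def test_shape_and_determinism(self):
        cfg = sk.SimulationConfig(seed=0)
        a = sk.simulate_td_like(cfg, n_syn_td=5, seed=3)
        b = sk.simulate_td_like(cfg, n_syn_td=5, seed=3)
        assert a.data.shape == (8, 5 * 101)
        np.testing.assert_array_equal(a.data, b.data)

    def test_poorly_explained_by_low_rank_patient_synergies(self):
        # patient-own VAF_POST exceeds VAF_TD, i.e. SPEC > 0 on average
        specs = []
        for s in range(20):
            gt = sk.make_ground_truth(8, 2, seed=s)
            cfg = sk.SimulationConfig(envelope_noise_sd=0.05)
            pre = ensure_scaled(sk.simulate_envelope(gt, cfg.replace(seed=2 * s)))
            post = ensure_scaled(sk.simulate_envelope(gt, cfg.replace(seed=2 * s + 1)))
            td = ensure_scaled(sk.simulate_td_like(cfg, n_syn_td=5, seed=s + 500))
            syn = sk.nnmf(pre, 2, n_restarts=5, seed=s)
            vaf_post = sk.reconstruct_aoa(syn.W, post).vaf_global
            vaf_td = sk.reconstruct_aoa(syn.W, td).vaf_global
            specs.append(vaf_post - vaf_td)
        assert np.mean(specs) > 0


def test_extraction_vaf_degrades_monotonically_with_noise():
    """More envelope noise -> lower NNMF fit VAF (Spearman rho < -0.9)."""
    from scipy.stats import spearmanr

    noise_grid = [0.0, 0.05, 0.1, 0.2, 0.4]
    means = []
    for noise in noise_grid:
        vafs = []
        for s in range(20):
            gt = sk.make_ground_truth(8, 3, seed=s)
            env = sk.simulate_envelope(gt, sk.SimulationConfig(envelope_noise_sd=noise, seed=s))
            vafs.append(sk.nnmf(ensure_scaled(env), 3, n_restarts=3, seed=s).fit_vaf)
        means.append(np.mean(vafs))
    rho = spearmanr(noise_grid, means).statistic
    assert rho < -0.9
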
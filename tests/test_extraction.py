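"""VAF statistic, NNMF, bootstrap rank selection, profile averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import synkit as sk
from synkit.datatypes import ConfigurationError, DataError, UndefinedVAFError
from synkit.extraction import _multiplicative_update, average_activation_profile

from conftest import make_scaled_envelope


class TestVAF:
    def test_identity_gives_100(self, rng):
        x = np.abs(rng.standard_normal((4, 30)))
        assert sk.vaf(x, x) == pytest.approx(100.0, abs=1e-9)

    def test_scale_invariance(self, rng):
        x = np.abs(rng.standard_normal((4, 30)))
        assert sk.vaf(x, 3.7 * x) == pytest.approx(100.0, abs=1e-9)

    def test_orthogonal_signals_give_0(self):
        assert sk.vaf(np.array([[1.0, 0.0], [0.0, 0.0]]),
                      np.array([[0.0, 0.0], [0.0, 1.0]])) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_two_element_case(self):
        # (1*1 + 1*0)^2 / ((1+1) * 1) * 100 = 50
        assert sk.vaf(np.array([1.0, 1.0]), np.array([1.0, 0.0])) == pytest.approx(50.0, abs=1e-9)

    def test_zero_signal_raises(self):
        with pytest.raises(UndefinedVAFError):
            sk.vaf(np.zeros((2, 2)), np.ones((2, 2)))

    @settings(deadline=None, max_examples=50)
    @given(
        x=hnp.arrays(float, (3, 8), elements=st.floats(0, 10)),
        r=hnp.arrays(float, (3, 8), elements=st.floats(0, 10)),
        k=st.floats(0.01, 100),
    )
    def test_bounded_and_rescaling_invariant(self, x, r, k):
        if not ((x * x).sum() > 0 and (r * r).sum() > 0):
            return
        v = sk.vaf(x, r)
        assert 0.0 <= v <= 100.0
        assert sk.vaf(x, k * r) == pytest.approx(v, rel=1e-9)
        assert sk.vaf(k * x, r) == pytest.approx(v, rel=1e-9)


class TestVAFPerMuscle:
    def test_identity_rows_all_100(self, rng):
        x = np.abs(rng.standard_normal((5, 20)))
        np.testing.assert_allclose(sk.vaf_per_muscle(x, x), 100.0, atol=1e-9)

    def test_orthogonal_row_scores_0_others_100(self, rng):
        x = np.zeros((2, 4))
        x[0, :2] = 1.0
        x[1] = [1.0, 1.0, 0.0, 0.0]
        r = x.copy()
        r[0, :2] = 0.0
        r[0, 2:] = 1.0  # orthogonal to x[0]
        out = sk.vaf_per_muscle(x, r)
        assert out[0] == pytest.approx(0.0, abs=1e-12)
        assert out[1] == pytest.approx(100.0, abs=1e-9)

    def test_per_row_scale_invariance(self, rng):
        x = np.abs(rng.standard_normal((2, 20)))
        r = x * np.array([[1.0], [7.0]])
        np.testing.assert_allclose(sk.vaf_per_muscle(x, r), 100.0, atol=1e-9)

    def test_zero_row_flagged_nan(self, rng):
        x = np.abs(rng.standard_normal((2, 10)))
        x[0] = 0.0
        out = sk.vaf_per_muscle(x, np.abs(rng.standard_normal((2, 10))))
        assert np.isnan(out[0]) and np.isfinite(out[1])


class TestNNMF:
    def test_rank_one_input_fully_explained(self, rng):
        w = np.abs(rng.standard_normal(6)) + 0.1
        h = np.abs(rng.standard_normal(40)) + 0.1
        syn = sk.nnmf(np.outer(w, h), 1, n_restarts=3, seed=0)
        assert syn.fit_vaf == pytest.approx(100.0, abs=1e-6)

    def test_noiseless_recovery_of_true_weights(self):
        gt, m = make_scaled_envelope(3, seed=42)
        syn = sk.nnmf(m, 3, n_restarts=10, seed=1)
        w_true = sk.scaled_weights(gt, m.channel_scale)
        match = sk.match_synergies(w_true, syn.W)
        assert match.correlations.min() > 0.99

    def test_capacity_monotone_in_rank(self):
        _, m = make_scaled_envelope(3, seed=5, noise=0.1)
        v_full = sk.nnmf(m, m.n_muscles, n_restarts=5, seed=2).fit_vaf
        v_one = sk.nnmf(m, 1, n_restarts=5, seed=2).fit_vaf
        assert v_full >= v_one

    def test_objective_trace_non_increasing(self, rng):
        V = np.abs(rng.standard_normal((6, 80)))
        _, _, trace = _multiplicative_update(V, 3, rng, tol=0.0, max_iter=300)
        assert np.all(np.diff(trace) <= 1e-8 * trace[0])

    def test_deterministic_given_seed(self):
        _, m = make_scaled_envelope(2, seed=3, noise=0.05)
        a = sk.nnmf(m, 2, n_restarts=3, seed=9)
        b = sk.nnmf(m, 2, n_restarts=3, seed=9)
        np.testing.assert_array_equal(a.W, b.W)

    def test_matches_sklearn_reconstruction_error(self):
        # independent implementation cross-check on a noiseless instance
        from sklearn.decomposition import NMF

        _, m = make_scaled_envelope(2, seed=13)
        syn = sk.nnmf(m, 2, n_restarts=5, seed=4, tol=1e-9, max_iter=5000)
        ours = np.linalg.norm(m.data - syn.W @ syn.H)
        ref = NMF(2, init="random", solver="mu", tol=1e-9, max_iter=5000, random_state=0)
        ref.fit(m.data)
        assert abs(ours - ref.reconstruction_err_) < 1e-3 * np.linalg.norm(m.data)

    def test_invalid_inputs_rejected(self, rng):
        V = np.abs(rng.standard_normal((4, 20)))
        with pytest.raises(ConfigurationError):
            sk.nnmf(V, 5)
        with pytest.raises(DataError):
            sk.nnmf(np.full((4, 20), np.nan), 2)


class TestBootstrapSelect:
    def test_rank_one_matrix_selects_one(self, rng):
        w = np.abs(rng.standard_normal(8)) + 0.1
        h = np.abs(rng.standard_normal(505)) + 0.1
        m = sk.GaitCycleMatrix(
            data=np.outer(w, h), n_cycles=5, n_samples_per_cycle=101,
            channel_names=sk.DEFAULT_MUSCLES,
        )
        sel = sk.bootstrap_select_nsyn(m, n_boot=50, seed=0, n_restarts=3)
        assert sel.n_syn == 1 and sel.criterion_met

    def test_noiseless_true_rank_recovered(self):
        _, m = make_scaled_envelope(3, seed=17)
        sel = sk.bootstrap_select_nsyn(m, n_boot=100, seed=1, n_restarts=5)
        assert sel.n_syn == 3

    def test_distributions_kept_for_diagnostics(self):
        _, m = make_scaled_envelope(2, seed=8)
        sel = sk.bootstrap_select_nsyn(m, n_boot=40, seed=2, n_restarts=3)
        assert set(sel.vaf_distributions) == set(range(1, sel.n_syn + 1))
        assert all(len(v) == 40 for v in sel.vaf_distributions.values())
        assert all(np.all((v >= 0) & (v <= 100)) for v in sel.vaf_distributions.values())

    def test_defaults_match_protocol(self):
        import inspect

        sig = inspect.signature(sk.bootstrap_select_nsyn)
        assert sig.parameters["n_boot"].default == 500
        assert sig.parameters["percentile"].default == 95.0
        assert sig.parameters["vaf_threshold"].default == 90.0


class TestAverageActivationProfile:
    def test_identical_cycles_average_to_one_cycle(self, rng):
        one = np.abs(rng.standard_normal((2, 101)))
        h = np.tile(one, (1, 5))
        np.testing.assert_allclose(average_activation_profile(h, 101), one)

    def test_arithmetic_mean_of_windows(self):
        h = np.array([[0.0, 2.0], [2.0, 0.0]]).reshape(1, 4)  # two 2-sample cycles
        np.testing.assert_allclose(average_activation_profile(h, 2), [[1.0, 1.0]])

    def test_multi_subject_windows_collapse_to_nt(self, rng):
        h = np.abs(rng.standard_normal((3, 101 * 5 * 3)))  # 3 subjects x 5 cycles
        assert average_activation_profile(h, 101).shape == (3, 101)

    def test_indivisible_column_count_rejected(self, rng):
        with pytest.raises(DataError):
            average_activation_profile(np.ones((2, 100)), 101)
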
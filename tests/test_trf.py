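import numpy as np
import pytest

import speechtrf as st
from speechtrf.core import EstimationError, LagGrid
from speechtrf.trf import _basis_matrix

from conftest import RECOVERY_BOOST


@pytest.fixture(scope="module")
def grid():
    return LagGrid.from_range(100.0)


class TestLagGrid:
    def test_k_is_51_at_100hz(self, grid):
        assert grid.K == 51
        assert grid.lags_ms[0] == -100 and grid.lags_ms[-1] == 400
        assert 0.0 in grid.lags_ms

    def test_nonuniform_rejected(self):
        with pytest.raises(ValueError):
            LagGrid(np.array([0.0, 10.0, 30.0]))


class TestBuildLagMatrix:
    def test_impulse_at_lag_zero(self, grid):
        x = np.zeros(60)
        x[10] = 1.0
        X = st.build_lag_matrix(st.EnvelopeSeries(x, fs=100), grid)
        k0 = int(np.flatnonzero(grid.lags_ms == 0.0)[0])
        assert X[k0, 10] == 1.0
        assert X[k0].sum() == 1.0

    def test_positive_lag_shifts_forward(self, grid):
        x = np.zeros(60)
        x[10] = 1.0
        X = st.build_lag_matrix(st.EnvelopeSeries(x, fs=100), grid)
        k10 = int(np.flatnonzero(grid.lags_ms == 10.0)[0])
        assert X[k10, 11] == 1.0

    def test_matvec_matches_nested_loop_convolution(self, grid):
        # brute-force oracle on a 50-sample series... padded to meet T >= K
        rng = np.random.default_rng(0)
        x = rng.random(60)
        beta = rng.standard_normal(grid.K)
        X = st.build_lag_matrix(st.EnvelopeSeries(x, fs=100), grid)
        got = beta @ X
        lag_samp = grid.lag_samples(100.0)
        expected = np.zeros(x.size)
        for t in range(x.size):
            for k, lag in enumerate(lag_samp):
                if 0 <= t - lag < x.size:
                    expected[t] += beta[k] * x[t - lag]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_too_short_rejected(self, grid):
        with pytest.raises(ValueError):
            st.build_lag_matrix(st.EnvelopeSeries(np.ones(20), fs=100), grid)


class TestPredictEEG:
    def _trf(self, grid, coef):
        return st.TRFSet(coefficients=coef, lag_grid=grid,
                         predictor_roles=("target", "masker"), fs=100.0)

    def test_zero_trf_zero_prediction(self, grid, noisefree_trial):
        coef = np.zeros((4, 2, grid.K))
        pred = st.predict_eeg(self._trf(grid, coef),
                              (noisefree_trial.target_env,
                               noisefree_trial.masker_env))
        np.testing.assert_array_equal(pred.predicted.data, 0.0)

    def test_unit_lag_zero_coefficient_reproduces_envelope(
            self, grid, noisefree_trial):
        coef = np.zeros((4, 2, grid.K))
        k0 = int(np.flatnonzero(grid.lags_ms == 0.0)[0])
        coef[:, 0, k0] = 1.0
        pred = st.predict_eeg(self._trf(grid, coef),
                              (noisefree_trial.target_env,
                               noisefree_trial.masker_env))
        for ch in range(4):
            np.testing.assert_allclose(pred.predicted.data[ch],
                                       noisefree_trial.target_env.data)

    def test_matches_nested_loop_oracle(self, grid):
        rng = np.random.default_rng(5)
        T = 120
        envs = (st.EnvelopeSeries(rng.random(T), fs=100, role="target"),
                st.EnvelopeSeries(rng.random(T), fs=100, role="masker"))
        coef = rng.standard_normal((2, 2, grid.K))
        pred = st.predict_eeg(self._trf(grid, coef), envs)
        lag_samp = grid.lag_samples(100.0)
        expected = np.zeros((2, T))
        for ch in range(2):
            for p, env in enumerate(envs):
                for t in range(T):
                    for k, lag in enumerate(lag_samp):
                        if 0 <= t - lag < T:
                            expected[ch, t] += coef[ch, p, k] * \
                                env.data[t - lag]
        np.testing.assert_allclose(pred.predicted.data, expected, atol=1e-10)

    def test_residual_reconstructs_input(self, grid, noisefree_trial):
        rng = np.random.default_rng(2)
        coef = rng.standard_normal((4, 2, grid.K))
        pred = st.predict_eeg(self._trf(grid, coef),
                              (noisefree_trial.target_env,
                               noisefree_trial.masker_env),
                              measured=noisefree_trial.observed_eeg)
        np.testing.assert_allclose(
            pred.predicted.data + pred.residual,
            noisefree_trial.observed_eeg.data, atol=1e-12)

    def test_rate_mismatch(self, grid):
        coef = np.zeros((1, 1, grid.K))
        trf = st.TRFSet(coefficients=coef, lag_grid=grid,
                        predictor_roles=("target",), fs=100.0)
        env = st.EnvelopeSeries(np.ones(200), fs=50.0, role="target")
        with pytest.raises(ValueError):
            st.predict_eeg(trf, (env,))


class TestBoostTRF:
    def test_zero_eeg_gives_zero_trf(self, noisefree_trial):
        eeg = noisefree_trial.observed_eeg.with_data(
            np.zeros_like(noisefree_trial.observed_eeg.data))
        est = st.boost_trf(eeg, (noisefree_trial.target_env,
                                 noisefree_trial.masker_env),
                           st.BoostConfig(max_iters=50))
        np.testing.assert_array_equal(est.coefficients, 0.0)

    def test_constant_envelope_rejected(self, noisefree_trial):
        env = st.EnvelopeSeries(np.ones(noisefree_trial.target_env.n_samples),
                                fs=100, role="target")
        with pytest.raises(EstimationError):
            st.boost_trf(noisefree_trial.observed_eeg,
                         (env, noisefree_trial.masker_env))

    def test_nan_rejected(self, noisefree_trial):
        data = noisefree_trial.observed_eeg.data.copy()
        data[0, 0] = np.nan
        with pytest.raises(ValueError):
            st.boost_trf(noisefree_trial.observed_eeg.with_data(data),
                         (noisefree_trial.target_env,
                          noisefree_trial.masker_env))

    def test_noiseless_recovery(self, small_config, ground_truth,
                                noisefree_trial):
        est = st.boost_trf(noisefree_trial.observed_eeg,
                           (noisefree_trial.target_env,
                            noisefree_trial.masker_env), RECOVERY_BOOST)
        tg, mg, _ = small_config.condition_params["NR_on"]
        truth = np.stack([tg * ground_truth.kernel, mg * ground_truth.kernel],
                         axis=1)
        for ch in range(small_config.n_channels):
            r = np.corrcoef(est.coefficients[ch].ravel(),
                            truth[ch].ravel())[0, 1]
            assert r >= 0.9

    def test_prediction_beats_zero_model(self, noisefree_trial):
        est = st.boost_trf(noisefree_trial.observed_eeg,
                           (noisefree_trial.target_env,
                            noisefree_trial.masker_env),
                           st.BoostConfig(max_iters=300))
        pred = st.predict_eeg(est, (noisefree_trial.target_env,
                                    noisefree_trial.masker_env),
                              measured=noisefree_trial.observed_eeg)
        zero_mse = np.mean(noisefree_trial.observed_eeg.data ** 2, axis=1)
        assert np.all(pred.mse_per_channel <= zero_mse)


class TestNoisePairing:
    def _trials(self, n_trials=3, n_subjects=1):
        cfg = st.SimulationConfig(
            n_subjects=n_subjects, n_trials_per_condition=n_trials,
            conditions=("NR_on",), n_channels=2, trial_duration=5.0,
            condition_params={"NR_on": (1.0, 0.3, 0.5)}, seed=4)
        return list(st.gen_dataset(cfg))

    def test_circular_shift_no_fixed_points(self):
        trials = self._trials(3)
        pairs = st.make_noise_pairing(trials)
        for t, (eeg, tgt, _) in zip(trials, pairs):
            assert eeg is t.observed_eeg
            assert not np.array_equal(tgt.data, t.target_env.data)

    def test_bijection(self):
        trials = self._trials(4)
        pairs = st.make_noise_pairing(trials)
        used = [id(tgt) for _, tgt, _ in pairs]
        assert len(set(used)) == len(trials)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            st.make_noise_pairing(self._trials(1))

    def test_mismatched_trf_much_smaller(self):
        # simulation oracle: noise-TRF peaks < 50% of matched-TRF peaks
        trials = self._trials(5)
        bc = st.BoostConfig(basis_width_ms=100, max_iters=1000)
        matched, mismatched = [], []
        for t, (eeg, tgt, msk) in zip(trials, st.make_noise_pairing(trials)):
            m = st.boost_trf(t.observed_eeg, (t.target_env, t.masker_env), bc)
            n = st.boost_trf(eeg, (tgt, msk), bc)
            matched.append(np.abs(m.coefficients[:, 0, :]).max(axis=1))
            mismatched.append(np.abs(n.coefficients[:, 0, :]).max(axis=1))
        assert np.all(np.mean(mismatched, axis=0)
                      < 0.5 * np.mean(matched, axis=0))


def test_basis_matrix_is_hamming_taper():
    grid = LagGrid.from_range(100.0)
    B = _basis_matrix(grid, 100.0, width_ms=50.0)
    row = B[25]
    support = np.flatnonzero(row)
    assert support.size == 5  # 50 ms at 100 Hz
    np.testing.assert_allclose(row[support], np.hamming(5))
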
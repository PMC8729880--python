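"""TRF estimation: design matrices, ridge solutions, cross-correlation, CV."""

import numpy as np
import pytest
from sklearn.base import clone

from speechtrf import encoding as enc
from speechtrf import synthgen as sg
from speechtrf.containers import EEGRecording, FeatureSeries


class TestLaggedDesign:
    def test_single_zero_lag_is_identity(self):
        x = np.arange(10.0)
        f = FeatureSeries(x, 100.0, label="f")
        des0 = enc.build_lagged_design([[f]], -0.0001, 0.0001)
        assert des0.trials[0].shape == (10, 1)
        assert np.array_equal(des0.trials[0][:, 0], x)

    def test_impulse_shifts(self):
        x = np.zeros(9)
        x[4] = 1.0
        f = FeatureSeries(x, 100.0, label="f")
        des = enc.build_lagged_design([[f]], -0.02, 0.02)
        assert des.trials[0].shape == (9, 5)
        for col, lag in enumerate(range(-2, 3)):
            expected = np.zeros(9)
            expected[4 + lag] = 1.0
            assert np.array_equal(des.trials[0][:, col], expected)

    def test_subcortical_window_has_125_columns(self):
        x = np.zeros(4096)
        f = FeatureSeries(x, 4096.0, label="f")
        des = enc.build_lagged_design([[f]], *enc.SUBCORTICAL_LAG_WINDOW)
        assert des.trials[0].shape[1] == 125

    def test_lag_span_exceeding_trial(self):
        f = FeatureSeries(np.zeros(10), 4096.0, label="f")
        with pytest.raises(ValueError):
            enc.build_lagged_design([[f]], -0.00513, 0.02515)


class TestFitRidge:
    def test_ols_recovers_kernel(self, white_trial):
        feature, h, eeg = white_trial
        des = enc.build_lagged_design([[feature]], 0.0, 0.029)
        trf = enc.fit_ridge(des, eeg, 0.0)
        assert np.abs(trf.weights[0, 0] - h).max() < 1e-6 * np.abs(h).max()

    def test_matches_brute_force_solve(self):
        """Normal-equation oracle on random small systems (1e-10 relative)."""
        r = np.random.default_rng(11)
        for _ in range(20):
            n, p = 60, int(r.integers(2, 30))
            X = r.standard_normal((n, p))
            y = r.standard_normal(n)
            lam = float(r.choice([0.0, 1e-3, 1.0, 100.0]))
            est = enc.TRFRidge(alpha=lam).fit(X, y)
            beta = np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ y)
            assert np.abs(est.coef_[:, 0] - beta).max() <= 1e-10 * max(
                1.0, np.abs(beta).max())

    def test_large_lambda_limit_is_cross_correlation(self, white_trial):
        feature, _, eeg = white_trial
        des = enc.build_lagged_design([[feature]], 0.0, 0.029)
        trf = enc.fit_ridge(des, eeg, 1e9)
        xty = des.trials[0].T @ eeg.trials[0][0]
        r = np.corrcoef(trf.weights[0, 0], xty)[0, 1]
        assert r > 0.999

    def test_lambda_continuity_at_zero(self, white_trial):
        feature, _, eeg = white_trial
        des = enc.build_lagged_design([[feature]], 0.0, 0.029)
        w0 = enc.fit_ridge(des, eeg, 0.0).weights
        w1 = enc.fit_ridge(des, eeg, 1e-12).weights
        assert np.abs(w0 - w1).max() <= 1e-6 * np.abs(w0).max()

    def test_estimator_is_sklearn_compatible(self):
        est = enc.TRFRidge(alpha=3.0)
        assert est.get_params() == {"alpha": 3.0}
        est2 = clone(est).set_params(alpha=1.0)
        assert est2.get_params()["alpha"] == 1.0
        r = np.random.default_rng(0)
        X, y = r.standard_normal((50, 4)), r.standard_normal(50)
        est2.fit(X, y)
        assert est2.coef_.shape == (4, 1)
        assert est2.predict(X).shape == (50,)


class TestFastNormalEquations:
    def test_gram_equals_explicit_design(self):
        r = np.random.default_rng(21)
        for lagw in [(-0.02, 0.05), (0.005, 0.04), (-0.03, -0.001)]:
            xs = [r.standard_normal(150) for _ in range(2)]
            feats = [FeatureSeries(x, 1000.0, label=f"f{i}")
                     for i, x in enumerate(xs)]
            des = enc.build_lagged_design([feats], *lagw)
            X = des.trials[0]
            lags = enc.lag_indices(*lagw, 1000.0)
            assert np.allclose(enc.lagged_gram(xs, lags), X.T @ X,
                               rtol=1e-8, atol=1e-8)
            y = r.standard_normal(150)
            assert np.allclose(enc.lagged_xty(xs, y, lags), X.T @ y,
                               rtol=1e-8, atol=1e-8)
            w = r.standard_normal((2, lags.size))
            assert np.allclose(enc.lagged_predict(xs, w, lags),
                               X @ w.reshape(-1), rtol=1e-8, atol=1e-8)


class TestComplexCrossCorrelation:
    def test_pure_delay_peak(self):
        r = np.random.default_rng(5)
        x = r.standard_normal(4000)
        d = 23
        y = np.concatenate([np.zeros(d), x[:-d]])
        resp = enc.cross_correlate_complex(FeatureSeries(x, 1000.0), y,
                                           -0.01, 0.05)
        lag_samples = np.round(resp.lag_axis * 1000.0).astype(int)
        assert abs(lag_samples[np.argmax(resp.magnitude)] - d) <= 1

    def test_magnitude_dominates_components(self):
        r = np.random.default_rng(6)
        x, y = r.standard_normal(1000), r.standard_normal(1000)
        resp = enc.cross_correlate_complex(FeatureSeries(x, 1000.0), y,
                                           -0.02, 0.02)
        assert np.all(resp.magnitude >= np.abs(resp.real) - 1e-12)
        assert np.all(resp.magnitude >= np.abs(resp.imag) - 1e-12)

    def test_cosine_flat_magnitude_oscillating_real(self):
        t = np.arange(4000) / 1000.0
        x = np.cos(2 * np.pi * 5.0 * t)
        resp = enc.cross_correlate_complex(FeatureSeries(x, 1000.0), x.copy(),
                                           -0.15, 0.15)
        interior = slice(20, -20)
        mag = resp.magnitude[interior]
        assert mag.max() - mag.min() <= 0.05 * mag.max()
        # real part oscillates at the stimulus frequency over lags
        assert np.sum(np.diff(np.sign(resp.real[interior])) != 0) >= 2

    def test_zero_eeg_gives_zeros(self):
        x = np.random.default_rng(7).standard_normal(500)
        resp = enc.cross_correlate_complex(FeatureSeries(x, 1000.0),
                                           np.zeros(500), -0.01, 0.01)
        assert np.all(resp.magnitude == 0.0)

    def test_zero_variance_feature_rejected(self):
        with pytest.raises(ValueError):
            enc.cross_correlate_complex(FeatureSeries(np.ones(100), 1000.0),
                                        np.zeros(100), -0.01, 0.01)

    def test_positive_scaling_invariance(self):
        r = np.random.default_rng(8)
        x = r.standard_normal(2000)
        y = np.concatenate([np.zeros(10), x[:-10]])
        a = enc.cross_correlate_complex(FeatureSeries(x, 1000.0), y, 0.0, 0.03)
        b = enc.cross_correlate_complex(FeatureSeries(5.0 * x, 1000.0), y,
                                        0.0, 0.03)
        assert np.argmax(a.magnitude) == np.argmax(b.magnitude)
        assert np.allclose(a.magnitude, b.magnitude)  # normalized


class TestPredictAndScore:
    def test_refit_on_training_data_is_perfect(self, white_trial):
        feature, _, eeg = white_trial
        des = enc.build_lagged_design([[feature]], 0.0, 0.029)
        trf = enc.fit_ridge(des, eeg, 0.0)
        res = enc.predict_and_score(trf, des, eeg)
        assert res.per_trial[0, 0] > 0.999

    def test_zero_weights_flagged(self, white_trial):
        feature, _, eeg = white_trial
        des = enc.build_lagged_design([[feature]], 0.0, 0.029)
        trf = enc.fit_ridge(des, eeg, 0.0)
        trf.weights[:] = 0.0
        res = enc.predict_and_score(trf, des, eeg)
        assert res.per_trial[0, 0] == 0.0
        assert res.flags[0, 0]

    def test_accuracy_decreases_with_noise(self):
        r = np.random.default_rng(9)
        k = sg.default_subcortical_kernel(4096.0)
        x = r.standard_normal(4096 * 5)
        f = FeatureSeries(x, 4096.0, label="f")
        scores = []
        for snr in [0.0, -10.0, -20.0, -30.0]:
            rec = sg.synthesize_eeg([f], [k], snr_db=snr, seed=17)
            des = enc.build_lagged_design([[f]], 0.0, 0.03)
            trf = enc.fit_ridge(des, eeg=rec, lam=0.0)
            scores.append(enc.predict_and_score(trf, des, rec).per_trial[0, 0])
        from scipy import stats as sp_stats
        # accuracy falls monotonically as SNR falls
        rho = sp_stats.spearmanr(scores, [0, -10, -20, -30]).statistic
        assert rho > 0.9
        assert scores[0] > scores[-1]


class TestCrossValidation:
    @staticmethod
    def _session(n_trials=6, snr_db=np.inf, seed=0, n=800):
        r = np.random.default_rng(seed)
        k = sg.default_cortical_envelope_kernel(64.0)
        feats, trials = [], []
        for i in range(n_trials):
            x = r.standard_normal(n)
            s = np.convolve(x, k.amplitude)[:n]
            if np.isinf(snr_db):
                y = s
            else:
                nz = sg.make_pink_noise(n, 1, seed=100 + i)[0]
                y = s + nz * np.sqrt(s.var() / 10 ** (snr_db / 10))
            feats.append([FeatureSeries(x, 64.0, label="env")])
            trials.append(y[None, :])
        return feats, EEGRecording(trials, 64.0, ["Cz"])

    def test_singleton_grid_reduces_to_train_test(self):
        feats, eeg = self._session()
        trf = enc.nested_cv_fit(feats, eeg, lambda_grid=[1.0], n_outer=2,
                                n_inner=1, seed=0)
        assert trf.lam == 1.0
        assert trf.cv_accuracy.shape == (1,)

    def test_noiseless_selects_grid_minimum(self):
        # score on all lags so the no-noise ridge-bias argument applies
        feats, eeg = self._session(snr_db=np.inf)
        trf = enc.nested_cv_fit(feats, eeg, lambda_grid=[1e-4, 1e2, 1e8],
                                fit_lag_window=(-0.4, 0.9),
                                n_outer=3, n_inner=2, seed=1)
        assert trf.lam == pytest.approx(1e-4)

    def test_autocorrelated_feature_selects_higher_lambda(self):
        """With a smoothed feature and noise, the selected ridge strength
        exceeds the grid minimum in most seeded runs."""
        from scipy.ndimage import gaussian_filter1d
        k = sg.default_cortical_envelope_kernel(64.0)
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            r = np.random.default_rng(300 + rep)
            feats, trials = [], []
            for i in range(6):
                x = gaussian_filter1d(r.standard_normal(800), 4.0)
                x = (x - x.mean()) / x.std()
                s = np.convolve(x, k.amplitude)[:800]
                nz = sg.make_pink_noise(800, 1, seed=500 + 10 * rep + i)[0]
                y = s + nz * np.sqrt(s.var() / 10 ** (-5.0 / 10))
                feats.append([FeatureSeries(x, 64.0, label="env")])
                trials.append(y[None, :])
            eeg = EEGRecording(trials, 64.0, ["Cz"])
            trf = enc.nested_cv_fit(feats, eeg,
                                    lambda_grid=np.logspace(-4, 8, 7),
                                    n_outer=2, n_inner=2, seed=rep)
            if trf.lam > 1e-4:
                hits += 1
        assert hits >= 0.8 * n_rep

    def test_too_few_trials_rejected(self):
        feats, eeg = self._session(n_trials=3)
        with pytest.raises(ValueError):
            enc.nested_cv_fit(feats, eeg)

    def test_loo_identical_trials_perfect(self):
        r = np.random.default_rng(31)
        x = r.standard_normal(600)
        k = sg.default_cortical_envelope_kernel(64.0)
        y = np.convolve(x, k.amplitude)[:600]
        feats = [[FeatureSeries(x, 64.0, label="f")]] * 2
        eeg = EEGRecording([y[None, :]] * 2, 64.0, ["Cz"])
        trf = enc.loo_cv_fit(feats, eeg, lag_window=(0.0, 0.4))
        assert trf.cv_accuracy[0] > 0.999

    def test_loo_not_better_than_training_fit(self):
        feats, eeg = self._session(n_trials=5, snr_db=-5.0, seed=3)
        trf = enc.loo_cv_fit(feats, eeg, lag_window=(0.0, 0.4))
        des = enc.build_lagged_design(feats, 0.0, 0.4)
        full = enc.fit_ridge(des, eeg, 0.0)
        train_score = enc.predict_and_score(full, des, eeg).mean[0]
        assert trf.cv_accuracy[0] <= train_score + 1e-9
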
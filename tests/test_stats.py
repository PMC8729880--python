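"""Peak extraction, permutation tests, correlations, B-Y FDR, comparisons."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h
from scipy import stats as sp_stats

from speechtrf import stats as st


class TestExtractPeak:
    lags = np.arange(0.0, 20.0, 0.5)  # ms

    def test_impulse_at_7ms(self):
        resp = np.zeros(self.lags.size)
        resp[self.lags == 7.0] = 1.0
        pk = st.extract_peak(resp, self.lags, (5.0, 11.0))
        assert pk.latency_ms == 7.0
        assert pk.amplitude == 1.0

    def test_monotone_series_peaks_at_boundary(self):
        pk = st.extract_peak(self.lags * 0.1, self.lags, (5.0, 11.0))
        assert pk.latency_ms == 11.0

    def test_tie_breaks_to_earliest(self):
        resp = np.zeros(self.lags.size)
        resp[self.lags == 6.0] = 1.0
        resp[self.lags == 9.0] = 1.0
        pk = st.extract_peak(resp, self.lags, (5.0, 11.0))
        assert pk.latency_ms == 6.0

    def test_empty_window(self):
        with pytest.raises(ValueError):
            st.extract_peak(self.lags, self.lags, (100.0, 110.0))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st_h.floats(0.1, 100.0))
    def test_scale_equivariance(self, scale):
        r = np.random.default_rng(0)
        resp = r.standard_normal(self.lags.size)
        a = st.extract_peak(resp, self.lags, (5.0, 11.0))
        b = st.extract_peak(scale * resp, self.lags, (5.0, 11.0))
        assert b.latency_ms == a.latency_ms
        assert b.amplitude == pytest.approx(scale * a.amplitude)


class TestChannelAggregate:
    labels = ["Cz"] + list(st.FRONTAL6) + ["Pz"]

    def test_identical_channels(self):
        data = np.tile(np.arange(5.0), (len(self.labels), 1))
        assert np.array_equal(st.channel_aggregate(data, self.labels, "cz"),
                              np.arange(5.0))
        assert np.allclose(st.channel_aggregate(data, self.labels, "frontal6"),
                           np.arange(5.0))

    def test_frontal6_one_hot(self):
        data = np.zeros((len(self.labels), 4))
        data[self.labels.index("FC5"), 2] = 1.0
        agg = st.channel_aggregate(data, self.labels, "frontal6")
        assert agg[2] == pytest.approx(1.0 / 6.0)

    def test_cz_ignores_others(self):
        r = np.random.default_rng(1)
        data = r.standard_normal((len(self.labels), 10))
        out = st.channel_aggregate(data, self.labels, "cz")
        data2 = data.copy()
        data2[1:] = 0.0
        assert np.array_equal(
            out, st.channel_aggregate(data2, self.labels, "cz"))

    def test_missing_labels(self):
        with pytest.raises(KeyError):
            st.channel_aggregate(np.zeros((2, 3)), ["a", "b"], "frontal6")


class TestPairedPermutation:
    def test_equal_samples_give_p_one(self):
        a = np.arange(5.0)
        assert st.paired_permutation_test(a, a.copy()) == 1.0

    def test_exhaustive_matches_brute_force(self):
        r = np.random.default_rng(2)
        a = r.standard_normal(5)
        b = r.standard_normal(5)
        p = st.paired_permutation_test(a, b, alternative="greater")
        d = a - b
        obs = d.mean()
        null = [np.mean(s * d) for s in
                itertools.product([-1.0, 1.0], repeat=5)]
        expected = np.mean(np.asarray(null) >= obs - 1e-15)
        assert p == pytest.approx(expected)

    def test_type_one_error_calibrated(self):
        """Under exchangeability, rejections at alpha=0.05 stay inside the
        95% binomial interval over 500 null simulations."""
        rng = np.random.default_rng(7)
        n_sim, n = 500, 10
        rejections = 0
        for i in range(n_sim):
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            p = st.paired_permutation_test(a, b, seed=i)
            rejections += p <= 0.05
        rate = rejections / n_sim
        half = 1.96 * np.sqrt(0.05 * 0.95 / n_sim)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_dominant_difference_smallest_p(self):
        a = np.full(8, 1.0)
        b = np.zeros(8)
        p = st.paired_permutation_test(a, b)
        assert p == pytest.approx(1.0 / 2 ** 8)

    def test_less_alternative_mirrors_greater(self):
        r = np.random.default_rng(3)
        a, b = r.standard_normal(6), r.standard_normal(6)
        p_g = st.paired_permutation_test(a, b, alternative="greater")
        p_l = st.paired_permutation_test(b, a, alternative="less")
        assert p_g == pytest.approx(p_l)


class TestPearsonOneTailed:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        rho, p = st.pearson_corr_onetailed(x, 2 * x)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_negative_slope_greater_tail(self):
        x = np.arange(10.0)
        rho, p = st.pearson_corr_onetailed(x, -x + np.sin(x) * 0.01,
                                           alternative="greater")
        assert p >= 0.5

    def test_matches_closed_form_t(self):
        r = np.random.default_rng(4)
        x, y = r.standard_normal(10), r.standard_normal(10)
        rho, p = st.pearson_corr_onetailed(x, y)
        # independent brute-force computation
        n = 10
        rho2 = (np.sum((x - x.mean()) * (y - y.mean()))
                / np.sqrt(np.sum((x - x.mean()) ** 2)
                          * np.sum((y - y.mean()) ** 2)))
        t = rho2 * np.sqrt((n - 2) / (1 - rho2 ** 2))
        p2 = sp_stats.t.sf(t, n - 2)
        assert rho == pytest.approx(rho2, abs=1e-10)
        assert p == pytest.approx(p2, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            st.pearson_corr_onetailed(np.ones(5), np.arange(5.0))


def _brute_force_by(p):
    """Independent Benjamini-Yekutieli step-up implementation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    c = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    adj = ranked * m * c / np.arange(1, m + 1)
    # step-up: running minimum from the largest rank down
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestFdrBY:
    def test_single_p_unchanged(self):
        assert st.fdr_by([0.3])[0] == pytest.approx(0.3)

    def test_hand_computed_example(self):
        # m=3, c(3)=11/6; all three step up to 0.01*3*(11/6)/1 = 0.055
        adj = st.fdr_by([0.01, 0.02, 0.03])
        assert np.allclose(adj, 0.055)

    def test_never_below_input(self):
        r = np.random.default_rng(5)
        p = r.uniform(size=50)
        assert np.all(st.fdr_by(p) >= p - 1e-12)

    def test_matches_brute_force_on_random_vectors(self):
        r = np.random.default_rng(6)
        for _ in range(200):
            m = int(r.integers(1, 25))
            p = r.uniform(size=m)
            assert np.allclose(st.fdr_by(p), _brute_force_by(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.fdr_by([0.5, 1.2])


class TestCompareModels:
    def test_combined_equals_individual(self):
        a = np.array([0.1, 0.2, 0.3, 0.25])
        comp = st.compare_models(a, a, a)
        assert np.allclose(comp.improvement, 0.0)
        assert all(p == 1.0 for p in comp.p_values.values())

    def test_uniform_gain_smallest_p(self):
        r = np.random.default_rng(8)
        a = r.uniform(0.1, 0.3, size=8)
        b = r.uniform(0.1, 0.3, size=8)
        c = np.maximum(a, b) + 0.05
        comp = st.compare_models(a, b, c)
        assert np.allclose(comp.improvement, 0.05)
        floor = 1.0 / 2 ** 8
        assert comp.p_values["combined_gt_model_a"] == pytest.approx(floor)
        assert comp.p_values["combined_gt_model_b"] == pytest.approx(floor)

    def test_orthogonal_features_detected_at_moderate_snr(self):
        """With two orthogonal drivers at SNR -5 dB, the combined model
        significantly beats the best individual model in >= 90% of runs."""
        from speechtrf import synthgen as sg
        from speechtrf.encoding import lag_indices, lagged_gram, lagged_xty, _solve, lagged_predict, _safe_pearson

        k1 = sg.default_cortical_envelope_kernel(64.0)
        k2 = sg.default_cortical_pitch_kernel(64.0)
        lags = lag_indices(-0.1, 0.5, 64.0)
        wins = 0
        n_runs = 20
        for run in range(n_runs):
            rng = np.random.default_rng(900 + run)
            accs = {"a": [], "b": [], "c": []}
            for subj in range(6):
                x1, x2 = (rng.standard_normal(1280) for _ in range(2))
                s = (np.convolve(x1, k1.amplitude)[:1280]
                     + np.convolve(x2, k2.amplitude)[:1280])
                nz = sg.make_pink_noise(1280, 1, seed=10000 + 100 * run + subj)[0]
                split = 960
                y = s + nz * np.sqrt(s.var() / 10 ** (-5.0 / 10))
                for key, xs in [("a", [x1]), ("b", [x2]), ("c", [x1, x2])]:
                    xs_tr = [x[:split] for x in xs]
                    xs_te = [x[split:] for x in xs]
                    G = lagged_gram(xs_tr, lags)
                    U = lagged_xty(xs_tr, y[:split], lags)
                    w = _solve(G, U, 1.0).reshape(len(xs), -1)
                    pred = lagged_predict(xs_te, w, lags)
                    accs[key].append(_safe_pearson(pred, y[split:])[0])
            comp = st.compare_models(np.asarray(accs["a"]),
                                     np.asarray(accs["b"]),
                                     np.asarray(accs["c"]), seed=run)
            if max(comp.p_values["combined_gt_model_a"],
                   comp.p_values["combined_gt_model_b"]) < 0.05:
                wins += 1
        assert wins >= 0.9 * n_runs

    def test_mismatched_subjects_rejected(self):
        with pytest.raises(ValueError):
            st.compare_models(np.zeros(3), np.zeros(4), np.zeros(3))
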
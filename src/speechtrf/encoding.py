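"""Forward stimulus-response (TRF) estimation.

The central model is the regularized linear forward map

    beta = (X'X + lambda I)^{-1} X'Y

where X is the time-lagged stimulus feature matrix, Y the EEG of one
channel and lambda a ridge parameter. lambda = 0 is ordinary least squares;
as lambda grows the solution converges (up to scale) to the plain
cross-correlation X'Y. The complex cross-correlation pairs the lagged
correlation of a feature with the correlation of its quadrature (Hilbert
transform) as real and imaginary parts; its magnitude serves as the
response envelope over lags for frequency-following (F0) analyses.

X'X and X'Y are accumulated per trial and summed, so lagged windows never
leak across trial boundaries. A fast path computes the same normal
equations directly from the raw feature series via FFT cross-correlations
plus edge corrections — exactly equal (to float rounding) to the explicit
design-matrix products, but without materializing the design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from sklearn.base import BaseEstimator, RegressorMixin

from .containers import ComplexResponse, EEGRecording, FeatureSeries, TRFModel

__all__ = [
    "SUBCORTICAL_LAG_WINDOW",
    "CORTICAL_LAG_WINDOW",
    "CORTICAL_FIT_WINDOW",
    "SUBCORTICAL_FIT_WINDOW",
    "DEFAULT_LAMBDA_GRID",
    "LaggedDesign",
    "build_lagged_design",
    "lag_indices",
    "lagged_gram",
    "lagged_xty",
    "lagged_predict",
    "TRFRidge",
    "fit_ridge",
    "cross_correlate_complex",
    "average_complex_responses",
    "predict_and_score",
    "ScoreResult",
    "nested_cv_fit",
    "loo_cv_fit",
]

#: analysis lag windows in seconds (stimulus preceding response = positive)
SUBCORTICAL_LAG_WINDOW = (-0.00513, 0.02515)
CORTICAL_LAG_WINDOW = (-0.312, 0.812)
#: lag windows used when scoring candidate regularization strengths
CORTICAL_FIT_WINDOW = (0.047, 0.266)
SUBCORTICAL_FIT_WINDOW = (0.00244, 0.01221)
#: 17 log-spaced values spanning OLS-like to cross-correlation-like regimes
DEFAULT_LAMBDA_GRID = np.logspace(-4, 12, 17)


def lag_indices(lag_min: float, lag_max: float, rate: float) -> np.ndarray:
    """Inclusive integer sample lags for a window in seconds."""
    if not lag_min < lag_max:
        raise ValueError("lag_min must be below lag_max")
    return np.arange(int(round(lag_min * rate)), int(round(lag_max * rate)) + 1)


def _shift(x: np.ndarray, lag: int) -> np.ndarray:
    """x delayed by ``lag`` samples, zero-padded (positive lag = delay)."""
    out = np.zeros_like(x)
    if lag > 0:
        out[lag:] = x[:-lag]
    elif lag < 0:
        out[:lag] = x[-lag:]
    else:
        out[:] = x
    return out


@dataclass
class LaggedDesign:
    """Per-trial lagged design matrices (samples x lags*features)."""

    trials: list  # list of 2D arrays
    lag_axis: np.ndarray  # seconds, length n_lags
    feature_labels: list
    rate: float

    @property
    def n_lags(self) -> int:
        return self.lag_axis.size

    @property
    def n_features(self) -> int:
        return len(self.feature_labels)


def _normalize_features(features):
    """Accept [FeatureSeries,...] (one trial) or [[...], ...] (trials x
    features); return (list of trials, each a list of 1D arrays, labels, rate)."""
    if not features:
        raise ValueError("no features given")
    if isinstance(features[0], FeatureSeries):
        features = [features]
    rates = {f.rate for trial in features for f in trial}
    if len(rates) != 1:
        raise ValueError("all features must share the sampling rate")
    rate = rates.pop()
    labels = [f.label for f in features[0]]
    trials = []
    for trial in features:
        if len(trial) != len(labels):
            raise ValueError("inconsistent feature count across trials")
        lengths = {f.samples.size for f in trial}
        if len(lengths) != 1:
            raise ValueError("features within a trial must share length")
        trials.append([f.samples for f in trial])
    return trials, labels, rate


def build_lagged_design(features, lag_min: float, lag_max: float) -> LaggedDesign:
    """Explicit lagged design: one column block of shifted copies per feature."""
    trials, labels, rate = _normalize_features(features)
    lags = lag_indices(lag_min, lag_max, rate)
    for xs in trials:
        if lags.size > xs[0].size:
            raise ValueError("lag span exceeds trial length")
    mats = []
    for xs in trials:
        n = xs[0].size
        X = np.empty((n, len(xs) * lags.size))
        col = 0
        for x in xs:
            for lag in lags:
                X[:, col] = _shift(x, int(lag))
                col += 1
        mats.append(X)
    return LaggedDesign(trials=mats, lag_axis=lags / rate,
                        feature_labels=labels, rate=rate)


# ---------------------------------------------------------------------------
# fast normal equations for lagged designs
# ---------------------------------------------------------------------------

def _full_xcorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """c[d + n - 1] = sum_u a[u] * b[u + d] for d in [-(n-1), n-1]."""
    return sp_signal.fftconvolve(a[::-1], b)


def _block_gram(xi: np.ndarray, xj: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Exact X_i'X_j for zero-padded lagged blocks, without materializing X.

    For lag pair (l1, l2) with d = l1 - l2 the product is the full lag-d
    cross-correlation minus head/tail terms clipped off by the zero-padding;
    the clipped regions are at most ``max|lag|`` samples long.
    """
    n = xi.size
    m = lags.size
    lmin, lmax = int(lags[0]), int(lags[-1])
    dmin, dmax = lmin - lmax, lmax - lmin
    c = _full_xcorr(xi, xj)  # index d + n - 1

    # head/tail partial sums of p_d[u] = xi[u] * xj[u+d] near the edges
    edge = max(abs(lmin), abs(lmax), abs(dmin), abs(dmax)) + 1
    n_d = dmax - dmin + 1
    head = np.zeros((n_d, edge + 1))  # head[k, j] = sum_{u < j, valid} p_d[u]
    tail = np.zeros((n_d, edge + 1))  # tail[k, j] = sum_{u > n-1-j, valid} p_d[u]
    for k, d in enumerate(range(dmin, dmax + 1)):
        u0, u1 = max(0, -d), n - 1 - max(0, d)
        he = min(edge, u1 - u0 + 1)
        if he > 0:
            u = np.arange(u0, u0 + he)
            head[k, 1:he + 1] = np.cumsum(xi[u] * xj[u + d])
            head[k, he + 1:] = head[k, he]
            u = np.arange(u1 - he + 1, u1 + 1)
            tail[k, 1:he + 1] = np.cumsum((xi[u] * xj[u + d])[::-1])
            tail[k, he + 1:] = tail[k, he]

    l1 = lags[:, None].astype(int)
    l2 = lags[None, :].astype(int)
    d = l1 - l2
    u_lo = np.maximum.reduce([np.zeros_like(d), -l1 + 0 * d, -d])
    u_hi = (n - 1) - np.maximum.reduce([np.zeros_like(d), l1 + 0 * d, d])
    u0 = np.maximum(0, -d)
    u1 = (n - 1) - np.maximum(0, d)
    k = d - dmin
    # elements removed from the head: u in [u0, u_lo - 1] -> count u_lo - u0
    head_cnt = np.clip(u_lo - u0, 0, edge)
    tail_cnt = np.clip(u1 - u_hi, 0, edge)
    G = c[d + n - 1] - head[k, head_cnt] - tail[k, tail_cnt]
    return G


def lagged_gram(xs, lags: np.ndarray) -> np.ndarray:
    """X'X of the lagged design for feature arrays ``xs`` (one trial)."""
    nf = len(xs)
    m = lags.size
    G = np.empty((nf * m, nf * m))
    for i in range(nf):
        for j in range(i, nf):
            B = _block_gram(xs[i], xs[j], lags)
            G[i * m:(i + 1) * m, j * m:(j + 1) * m] = B
            if j != i:
                G[j * m:(j + 1) * m, i * m:(i + 1) * m] = B.T
    return G


def lagged_xty(xs, y: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """X'y for a trial; y may be (n,) or (n, n_channels)."""
    y2 = y[:, None] if y.ndim == 1 else y
    n = xs[0].size
    cols = []
    for x in xs:
        c = np.stack([_full_xcorr(x, y2[:, ch]) for ch in range(y2.shape[1])], axis=1)
        cols.append(c[lags + n - 1])
    out = np.concatenate(cols, axis=0)
    return out[:, 0] if y.ndim == 1 else out


def lagged_predict(xs, weights: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Design @ weights without materializing the design.

    ``weights`` is (n_features, n_lags); returns the predicted trace (n,).
    """
    n = xs[0].size
    lmin = int(lags[0])
    pred = np.zeros(n)
    for x, w in zip(xs, weights):
        full = sp_signal.fftconvolve(x, w)
        t = np.arange(n)
        k = t - lmin
        ok = (k >= 0) & (k < full.size)
        pred[t[ok]] += full[k[ok]]
    return pred


def _solve(G: np.ndarray, U: np.ndarray, lam: float) -> np.ndarray:
    A = G if lam == 0 else G + lam * np.eye(G.shape[0])
    try:
        return np.linalg.solve(A, U)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, U, rcond=None)[0]


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class TRFRidge(RegressorMixin, BaseEstimator):
    """Ridge regression on (lagged) design matrices, trial-aware.

    Parameters
    ----------
    alpha : float
        Ridge regularization strength (the lambda in
        ``(X'X + lambda I)^{-1} X'Y``). 0 gives ordinary least squares.

    ``fit`` accepts a single 2D matrix and target, or lists of per-trial
    matrices/targets, in which case the normal equations are accumulated
    across trials before a single solve (no cross-trial lag leakage).

    Attributes
    ----------
    coef_ : ndarray of shape (n_columns, n_targets)
    n_features_in_ : int
    """

    def __init__(self, alpha: float = 0.0):
        self.alpha = alpha

    @staticmethod
    def _as_trials(X, y):
        if isinstance(X, (list, tuple)):
            Xs = [np.asarray(x, dtype=np.float64) for x in X]
            ys = [np.asarray(t, dtype=np.float64) for t in y]
        else:
            Xs = [np.asarray(X, dtype=np.float64)]
            ys = [np.asarray(y, dtype=np.float64)]
        ys = [t[:, None] if t.ndim == 1 else t for t in ys]
        for x, t in zip(Xs, ys):
            if x.ndim != 2:
                raise ValueError("each design must be 2D")
            if x.shape[0] != t.shape[0]:
                raise ValueError("design rows must match target samples")
        return Xs, ys

    def fit(self, X, y):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        Xs, ys = self._as_trials(X, y)
        p = Xs[0].shape[1]
        G = np.zeros((p, p))
        U = np.zeros((p, ys[0].shape[1]))
        for x, t in zip(Xs, ys):
            if x.shape[1] != p:
                raise ValueError("inconsistent column count across trials")
            G += x.T @ x
            U += x.T @ t
        self.coef_ = _solve(G, U, float(self.alpha))
        self.n_features_in_ = p
        self._single_target = (np.asarray(y[0] if isinstance(y, (list, tuple)) else y).ndim == 1)
        return self

    def fit_gram(self, G: np.ndarray, U: np.ndarray):
        """Fit from precomputed normal equations (X'X, X'Y)."""
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        U = U[:, None] if U.ndim == 1 else U
        self.coef_ = _solve(np.asarray(G, dtype=np.float64),
                            np.asarray(U, dtype=np.float64), float(self.alpha))
        self.n_features_in_ = G.shape[0]
        self._single_target = False
        return self

    def predict(self, X):
        if isinstance(X, (list, tuple)):
            return [self.predict(x) for x in X]
        pred = np.asarray(X, dtype=np.float64) @ self.coef_
        return pred[:, 0] if getattr(self, "_single_target", False) else pred

    def score(self, X, y):
        """Mean Pearson correlation between prediction and target."""
        Xs, ys = self._as_trials(X, y)
        rs = []
        for x, t in zip(Xs, ys):
            pred = x @ self.coef_
            for ch in range(t.shape[1]):
                r, _ = _safe_pearson(pred[:, ch], t[:, ch])
                rs.append(r)
        return float(np.mean(rs))


def _safe_pearson(a: np.ndarray, b: np.ndarray):
    """(r, flagged): r = 0 with flag when either input is constant."""
    sa, sb = a.std(), b.std()
    if sa < 1e-300 or sb < 1e-300:
        return 0.0, True
    r = float(np.dot(a - a.mean(), b - b.mean()) / (a.size * sa * sb))
    return r, False


def fit_ridge(design: LaggedDesign, eeg: EEGRecording, lam: float = 0.0) -> TRFModel:
    """Solve the regularized normal equations accumulated across trials."""
    if len(design.trials) != eeg.n_trials:
        raise ValueError("design and EEG trial counts differ")
    ys = [t.T for t in eeg.trials]  # samples x channels
    est = TRFRidge(alpha=lam).fit(list(design.trials), ys)
    n_ch = eeg.n_channels
    weights = est.coef_.T.reshape(n_ch, design.n_features, design.n_lags)
    return TRFModel(weights=weights, lam=float(lam), lag_axis=design.lag_axis,
                    rate=design.rate, feature_labels=list(design.feature_labels))


# ---------------------------------------------------------------------------
# complex cross-correlation
# ---------------------------------------------------------------------------

def cross_correlate_complex(feature, eeg_channel: np.ndarray, lag_min: float,
                            lag_max: float, rate: float | None = None) -> ComplexResponse:
    """Normalized complex cross-correlation over a lag window.

    The real part is the lagged correlation coefficient of the feature with
    the EEG trace; the imaginary part the same for the feature's quadrature
    (imaginary part of its analytic signal). Normalization by
    ``n * std(x) * std(y)`` makes the real part a per-lag correlation
    coefficient.
    """
    if isinstance(feature, FeatureSeries):
        x, rate = feature.samples, feature.rate
    else:
        if rate is None:
            raise ValueError("rate required when feature is a plain array")
        x = np.asarray(feature, dtype=np.float64)
    y = np.asarray(eeg_channel, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("feature and EEG must have equal length")
    lags = lag_indices(lag_min, lag_max, rate)
    xc = x - x.mean()
    sx = xc.std()
    if sx == 0:
        raise ValueError("zero-variance feature")
    yc = y - y.mean()
    sy = yc.std()
    n = x.size
    if sy == 0:
        z = np.zeros(lags.size)
        return ComplexResponse(lags / rate, z, z.copy())
    xq = np.imag(sp_signal.hilbert(xc))
    norm = n * sx * sy
    # real[l] = sum_t y[t] x[t-l] -> full cross-correlation at d = l
    cr = _full_xcorr(xc, yc)[lags + n - 1] / norm
    ci = _full_xcorr(xq, yc)[lags + n - 1] / norm
    return ComplexResponse(lags / rate, cr, ci)


def average_complex_responses(responses) -> ComplexResponse:
    """Phase-coherent average: mean real and imaginary parts across trials."""
    lag0 = responses[0].lag_axis
    for r in responses[1:]:
        if r.lag_axis.size != lag0.size or not np.allclose(r.lag_axis, lag0):
            raise ValueError("responses must share the lag axis")
    re = np.mean([r.real for r in responses], axis=0)
    im = np.mean([r.imag for r in responses], axis=0)
    return ComplexResponse(lag0.copy(), re, im)


# ---------------------------------------------------------------------------
# scoring and cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ScoreResult:
    """Per-trial/channel Pearson accuracies with degenerate-prediction flags."""

    per_trial: np.ndarray  # (n_trials, n_channels)
    flags: np.ndarray  # bool, same shape; True where r was undefined -> 0

    @property
    def mean(self) -> np.ndarray:
        """Mean across trials, per channel."""
        return self.per_trial.mean(axis=0)


def predict_and_score(trf: TRFModel, design: LaggedDesign,
                      eeg: EEGRecording) -> ScoreResult:
    """Predict each trial from the design and correlate with the EEG."""
    if len(design.trials) != eeg.n_trials:
        raise ValueError("design and EEG trial counts differ")
    n_ch = eeg.n_channels
    W = trf.weights.reshape(n_ch, -1)  # channels x columns
    scores = np.zeros((eeg.n_trials, n_ch))
    flags = np.zeros((eeg.n_trials, n_ch), dtype=bool)
    for ti, (X, t) in enumerate(zip(design.trials, eeg.trials)):
        pred = X @ W.T
        for ch in range(n_ch):
            scores[ti, ch], flags[ti, ch] = _safe_pearson(pred[:, ch], t[ch])
    return ScoreResult(per_trial=scores, flags=flags)


def _three_way_split(n_trials: int, rng: np.random.Generator,
                     fractions=(0.72, 0.18, 0.10)):
    """Shuffled train/validation/test indices (~72/18/10%)."""
    order = rng.permutation(n_trials)
    n_test = max(1, int(round(fractions[2] * n_trials)))
    n_val = max(1, int(round(fractions[1] * n_trials)))
    n_train = n_trials - n_test - n_val
    if n_train < 1:
        raise ValueError("too few trials for a 3-way split")
    return (order[:n_train], order[n_train:n_train + n_val],
            order[n_train + n_val:])


class _GramCache:
    """Per-trial normal equations for a fixed lag window."""

    def __init__(self, trials, labels, rate, lags, eeg: EEGRecording):
        self.xs = trials
        self.labels = labels
        self.rate = rate
        self.lags = lags
        self.eeg = eeg
        self.G = [lagged_gram(xs, lags) for xs in trials]
        self.U = [lagged_xty(xs, eeg.trials[i].T, lags)
                  for i, xs in enumerate(trials)]

    def accumulate(self, idx):
        G = sum(self.G[i] for i in idx)
        U = sum(self.U[i] for i in idx)
        return G, U

    def score(self, coef, idx, lag_mask=None):
        """Mean Pearson r over the given trials and all channels."""
        nf, m = len(self.labels), self.lags.size
        W = coef.T.reshape(-1, nf, m).copy()  # channels x features x lags
        if lag_mask is not None:
            W[:, :, ~lag_mask] = 0.0
        rs = []
        for i in idx:
            y = self.eeg.trials[i]
            for ch in range(y.shape[0]):
                pred = lagged_predict(self.xs[i], W[ch], self.lags)
                r, _ = _safe_pearson(pred, y[ch])
                rs.append(r)
        return float(np.mean(rs))

    def per_channel_scores(self, coef, idx):
        nf, m = len(self.labels), self.lags.size
        W = coef.T.reshape(-1, nf, m)
        n_ch = self.eeg.n_channels
        out = np.zeros((len(idx), n_ch))
        for k, i in enumerate(idx):
            y = self.eeg.trials[i]
            for ch in range(n_ch):
                pred = lagged_predict(self.xs[i], W[ch], self.lags)
                out[k, ch], _ = _safe_pearson(pred, y[ch])
        return out


def nested_cv_fit(features, eeg: EEGRecording, lambda_grid=None,
                  fit_lag_window=CORTICAL_FIT_WINDOW,
                  lag_window=CORTICAL_LAG_WINDOW, n_outer: int = 10,
                  n_inner: int = 5, seed: int = 0) -> TRFModel:
    """Three-way nested cross-validation of the ridge parameter.

    Trials are split ~72/18/10% into training/validation/test. For each of
    ``n_inner`` re-splits of the training+validation pool, every lambda on
    the grid is fit on the training trials and scored on the validation
    trials using only the lags inside ``fit_lag_window``; the lambda with
    the best mean validation correlation is then refit on training +
    validation and scored on the held-out test trials. The outer loop
    repeats ``n_outer`` times with re-randomized splits and the final
    weights are the mean over outer repeats.
    """
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    lambda_grid = np.atleast_1d(np.asarray(lambda_grid, dtype=float))
    if lambda_grid.size == 0:
        raise ValueError("lambda grid is empty")
    trials, labels, rate = _normalize_features(features)
    if len(trials) != eeg.n_trials:
        raise ValueError("feature and EEG trial counts differ")
    if len(trials) < 5:
        raise ValueError("nested cross-validation needs at least 5 trials")
    lags = lag_indices(*lag_window, rate)
    cache = _GramCache(trials, labels, rate, lags, eeg)
    lag_s = lags / rate
    window_mask = (lag_s >= fit_lag_window[0]) & (lag_s <= fit_lag_window[1])
    if not window_mask.any():
        window_mask = np.ones(lags.size, dtype=bool)

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xCF)))
    n_ch = eeg.n_channels
    weights_sum = np.zeros((n_ch, len(labels), lags.size))
    test_acc = np.zeros(n_ch)
    chosen = []
    for _ in range(n_outer):
        tr, va, te = _three_way_split(len(trials), rng)
        pool = np.concatenate([tr, va])
        if lambda_grid.size == 1:
            lam_star = float(lambda_grid[0])
        else:
            grid_scores = np.zeros(lambda_grid.size)
            for _ in range(n_inner):
                order = rng.permutation(pool)
                va_i = order[:va.size]
                tr_i = order[va.size:]
                G, U = cache.accumulate(tr_i)
                for li, lam in enumerate(lambda_grid):
                    coef = _solve(G, U, lam)
                    grid_scores[li] += cache.score(coef, va_i, window_mask)
            lam_star = float(lambda_grid[int(np.argmax(grid_scores))])
        chosen.append(lam_star)
        G, U = cache.accumulate(pool)
        coef = _solve(G, U, lam_star)
        weights_sum += coef.T.reshape(n_ch, len(labels), lags.size)
        test_acc += cache.per_channel_scores(coef, te).mean(axis=0)

    weights = weights_sum / n_outer
    lam_rep = float(np.exp(np.median(np.log(np.maximum(chosen, 1e-300)))))
    return TRFModel(weights=weights, lam=lam_rep, lag_axis=lag_s, rate=rate,
                    feature_labels=labels, cv_accuracy=test_acc / n_outer)


def loo_cv_fit(features, eeg: EEGRecording,
               lag_window=SUBCORTICAL_LAG_WINDOW) -> TRFModel:
    """Leave-one-trial-out OLS: fit on all-but-one, score the held-out trial,
    average the fold weights."""
    trials, labels, rate = _normalize_features(features)
    if len(trials) != eeg.n_trials:
        raise ValueError("feature and EEG trial counts differ")
    if len(trials) < 2:
        raise ValueError("leave-one-out needs at least 2 trials")
    lags = lag_indices(*lag_window, rate)
    cache = _GramCache(trials, labels, rate, lags, eeg)
    G_tot = sum(cache.G)
    U_tot = sum(cache.U)
    n_ch = eeg.n_channels
    weights_sum = np.zeros((n_ch, len(labels), lags.size))
    acc = np.zeros(n_ch)
    for i in range(len(trials)):
        coef = _solve(G_tot - cache.G[i], U_tot - cache.U[i], 0.0)
        weights_sum += coef.T.reshape(n_ch, len(labels), lags.size)
        acc += cache.per_channel_scores(coef, [i])[0]
    n = len(trials)
    return TRFModel(weights=weights_sum / n, lam=0.0, lag_axis=lags / rate,
                    rate=rate, feature_labels=labels, cv_accuracy=acc / n)
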
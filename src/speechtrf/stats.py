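"""Peak statistics, model comparison, permutation tests, FDR correction.

Response peaks are the maxima of a response trace inside pre-defined lag
windows (5–11 ms for subcortical wave-V-like responses; 100–210 ms for
cortical envelope and 50–160 ms for relative-pitch responses), read at the
vertex electrode Cz (subcortical) or the mean of six frontal electrodes
(cortical). Paired contrasts use sign-flip permutation tests on per-subject
differences; families of p-values are corrected with the Benjamini–
Yekutieli step-up procedure (valid under arbitrary dependence).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .containers import ModelComparison, PeakEstimate

__all__ = [
    "FRONTAL6",
    "extract_peak",
    "channel_aggregate",
    "paired_permutation_test",
    "pearson_corr_onetailed",
    "fdr_by",
    "compare_models",
    "PEAK_WINDOWS_MS",
]

FRONTAL6 = ("FC1", "FC2", "FC5", "FC6", "F3", "F4")

#: peak search windows in milliseconds per analysis
PEAK_WINDOWS_MS = {
    "subcortical": (5.0, 11.0),
    "cortical_envelope": (100.0, 210.0),
    "cortical_pitch": (50.0, 160.0),
}


def extract_peak(response: np.ndarray, lags_ms: np.ndarray, window_ms,
                 channel_set: str = "") -> PeakEstimate:
    """Maximum of the response inside the window; ties break to the earliest
    latency (argmax returns the first maximum)."""
    response = np.asarray(response, dtype=np.float64)
    lags_ms = np.asarray(lags_ms, dtype=np.float64)
    lo, hi = window_ms
    mask = (lags_ms >= lo) & (lags_ms <= hi)
    if not mask.any():
        raise ValueError("window contains no lag samples")
    seg = response[mask]
    seg_lags = lags_ms[mask]
    i = int(np.argmax(seg))
    return PeakEstimate(latency_ms=float(seg_lags[i]), amplitude=float(seg[i]),
                        window_ms=(float(lo), float(hi)), channel_set=channel_set)


def channel_aggregate(data: np.ndarray, channel_labels, mode: str = "cz") -> np.ndarray:
    """Select Cz or average the six frontal electrodes along the channel axis."""
    data = np.asarray(data, dtype=np.float64)
    labels = list(channel_labels)
    if mode == "cz":
        try:
            return data[labels.index("Cz")]
        except ValueError:
            raise KeyError("channel 'Cz' not present") from None
    if mode == "frontal6":
        missing = [l for l in FRONTAL6 if l not in labels]
        if missing:
            raise KeyError(f"missing frontal electrodes: {missing}")
        idx = [labels.index(l) for l in FRONTAL6]
        return data[idx].mean(axis=0)
    raise ValueError("mode must be 'cz' or 'frontal6'")


def paired_permutation_test(a, b, n_perm: int = 10000,
                            alternative: str = "greater", seed: int = 0,
                            exhaustive_limit: int = 65536) -> float:
    """Sign-flip permutation test on paired differences.

    The statistic is ``mean(a - b)``; the null distribution flips the sign
    of each subject's difference. When ``2**n <= exhaustive_limit`` all sign
    patterns are enumerated (exact p); otherwise ``n_perm`` random flips are
    drawn and ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("a and b must be equal-length 1D arrays, n >= 2")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError("alternative must be greater, less or two-sided")
    d = a - b
    if alternative == "less":
        d = -d
    obs = d.mean()
    n = d.size
    tol = 1e-12 * max(1.0, np.abs(d).max())
    if 2 ** n <= exhaustive_limit:
        bits = (np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]) & 1
        signs = 2 * bits - 1
        null = signs @ d / n
        if alternative == "two-sided":
            return float(np.mean(np.abs(null) >= np.abs(obs) - tol))
        return float(np.mean(null >= obs - tol))
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x9E12)))
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = signs @ d / n
    if alternative == "two-sided":
        hits = np.sum(np.abs(null) >= np.abs(obs) - tol)
    else:
        hits = np.sum(null >= obs - tol)
    return float((1 + hits) / (1 + n_perm))


def pearson_corr_onetailed(x, y, alternative: str = "greater"):
    """Pearson correlation with a one-tailed p from the t distribution.

    ``t = rho * sqrt((n-2) / (1-rho^2))`` with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    rho = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if abs(rho) >= 1.0:
        p = 0.0 if (rho > 0) == (alternative == "greater") else 1.0
        return rho, p
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = sp_stats.t.sf(t, df=n - 2) if alternative == "greater" \
        else sp_stats.t.cdf(t, df=n - 2)
    return rho, float(p)


def fdr_by(pvals) -> np.ndarray:
    """Benjamini–Yekutieli adjusted p-values (step-up with c(m) = sum 1/i)."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1D array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def compare_models(accuracy_a, accuracy_b, accuracy_combined,
                   labels=("model_a", "model_b"), n_perm: int = 10000,
                   seed: int = 0) -> ModelComparison:
    """Does the combined model out-predict each individual model?

    Improvements are computed per subject (combined minus the subject's best
    individual model). One-sided sign-flip permutation tests are run for
    combined > A, combined > B, and best(A,B) ordering; the family is
    corrected with Benjamini–Yekutieli FDR.
    """
    a = np.asarray(accuracy_a, dtype=np.float64)
    b = np.asarray(accuracy_b, dtype=np.float64)
    c = np.asarray(accuracy_combined, dtype=np.float64)
    if not (a.shape == b.shape == c.shape) or a.ndim != 1:
        raise ValueError("accuracy vectors must be 1D with matched subjects")
    best = np.maximum(a, b)
    improvement = c - best
    contrasts = {
        f"combined_gt_{labels[0]}": (c, a),
        f"combined_gt_{labels[1]}": (c, b),
        f"{labels[0]}_gt_{labels[1]}": (a, b),
    }
    p_raw = {}
    for k, (u, v) in contrasts.items():
        if np.allclose(u, v):
            p_raw[k] = 1.0
        else:
            p_raw[k] = paired_permutation_test(u, v, n_perm=n_perm,
                                               alternative="greater", seed=seed)
    keys = list(p_raw)
    adj = fdr_by(np.array([p_raw[k] for k in keys]))
    p_fdr = {k: float(v) for k, v in zip(keys, adj)}
    return ModelComparison(accuracy_a=a, accuracy_b=b, accuracy_combined=c,
                           improvement=improvement, p_values=p_raw,
                           p_values_fdr=p_fdr, n_permutations=n_perm,
                           seed=int(seed))
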
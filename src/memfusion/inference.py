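"""Jackknife onset-latency inference and group-level correlation tests.

Onset estimation follows the jackknife baseline-criteria technique: the
baseline standard deviation σ_b is computed from the grand-average series
over −200..0 ms (endpoint-exclusive); each leave-one-subject-out subsample
series is scanned for the first post-stimulus time point t where (1) the
value is ≥ 2·σ_b and (2) each of the 10 consecutive non-overlapping 50 ms
windows starting at t has mean ≥ 2·σ_b.  A condition is "not significant"
(N.S.) unless every subsample has such a time point.  Because jackknife
subsamples are strongly dependent, the standard error of the n subsample
onsets is inflated by (n − 1) — equivalently the variance by (n − 1)² —
before confidence intervals and t statistics are formed; the 95% CI uses the
two-tailed critical t at n − 1 degrees of freedom (2.145 at df = 14).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OnsetConfig",
    "OnsetResult",
    "jackknife_subsamples",
    "baseline_sd",
    "onset_detect",
    "estimate_onsets",
    "onset_summary",
    "latency_difference",
    "holm_correction",
    "roi_model_test",
]


@dataclass
class OnsetConfig:
    baseline_window: tuple = (-200.0, 0.0)  # endpoint-exclusive at 0
    sd_multiplier: float = 2.0
    window_ms: float = 50.0
    n_windows: int = 10
    criterion2: str = "each_window"  # "each_window" | "grand_mean" over the full span
    t_critical: float | None = None  # None -> two-tailed 95% critical t at df
    search_from_ms: float = 0.0

    def critical_t(self, df: int) -> float:
        if self.t_critical is not None:
            return self.t_critical
        return float(stats.t.ppf(0.975, df))


@dataclass
class OnsetResult:
    subsample_onsets: list = field(default_factory=list)  # ms or None per subsample
    mean_onset: float = np.nan
    ci95: tuple = (np.nan, np.nan)
    p_value: float = np.nan
    t_statistic: float = np.nan
    significant_timepoints: np.ndarray = None  # all subsamples pass, per time point
    ns_flag: bool = True
    n: int = 0


def jackknife_subsamples(series_matrix: np.ndarray) -> np.ndarray:
    """Leave-one-out mean series; row k averages all subjects except k."""
    series_matrix = np.asarray(series_matrix, dtype=float)
    n = series_matrix.shape[0]
    if n < 3:
        raise ValueError("jackknife needs >= 3 subjects")
    total = series_matrix.sum(axis=0, keepdims=True)
    return (total - series_matrix) / (n - 1)


def baseline_sd(series: np.ndarray, time_axis: np.ndarray, config: OnsetConfig) -> float:
    """SD of the series over the baseline window (population SD, ddof=0)."""
    time_axis = np.asarray(time_axis, dtype=float)
    sel = (time_axis >= config.baseline_window[0]) & (time_axis < config.baseline_window[1])
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    sd = float(np.std(np.asarray(series, dtype=float)[sel]))
    if sd == 0:
        raise ValueError("degenerate baseline: standard deviation is zero")
    return sd


def _passes_criteria(series, t_idx, threshold, w_samples, n_windows, criterion2):
    if series[t_idx] < threshold:
        return False
    span = series[t_idx : t_idx + n_windows * w_samples]
    if span.size < n_windows * w_samples:
        return False  # series does not cover the temporal criterion
    if criterion2 == "grand_mean":
        return span.mean() >= threshold
    windows = span.reshape(n_windows, w_samples)
    return bool(np.all(windows.mean(axis=1) >= threshold))


def onset_detect(series: np.ndarray, time_axis: np.ndarray, sigma_baseline: float, config: OnsetConfig | None = None) -> float | None:
    """First post-stimulus time (ms) meeting both baseline criteria, or None."""
    config = config or OnsetConfig()
    if sigma_baseline <= 0:
        raise ValueError("baseline SD must be positive")
    series = np.asarray(series, dtype=float)
    time_axis = np.asarray(time_axis, dtype=float)
    step = float(np.median(np.diff(time_axis)))
    w_samples = max(int(round(config.window_ms / step)), 1)
    threshold = config.sd_multiplier * sigma_baseline
    for t_idx in np.flatnonzero(time_axis >= config.search_from_ms):
        if _passes_criteria(series, t_idx, threshold, w_samples, config.n_windows, config.criterion2):
            return float(time_axis[t_idx])
    return None


def _significant_timepoints(subsamples, time_axis, threshold, w_samples, config):
    """Boolean series: time points where every subsample passes both criteria."""
    out = np.zeros(time_axis.size, dtype=bool)
    for t_idx in np.flatnonzero(time_axis >= config.search_from_ms):
        out[t_idx] = all(
            _passes_criteria(s, t_idx, threshold, w_samples, config.n_windows, config.criterion2)
            for s in subsamples
        )
    return out


def estimate_onsets(series_matrix: np.ndarray, time_axis: np.ndarray, config: OnsetConfig | None = None) -> OnsetResult:
    """Full jackknife onset inference for a subjects × time series matrix.

    σ_b comes from the grand-average series; onsets are detected per
    leave-one-out subsample and summarized with the (n − 1) variance
    correction.  ``ns_flag`` is set unless every subsample has an onset.
    """
    config = config or OnsetConfig()
    series_matrix = np.asarray(series_matrix, dtype=float)
    time_axis = np.asarray(time_axis, dtype=float)
    grand = series_matrix.mean(axis=0)
    sigma = baseline_sd(grand, time_axis, config)
    subsamples = jackknife_subsamples(series_matrix)
    onsets = [onset_detect(s, time_axis, sigma, config) for s in subsamples]

    step = float(np.median(np.diff(time_axis)))
    w_samples = max(int(round(config.window_ms / step)), 1)
    sig_tp = _significant_timepoints(subsamples, time_axis, config.sd_multiplier * sigma, w_samples, config)

    result = onset_summary(onsets, config)
    result.significant_timepoints = sig_tp
    return result


def onset_summary(subsample_onsets, config: OnsetConfig | None = None) -> OnsetResult:
    """Mean onset, jackknife-corrected 95% CI, and one-sided t test vs 0 ms."""
    config = config or OnsetConfig()
    onsets = list(subsample_onsets)
    n = len(onsets)
    if any(o is None or not np.isfinite(o) for o in onsets):
        return OnsetResult(subsample_onsets=onsets, ns_flag=True, n=n)
    values = np.asarray(onsets, dtype=float)
    mean = float(values.mean())
    se_naive = float(values.std(ddof=1) / np.sqrt(n))
    se_corrected = (n - 1) * se_naive
    df = n - 1
    t_crit = config.critical_t(df)
    half = t_crit * se_corrected
    if se_corrected == 0:
        t_stat = np.inf if mean > 0 else (-np.inf if mean < 0 else 0.0)
        p = 0.0 if mean > 0 else (1.0 if mean < 0 else 0.5)
    else:
        t_stat = mean / se_corrected
        p = float(stats.t.sf(t_stat, df))
    return OnsetResult(
        subsample_onsets=onsets,
        mean_onset=mean,
        ci95=(mean - half, mean + half),
        p_value=p,
        t_statistic=float(t_stat),
        ns_flag=False,
        n=n,
    )


def latency_difference(onsets_a, onsets_b, config: OnsetConfig | None = None) -> dict:
    """Two-sided paired t test on subsample onset differences, (n−1)-corrected.

    Zero-variance differences are reported as the exact-equality case
    (p = 1 when the mean difference is 0, p = 0 otherwise), not NaN.
    """
    config = config or OnsetConfig()
    a = np.asarray(list(onsets_a), dtype=float)
    b = np.asarray(list(onsets_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("onset vectors must have equal length")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("latency difference requires fully significant onsets on both sides")
    d = a - b
    n = d.size
    mean = float(d.mean())
    se_corrected = (n - 1) * float(d.std(ddof=1) / np.sqrt(n))
    if se_corrected == 0:
        t_stat = 0.0 if mean == 0 else np.sign(mean) * np.inf
        p = 1.0 if mean == 0 else 0.0
    else:
        t_stat = mean / se_corrected
        p = float(2 * stats.t.sf(abs(t_stat), n - 1))
    return {"mean_difference_ms": mean, "t": float(t_stat), "p": p, "df": n - 1}


def holm_correction(p_values, q: float = 0.05) -> dict:
    """Bonferroni–Holm step-down correction at family-wise level ``q``."""
    p = np.asarray(list(p_values), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="holm")
    return {"reject": reject, "p_adjusted": np.minimum(p_adj, 1.0)}


def roi_model_test(subject_correlations: dict, q: float = 0.05) -> dict:
    """Group tests of ROI-model correlations against 0, Holm-corrected.

    ``subject_correlations`` maps ROI name -> per-subject correlation vector.
    Per ROI: one-sided (right) one-sample t test and one-sided Wilcoxon
    signed-rank test; Holm correction across ROIs separately per test family.
    An all-zero vector leaves the Wilcoxon undefined (reported as NaN).
    """
    rois = list(subject_correlations)
    t_ps, w_ps, rows = [], [], {}
    for roi in rois:
        v = np.asarray(subject_correlations[roi], dtype=float)
        if v.size < 3:
            raise ValueError(f"ROI {roi!r} needs >= 3 subjects")
        if v.std(ddof=1) == 0:  # degenerate: identical values across subjects
            t_stat = 0.0 if v.mean() == 0 else np.sign(v.mean()) * np.inf
            p_t = 0.5 if v.mean() == 0 else (0.0 if v.mean() > 0 else 1.0)
        else:
            t_res = stats.ttest_1samp(v, 0.0, alternative="greater")
            t_stat, p_t = t_res.statistic, t_res.pvalue
        if np.allclose(v, 0):
            w_p = np.nan
        else:
            w_p = float(stats.wilcoxon(v, alternative="greater", zero_method="wilcox").pvalue)
        rows[roi] = {
            "mean_correlation": float(v.mean()),
            "t": float(t_stat),
            "p_t": float(p_t),
            "p_wilcoxon": w_p,
            "n": int(v.size),
        }
        t_ps.append(rows[roi]["p_t"])
        w_ps.append(w_p)
    holm_t = holm_correction(t_ps, q)
    finite_w = np.isfinite(w_ps)
    w_adj = np.full(len(rois), np.nan)
    w_rej = np.zeros(len(rois), dtype=bool)
    if finite_w.any():
        hw = holm_correction(np.asarray(w_ps)[finite_w], q)
        w_adj[finite_w] = hw["p_adjusted"]
        w_rej[finite_w] = hw["reject"]
    for k, roi in enumerate(rois):
        rows[roi]["p_t_holm"] = float(holm_t["p_adjusted"][k])
        rows[roi]["reject_t"] = bool(holm_t["reject"][k])
        rows[roi]["p_wilcoxon_holm"] = float(w_adj[k]) if np.isfinite(w_adj[k]) else np.nan
        rows[roi]["reject_wilcoxon"] = bool(w_rej[k])
    return rows
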
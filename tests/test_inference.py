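"""Jackknife onset inference, latency contrasts, Holm correction, ROI tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from memfusion.inference import (
    OnsetConfig,
    baseline_sd,
    estimate_onsets,
    holm_correction,
    jackknife_subsamples,
    latency_difference,
    onset_detect,
    onset_summary,
    roi_model_test,
)
from memfusion.rdm import time_axis_ms


def brute_force_onset(series, time_axis, sigma, config):
    """Independent scan: check both criteria at every time point directly."""
    step = np.median(np.diff(time_axis))
    w = max(int(round(config.window_ms / step)), 1)
    thr = config.sd_multiplier * sigma
    for idx in range(time_axis.size):
        if time_axis[idx] < config.search_from_ms:
            continue
        if series[idx] < thr:
            continue
        span = series[idx : idx + config.n_windows * w]
        if span.size < config.n_windows * w:
            continue
        means = [span[k * w : (k + 1) * w].mean() for k in range(config.n_windows)]
        if all(m >= thr for m in means):
            return float(time_axis[idx])
    return None


class TestJackknife:
    def test_identical_subjects_collapse_to_grand_mean(self):
        series = np.tile(np.arange(6.0), (4, 1))
        sub = jackknife_subsamples(series)
        assert np.allclose(sub, series)

    def test_hand_computed_leave_one_out_means(self):
        m = np.array([[1, 2, 3, 4], [5, 6, 7, 8], [9, 10, 11, 12.0]])
        sub = jackknife_subsamples(m)
        assert np.allclose(sub[0], [7, 8, 9, 10])  # mean of rows 1, 2
        assert np.allclose(sub[1], [5, 6, 7, 8])
        assert np.allclose(sub[2], [3, 4, 5, 6])

    def test_mean_of_subsamples_equals_grand_mean(self, rng):
        m = rng.standard_normal((7, 30))
        assert np.allclose(jackknife_subsamples(m).mean(axis=0), m.mean(axis=0))

    def test_requires_three_subjects(self, rng):
        with pytest.raises(ValueError, match=">= 3"):
            jackknife_subsamples(rng.standard_normal((2, 10)))


class TestOnsetDetect:
    def setup_method(self):
        self.t = time_axis_ms(-200, 1000, 10)
        self.cfg = OnsetConfig()

    def test_everything_below_threshold_is_ns(self):
        series = np.zeros(self.t.size)
        assert onset_detect(series, self.t, 1.0, self.cfg) is None

    def test_sustained_step_detected_at_its_onset(self):
        series = np.where(self.t >= 100, 10.0, 0.0)
        assert onset_detect(series, self.t, 1.0, self.cfg) == 100.0

    def test_brief_excursion_fails_temporal_criterion(self):
        series = np.zeros(self.t.size)
        series[(self.t >= 100) & (self.t < 120)] = 10.0
        assert onset_detect(series, self.t, 1.0, self.cfg) is None

    def test_prestimulus_crossings_ignored(self):
        series = np.where(self.t >= -150, 10.0, 0.0)
        assert onset_detect(series, self.t, 1.0, self.cfg) == 0.0

    def test_equals_brute_force_scan_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            series = rng.standard_normal(self.t.size) + rng.choice([0, 1.5, 3.0])
            sigma = float(rng.uniform(0.5, 2.0))
            assert onset_detect(series, self.t, sigma, self.cfg) == brute_force_onset(
                series, self.t, sigma, self.cfg
            )

    def test_grand_mean_reading_is_looser(self):
        # passes the pooled 500 ms mean but fails one individual window
        series = np.zeros(self.t.size)
        series[(self.t >= 100) & (self.t < 600)] = 4.0
        series[(self.t >= 200) & (self.t < 250)] = 0.5
        strict = OnsetConfig(criterion2="each_window")
        loose = OnsetConfig(criterion2="grand_mean")
        assert onset_detect(series, self.t, 1.0, strict) != 100.0
        assert onset_detect(series, self.t, 1.0, loose) == 100.0

    def test_zero_baseline_sd_is_an_error(self):
        cfg = OnsetConfig()
        with pytest.raises(ValueError, match="positive"):
            onset_detect(np.zeros(self.t.size), self.t, 0.0, cfg)
        with pytest.raises(ValueError, match="degenerate baseline"):
            baseline_sd(np.ones(self.t.size), self.t, cfg)


class TestOnsetSummary:
    def test_identical_onsets_have_zero_width_ci(self):
        res = onset_summary([120.0] * 5)
        assert res.mean_onset == 120.0
        assert res.ci95 == (120.0, 120.0)
        assert not res.ns_flag

    def test_critical_t_default_matches_df14(self):
        assert OnsetConfig().critical_t(14) == pytest.approx(2.145, abs=5e-4)

    def test_hand_arithmetic_oracle_n3(self):
        res = onset_summary([100.0, 110.0, 120.0])
        se_naive = np.std([100, 110, 120], ddof=1) / np.sqrt(3)
        se_corr = 2 * se_naive  # (n − 1) jackknife inflation
        t_crit = stats.t.ppf(0.975, 2)
        assert res.mean_onset == 110.0
        assert res.ci95[0] == pytest.approx(110 - t_crit * se_corr)
        assert res.ci95[1] == pytest.approx(110 + t_crit * se_corr)
        assert res.p_value == pytest.approx(stats.t.sf(110 / se_corr, 2))

    def test_any_missing_subsample_sets_ns(self):
        res = onset_summary([100.0, None, 120.0])
        assert res.ns_flag
        assert np.isnan(res.mean_onset)


class TestLatencyDifference:
    def test_self_comparison_is_exact_equality_case(self):
        a = [100.0, 120.0, 140.0]
        res = latency_difference(a, a)
        assert res["mean_difference_ms"] == 0.0
        assert res["p"] == 1.0

    def test_swap_negates_mean_keeps_p(self):
        a, b = [100.0, 130.0, 150.0, 90.0], [80.0, 135.0, 120.0, 100.0]
        r1, r2 = latency_difference(a, b), latency_difference(b, a)
        assert r1["mean_difference_ms"] == -r2["mean_difference_ms"]
        assert r1["p"] == pytest.approx(r2["p"])

    def test_matches_direct_formula_with_corrected_se(self):
        a, b = np.array([300.0, 320.0, 310.0]), np.array([280.0, 290.0, 270.0])
        res = latency_difference(a, b)
        d = a - b
        se_corr = 2 * d.std(ddof=1) / np.sqrt(3)
        t_stat = d.mean() / se_corr
        assert res["t"] == pytest.approx(t_stat)
        assert res["p"] == pytest.approx(2 * stats.t.sf(abs(t_stat), 2))

    def test_rejects_missing_onsets(self):
        with pytest.raises(ValueError, match="significant"):
            latency_difference([100.0, np.nan, 120.0], [90.0, 95.0, 100.0])


class TestHolm:
    def test_single_p_unchanged(self):
        res = holm_correction([0.03])
        assert res["p_adjusted"][0] == pytest.approx(0.03)
        assert res["reject"][0]

    def test_step_down_by_hand(self):
        res = holm_correction([0.01, 0.02, 0.04, 0.20], q=0.05)
        # 0.01 < 0.05/4; then 0.02 > 0.05/3 stops the step-down
        assert res["reject"].tolist() == [True, False, False, False]

    def test_all_zero_p_all_rejected(self):
        assert holm_correction([0.0, 0.0, 0.0])["reject"].all()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12))
    def test_never_rejects_fewer_than_bonferroni(self, p_values):
        q = 0.05
        holm = holm_correction(p_values, q)["reject"].sum()
        bonferroni = sum(p <= q / len(p_values) for p in p_values)
        assert holm >= bonferroni

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            holm_correction([0.5, 1.2])


class TestRoiModelTest:
    def test_null_center_gives_half_p(self):
        res = roi_model_test({"roi_a": np.zeros(10), "roi_b": np.full(10, 1e-12)})
        assert res["roi_a"]["p_t"] == pytest.approx(0.5)
        assert np.isnan(res["roi_a"]["p_wilcoxon"])

    def test_planted_positive_correlation_rejected_at_q(self):
        rng = np.random.default_rng(0)
        groups = {f"roi{k}": 0.2 + 0.05 * rng.standard_normal(15) for k in range(4)}
        res = roi_model_test(groups, q=0.05)
        assert all(res[r]["reject_t"] for r in groups)
        assert all(res[r]["reject_wilcoxon"] for r in groups)

    def test_sign_flip_maps_p_to_complement(self, rng):
        v = rng.standard_normal(12) + 0.3
        p_pos = roi_model_test({"roi": v})["roi"]["p_t"]
        p_neg = roi_model_test({"roi": -v})["roi"]["p_t"]
        assert p_pos + p_neg == pytest.approx(1.0)

    def test_needs_three_subjects(self):
        with pytest.raises(ValueError, match=">= 3"):
            roi_model_test({"roi": [0.1, 0.2]})


class TestEstimateOnsets:
    def test_full_jackknife_pipeline_on_synthetic_step(self, rng):
        t = time_axis_ms(-200, 1000, 10)
        signal = np.where(t >= 300, 1.0, 0.0)
        series = signal[None, :] + 0.05 * rng.standard_normal((6, t.size))
        res = estimate_onsets(series, t, OnsetConfig())
        assert not res.ns_flag
        assert res.mean_onset == pytest.approx(300.0, abs=20)
        assert res.ci95[0] <= res.mean_onset <= res.ci95[1]
        assert res.significant_timepoints[t < 300].sum() == 0

    def test_null_series_rarely_produce_onsets(self):
        """All-subsample agreement keeps the false-onset rate low."""
        rng = np.random.default_rng(123)
        t = time_axis_ms(-200, 1000, 10)
        false_onsets = 0
        n_runs = 200
        for _ in range(n_runs):
            series = rng.standard_normal((5, t.size)) * 0.3
            res = estimate_onsets(series, t, OnsetConfig())
            false_onsets += not res.ns_flag
        assert false_onsets / n_runs <= 0.05
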
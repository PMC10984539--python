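"""End-to-end validation experiments: parameter recovery and calibration.

These are the package's standing evaluation runs, executed by the test suite
and the acceptance script.  Problem sizes are the desk-scale profile
(5 subjects, 10 pairs, 121 time points at 10 ms, 12³ voxel grid); the
cluster-test studies use 12 synthetic subjects because a sign-flip test with
5 subjects has only 2⁵ flip patterns and cannot resolve p < 0.01.
"""

from __future__ import annotations

import numpy as np

from .cluster import ClusterConfig, permutation_cluster_test
from .decoding import DecodingConfig
from .fusion import difference_contrast, fusion_series
from .models import feature_rdm
from .pipeline import analyze_experiment
from .rdm import time_axis_ms
from .synth import SimConfig, simulate_experiment

__all__ = [
    "recover_onset",
    "onset_recovery_study",
    "cluster_fwer_study",
    "prestimulus_decoding_accuracy",
    "confound_removal_study",
]


def _child_seeds(seed: int, n: int) -> list:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def recover_onset(seed: int, onset_true: float = 300.0, n_iterations: int = 30) -> float | None:
    """Full-pipeline High>Low onset estimate on one scaled synthetic run.

    Simulates a scaled experiment with the planted divergence at
    ``onset_true`` (amplitude 5× the noise SD), runs decoding, searchlight,
    ROI fusion and jackknife onset inference, and returns the estimated mean
    onset in ms (None when the difference curve is not significant).
    """
    sim_seed, dec_seed = _child_seeds(seed, 2)
    exp = simulate_experiment(SimConfig.scaled(seed=sim_seed, onset_true=onset_true))
    res = analyze_experiment(exp, DecodingConfig(n_iterations=n_iterations, seed=dec_seed), rois=(0,))
    onset = res["rois"][0]["onsets"]["Difference"]
    return None if onset.ns_flag else float(onset.mean_onset)


def onset_recovery_study(seed: int, n_runs: int = 20, onset_true: float = 300.0, tolerance_ms: float = 25.0) -> dict:
    """Repeat :func:`recover_onset` over seeded runs; report the hit rate."""
    onsets = [recover_onset(s, onset_true) for s in _child_seeds(seed, n_runs)]
    hits = [o for o in onsets if o is not None and abs(o - onset_true) <= tolerance_ms]
    errors = [abs(o - onset_true) for o in onsets if o is not None]
    return {
        "onsets_ms": onsets,
        "recovery_rate": len(hits) / n_runs,
        "mean_abs_error_ms": float(np.mean(errors)) if errors else float("nan"),
        "n_runs": n_runs,
    }


def cluster_fwer_study(seed: int, n_runs: int = 100, n_subjects: int = 12, n_permutations: int = 200) -> dict:
    """Family-wise error of the sign-flip cluster test on null subject maps.

    Null maps are exchangeable zero-mean Gaussian (x, y, z, t) volumes — the
    regime the sign-flip permutation scheme assumes under H0.
    """
    t = time_axis_ms(-200, 400, 10)
    rejections = 0
    for run_seed in _child_seeds(seed, n_runs):
        rng = np.random.default_rng(run_seed)
        maps = rng.standard_normal((n_subjects, 6, 6, 6, t.size))
        cfg = ClusterConfig(n_permutations=n_permutations, alpha=0.01, seed=run_seed)
        res = permutation_cluster_test(maps, t, cfg)
        rejections += bool(res.significant_clusters)
    return {"fwer": rejections / n_runs, "n_runs": n_runs, "alpha": 0.01}


def prestimulus_decoding_accuracy(seed: int, n_runs: int = 2) -> dict:
    """Mean pre-stimulus pairwise decoding accuracy on null experiments.

    With no planted effect and no confound the patterns are exchangeable
    noise, so decoding must sit at the 50% chance level.
    """
    values = []
    for run_seed in _child_seeds(seed, n_runs):
        sim_seed, dec_seed = _child_seeds(run_seed, 2)
        exp = simulate_experiment(
            SimConfig.scaled(seed=sim_seed, effect_amplitude=0.0, high_amplitude=0.0, confound_weight=0.0)
        )
        res = analyze_experiment(
            exp, DecodingConfig(n_iterations=20, seed=dec_seed), rois=(0,)
        )
        t = res["time_axis"]
        for series in res["meg_rdm_series"].values():
            values.append(series.vectors()[t < 0].mean())
    return {"accuracy_pct": float(np.mean(values)), "n_runs": n_runs}


def confound_removal_study(seed: int) -> dict:
    """Difference fusion when the sets differ only through the confound.

    The confound ("GIST-like") geometry is expressed with twice the weight in
    the High set; base and divergence amplitudes are zero.  Reported are the
    magnitudes of the post-stimulus time-mean of the grand-average difference
    series with the confound partialled out (should be ~0) and, for contrast,
    with an independent dummy RDM partialled out (leaving the confound in).
    """
    sim_seed, dec_seed, dummy_seed = _child_seeds(seed, 3)
    exp = simulate_experiment(
        SimConfig.scaled(
            seed=sim_seed,
            n_subjects=15,
            n_pairs=32,
            effect_amplitude=0.0,
            high_amplitude=0.0,
            confound_weight=(0.4, 0.2),
        )
    )
    res = analyze_experiment(exp, DecodingConfig(n_iterations=20, seed=dec_seed), rois=(0,))
    t = res["time_axis"]
    roi = res["rois"][0]
    partialled = roi["fusion"]["Difference"].grand_average()[t >= 0]

    rng = np.random.default_rng(dummy_seed)
    dummy = feature_rdm(rng.standard_normal((len(exp.condition_ids), 12)), exp.condition_ids)
    hi, lo = exp.stimuli.high_ids, exp.stimuli.low_ids
    fs = {}
    for label, ids in (("High", hi), ("Low", lo)):
        targets = [r.subset(ids) for r in roi["roi_rdms"]]
        fs[label] = fusion_series(res["meg_rdm_series"][label], targets, dummy.subset(ids), label)
    unpartialled = difference_contrast(fs["High"], fs["Low"]).grand_average()[t >= 0]
    return {
        "partialled_abs_mean": float(abs(partialled.mean())),
        "unpartialled_mean": float(unpartialled.mean()),
        "n_pairs": 32,
    }
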
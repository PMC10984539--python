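"""Synthetic experiments with known representational ground truth.

The generator emulates the structure of a paired-memorability MEG+fMRI
experiment: 78 matched High/Low-memorability condition pairs viewed by 15
subjects, with per-trial MEG sensor patterns on a millisecond time axis and
per-condition fMRI t-value volumes on a small 3-D grid.  Every downstream
stage of the pipeline (decoding RDMs, searchlight RDMs, fusion, cluster
statistics, onset latencies) therefore has a recoverable planted target.

Planted representational structure
----------------------------------
Condition geometry is generated as latent feature vectors per condition and
the planted RDM is 1 − Pearson of those vectors, so the ground-truth RDM is
exact.  By default the latent vectors lie on a great-circle arc between two
random orthonormal axes, at equally spaced but randomly permuted angles
("arc" style).  This gives a graded, well-spread spectrum of pairwise
dissimilarities that keeps pairwise decoding in its sensitive range (roughly
55–95% accuracy) instead of saturating at 100%, where the decoding RDM would
flatten and carry no geometry; it also makes the planted rank structure
identifiable even at small condition counts.  An isotropic "cloud"
alternative (unit-norm perturbations of a random prototype) is available.
Three mutually independent latent components are planted:

base
    expressed by every condition in MEG within ``base_window_ms`` and in the
    fMRI t-maps of the planted ROIs.
divergence
    expressed in fMRI throughout, but in MEG only by High conditions and
    only from ``onset_true`` onward.  This makes the High-vs-Low fusion
    difference rise at ``onset_true``.
confound
    a "GIST-like" component mixed into both modalities and returned as
    per-condition ``confound_features`` for model RDMs.

Latent vectors are drawn per *pair* and assigned identically to both pair
members, emulating the matched High/Low design: High and Low sub-RDMs share
the same planted structure (base, divergence-as-seen-by-fMRI, confound) and
identical voxel loadings, so the two fusion series are exchangeable before
``onset_true`` and differ afterwards only through the MEG expression of the
divergence component.  Amplitudes are in multiples of the modality noise SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .rdm import RDM, time_axis_ms
from .searchlight import StatMapSet

__all__ = ["StimulusSet", "SimConfig", "SyntheticExperiment", "simulate_experiment", "toy_atlas"]


@dataclass
class StimulusSet:
    """156 conditions in 78 matched High/Low pairs with memorability scores."""

    condition_ids: list
    memorability_score: np.ndarray
    pair_index: dict  # High condition id -> Low condition id
    set_label: list  # "High" | "Low" per condition

    def __post_init__(self):
        self.memorability_score = np.asarray(self.memorability_score, dtype=float)
        if len(self.condition_ids) != len(self.memorability_score) or len(self.condition_ids) != len(self.set_label):
            raise ValueError("inconsistent StimulusSet field lengths")
        if self.memorability_score.min() < 0 or self.memorability_score.max() > 1:
            raise ValueError("memorability scores must lie in [0, 1]")
        highs = [c for c, s in zip(self.condition_ids, self.set_label) if s == "High"]
        lows = [c for c, s in zip(self.condition_ids, self.set_label) if s == "Low"]
        if set(self.pair_index) != set(highs) or set(self.pair_index.values()) != set(lows):
            raise ValueError("pair_index must map each High condition to a distinct Low condition")

    @property
    def high_ids(self) -> list:
        return [c for c, s in zip(self.condition_ids, self.set_label) if s == "High"]

    @property
    def low_ids(self) -> list:
        return [c for c, s in zip(self.condition_ids, self.set_label) if s == "Low"]

    def scores_for(self, ids) -> np.ndarray:
        index = {c: k for k, c in enumerate(self.condition_ids)}
        return self.memorability_score[[index[c] for c in ids]]


@dataclass
class SimConfig:
    """Parameters of a synthetic experiment (defaults mirror the real design)."""

    n_subjects: int = 15
    n_pairs: int = 78
    n_trials_per_condition: int = 25
    t_start: float = -200.0
    t_end: float = 1000.0
    t_step: float = 1.0
    n_sensors: int = 306
    grid_shape: tuple = (16, 16, 16)
    n_rois: int = 3
    planted_rois: tuple = (0,)
    latent_dim: int = 12
    geometry_style: str = "arc"  # "arc" | "cloud", see _latent_features
    geometry_spread: float = 1.5  # arc: angular extent (rad); cloud: perturbation SD
    base_window_ms: tuple = (100.0, 1000.0)
    effect_amplitude: float = 1.5  # base geometry in MEG, × noise_sd
    high_amplitude: float = 5.0  # divergence component (the planted effect), × noise_sd
    onset_true: float = 300.0
    confound_weight: float | tuple = 1.0  # scalar or (High, Low), × noise_sd
    confound_window_ms: tuple = (0.0, 1000.0)
    noise_sd: float = 1.0
    fmri_amplitude: float = 1.0  # base geometry in t-maps, × fmri_noise_sd
    fmri_noise_sd: float = 1.0
    score_means: tuple = (0.854, 0.519)  # High, Low
    score_sds: tuple = (0.089, 0.105)
    seed: int = 0

    @classmethod
    def scaled(cls, **overrides) -> "SimConfig":
        """Desk-scale profile: 5 subjects, 10 pairs, 8 trials, 10 ms step, 12³ grid."""
        base = dict(
            n_subjects=5,
            n_pairs=10,
            n_trials_per_condition=8,
            t_step=10.0,
            n_sensors=16,
            grid_shape=(12, 12, 12),
        )
        base.update(overrides)
        return cls(**base)

    @property
    def time_axis(self) -> np.ndarray:
        return time_axis_ms(self.t_start, self.t_end, self.t_step)

    @property
    def confound_weights(self) -> tuple:
        w = self.confound_weight
        return tuple(w) if np.iterable(w) else (float(w), float(w))

    def validate(self) -> None:
        if self.noise_sd <= 0 or self.fmri_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")
        if self.t_step <= 0 or self.t_end <= self.t_start:
            raise ValueError("invalid time axis")
        for w0, w1 in (self.base_window_ms, self.confound_window_ms):
            if not (self.t_start <= w0 <= w1 <= self.t_end):
                raise ValueError(f"planted window ({w0}, {w1}) outside the time axis")
        if not (self.t_start <= self.onset_true <= self.t_end):
            raise ValueError("onset_true outside the time axis")
        if self.latent_dim > self.n_sensors:
            raise ValueError("latent_dim cannot exceed n_sensors")
        if self.n_pairs < 2 or self.n_subjects < 1 or self.n_trials_per_condition < 1:
            raise ValueError("degenerate design size")


@dataclass
class SyntheticExperiment:
    """A complete simulated experiment plus its planted ground truth."""

    meg_trials: np.ndarray  # (subjects, conditions, trials, sensors, times), float32
    stat_maps: list  # StatMapSet per subject
    stimuli: StimulusSet
    confound_features: np.ndarray  # (conditions, latent_dim)
    roi_masks: list  # boolean volumes from toy_atlas
    time_axis: np.ndarray
    ground_truth: dict

    @property
    def condition_ids(self) -> list:
        return self.stimuli.condition_ids


def toy_atlas(grid_shape: tuple, n_rois: int = 3) -> list:
    """Disjoint contiguous box ROIs packed on a 2-D grid of patches.

    Boxes tile the first two axes (full extent along the third) and are
    separated by one empty voxel plane, so masks are pairwise disjoint by
    construction and each is at least 3 voxels thick in every direction.
    """
    if n_rois < 1:
        raise ValueError("need at least one ROI")
    g0 = int(np.ceil(np.sqrt(n_rois)))
    g1 = int(np.ceil(n_rois / g0))
    t0 = (grid_shape[0] - (g0 - 1)) // g0
    t1 = (grid_shape[1] - (g1 - 1)) // g1
    if t0 < 3 or t1 < 3 or grid_shape[2] < 3:
        raise ValueError(f"grid {grid_shape} too small for {n_rois} searchlight-compatible ROIs")
    masks = []
    for r in range(n_rois):
        i, j = divmod(r, g1)
        m = np.zeros(grid_shape, dtype=bool)
        m[i * (t0 + 1) : i * (t0 + 1) + t0, j * (t1 + 1) : j * (t1 + 1) + t1, :] = True
        masks.append(m)
    return masks


def _latent_features(rng: np.random.Generator, n: int, k: int, spread: float, style: str = "arc") -> np.ndarray:
    """Unit-norm latent feature vectors with graded pairwise dissimilarities.

    ``arc`` (default): points on a great-circle arc of total angular extent
    ``spread`` radians between two random orthonormal axes, at equally spaced
    but randomly permuted angles.  This yields a well-spread, identifiable
    planted RDM whose dissimilarities stay in the decodable range even for
    small condition counts.  ``cloud``: isotropic perturbations of a random
    prototype, u0 + spread·g, normalized.
    """
    # rows are kept zero-mean across latent dims so that the planted
    # 1 − Pearson RDM coincides with the cosine geometry realized by
    # linear voxel/sensor projections of the features
    if style == "cloud":
        u0 = rng.standard_normal(k)
        u0 /= np.linalg.norm(u0)
        f = u0[None, :] + spread * rng.standard_normal((n, k))
        f -= f.mean(axis=1, keepdims=True)
        return f / np.linalg.norm(f, axis=1, keepdims=True)
    g = rng.standard_normal((k, 2))
    g -= g.mean(axis=0)  # zero-mean axes -> zero-mean rows
    q, _ = np.linalg.qr(g)
    theta = spread * rng.permutation(n) / max(n - 1, 1)
    return np.outer(np.cos(theta), q[:, 0]) + np.outer(np.sin(theta), q[:, 1])


def _orthonormal_projection(rng: np.random.Generator, p: int, k: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((p, k)))
    return q[:, :k]


def _pearson_rdm(features: np.ndarray) -> np.ndarray:
    c = np.corrcoef(features)
    return 1.0 - np.clip(c, -1.0, 1.0)


def make_stimulus_set(config: SimConfig, rng: np.random.Generator) -> StimulusSet:
    high_ids = [f"pair{i:03d}_H" for i in range(config.n_pairs)]
    low_ids = [f"pair{i:03d}_L" for i in range(config.n_pairs)]
    scores_h = np.clip(rng.normal(config.score_means[0], config.score_sds[0], config.n_pairs), 0, 1)
    scores_l = np.clip(rng.normal(config.score_means[1], config.score_sds[1], config.n_pairs), 0, 1)
    return StimulusSet(
        condition_ids=high_ids + low_ids,
        memorability_score=np.concatenate([scores_h, scores_l]),
        pair_index=dict(zip(high_ids, low_ids)),
        set_label=["High"] * config.n_pairs + ["Low"] * config.n_pairs,
    )


def simulate_experiment(config: SimConfig) -> SyntheticExperiment:
    """Generate a fully seeded synthetic experiment per the planted model above."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pairs, k = config.n_pairs, config.latent_dim
    n_cond = 2 * n_pairs
    time = config.time_axis
    n_t = time.size

    stimuli = make_stimulus_set(config, rng)

    # pair-level latent geometries, assigned identically to both pair members
    fp_base = _latent_features(rng, n_pairs, k, config.geometry_spread, config.geometry_style)
    fp_div = _latent_features(rng, n_pairs, k, config.geometry_spread, config.geometry_style)
    fp_conf = _latent_features(rng, n_pairs, k, config.geometry_spread, config.geometry_style)
    f_base = np.vstack([fp_base, fp_base])  # (C, k), High block then Low block
    f_div = np.vstack([fp_div, fp_div])
    f_conf = np.vstack([fp_conf, fp_conf])

    # sensor-space projections (orthonormal columns -> unit-norm patterns)
    w_base = _orthonormal_projection(rng, config.n_sensors, k)
    w_div = _orthonormal_projection(rng, config.n_sensors, k)
    w_conf = _orthonormal_projection(rng, config.n_sensors, k)

    p_base = f_base @ w_base.T  # (C, p)
    p_div = fp_div @ w_div.T  # (pairs, p); expressed in MEG by High members only
    p_conf = f_conf @ w_conf.T  # (C, p)

    in_base = (time >= config.base_window_ms[0]) & (time <= config.base_window_ms[1])
    in_div = (time >= config.onset_true) & (time <= config.base_window_ms[1])
    in_conf = (time >= config.confound_window_ms[0]) & (time <= config.confound_window_ms[1])

    w_conf_high, w_conf_low = config.confound_weights
    sd = config.noise_sd
    set_conf_w = np.array([w_conf_high] * n_pairs + [w_conf_low] * n_pairs)

    # noiseless condition signal, (C, p, T)
    signal = np.zeros((n_cond, config.n_sensors, n_t))
    signal += config.effect_amplitude * sd * p_base[:, :, None] * in_base[None, None, :]
    signal[:n_pairs] += config.high_amplitude * sd * p_div[:, :, None] * in_div[None, None, :]
    signal += set_conf_w[:, None, None] * sd * p_conf[:, :, None] * in_conf[None, None, :]

    meg = np.empty(
        (config.n_subjects, n_cond, config.n_trials_per_condition, config.n_sensors, n_t),
        dtype=np.float32,
    )
    for s in range(config.n_subjects):
        noise = rng.standard_normal(meg.shape[1:]).astype(np.float32)
        meg[s] = signal[:, None, :, :].astype(np.float32) + sd * noise

    # fMRI t-maps: planted ROIs carry the geometry through fixed voxel loadings
    roi_masks = toy_atlas(config.grid_shape, config.n_rois)
    brain_mask = np.ones(config.grid_shape, dtype=bool)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    fsd = config.fmri_noise_sd

    region_signal = np.zeros((n_cond,) + config.grid_shape)
    for r in config.planted_rois:
        vox = np.argwhere(roi_masks[r])
        nv = len(vox)
        u_b = rng.standard_normal((nv, k))
        u_d = rng.standard_normal((nv, k))
        u_c = rng.standard_normal((nv, k))
        # identical loadings for both pair members: High/Low t-patterns match
        sig = config.fmri_amplitude * fsd * (f_base @ u_b.T)  # (C, nv)
        sig += config.high_amplitude * fsd * (f_div @ u_d.T)
        sig += set_conf_w[:, None] * fsd * (f_conf @ u_c.T)
        region_signal[:, vox[:, 0], vox[:, 1], vox[:, 2]] = sig

    stat_maps = []
    for s in range(config.n_subjects):
        noise = fsd * rng.standard_normal((n_cond,) + config.grid_shape)
        stat_maps.append(
            StatMapSet(region_signal + noise, brain_mask, affine, list(stimuli.condition_ids))
        )

    ids = stimuli.condition_ids
    ground_truth = {
        "config": asdict(config),
        "onset_true_ms": config.onset_true,
        "planted_rois": tuple(config.planted_rois),
        "rdm_base": RDM(_pearson_rdm(fp_base), stimuli.high_ids, "one_minus_pearson"),
        "rdm_divergence": RDM(_pearson_rdm(fp_div), stimuli.high_ids, "one_minus_pearson"),
        "rdm_confound": RDM(_pearson_rdm(fp_conf), stimuli.high_ids, "one_minus_pearson"),
    }
    return SyntheticExperiment(
        meg_trials=meg,
        stat_maps=stat_maps,
        stimuli=stimuli,
        confound_features=f_conf,
        roi_masks=roi_masks,
        time_axis=time,
        ground_truth=ground_truth,
    )
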
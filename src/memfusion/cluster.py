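"""Sign-flip permutation cluster statistics over space × time fusion maps.

The observed statistic is the subject-mean 4-D (x, y, z, t) map.  The
cluster-forming threshold is the empirical (1 − cluster_def_p) quantile of
the mean map's baseline-period (−200 to 0 ms) values, pooled over in-mask
voxels (right-sided).  Clusters are connected components of supra-threshold
voxel-timepoints under a chosen spatial connectivity (6/18/26) combined with
±1-sample temporal adjacency at the same voxel; cluster size is counted in
voxel-timepoint units.  The null distribution of the maximum cluster size is
built by randomly flipping the sign of each subject's whole map, and a
cluster's p-value is ``(1 + #{null max ≥ size}) / (1 + n_permutations)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["ClusterConfig", "Cluster", "ClusterResult", "baseline_cluster_threshold", "find_clusters", "permutation_cluster_test"]


@dataclass
class ClusterConfig:
    n_permutations: int = 1000
    cluster_def_p: float = 0.001  # right-sided cluster-forming quantile
    alpha: float = 0.01
    baseline_window: tuple = (-200.0, 0.0)  # endpoint-exclusive at 0
    spatial_connectivity: int = 26  # 6 | 18 | 26
    pooled_baseline: bool = True  # pool baseline values across voxels
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.cluster_def_p <= 1) or not (0 < self.alpha <= 1):
            raise ValueError("cluster_def_p and alpha must lie in (0, 1]")
        if self.spatial_connectivity not in (6, 18, 26):
            raise ValueError("spatial_connectivity must be 6, 18 or 26")


@dataclass
class Cluster:
    coordinates: np.ndarray  # (size, 4) voxel-time indices
    size: int
    p_value: float


@dataclass
class ClusterResult:
    clusters: list = field(default_factory=list)
    null_max_sizes: np.ndarray = None
    threshold_value: float = np.nan
    significant_mask: np.ndarray = None
    alpha: float = 0.01

    @property
    def significant_clusters(self) -> list:
        return [c for c in self.clusters if c.p_value < self.alpha]


def _connectivity_structure(spatial: int) -> np.ndarray:
    """4-D structuring element: spatial neighborhood at the same time sample
    plus the same voxel at ±1 time sample."""
    order = {6: 1, 18: 2, 26: 3}[spatial]
    struct = np.zeros((3, 3, 3, 3), dtype=bool)
    struct[:, :, :, 1] = ndimage.generate_binary_structure(3, order)
    struct[1, 1, 1, 0] = struct[1, 1, 1, 2] = True
    return struct


def baseline_cluster_threshold(mean_map: np.ndarray, time_axis: np.ndarray, config: ClusterConfig, mask: np.ndarray | None = None) -> float:
    """Cluster-forming cutoff: the (1 − cluster_def_p) empirical quantile of
    the mean map's in-mask baseline-period values (sort-based, no
    interpolation: the ceil((1−p)·n)-th order statistic)."""
    time_axis = np.asarray(time_axis, dtype=float)
    t_sel = (time_axis >= config.baseline_window[0]) & (time_axis < config.baseline_window[1])
    if not t_sel.any():
        raise ValueError("empty baseline window")
    base = mean_map[..., t_sel]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask")
        base = base[mask]
    values = np.sort(base[np.isfinite(base)].ravel())
    if values.size == 0:
        raise ValueError("no finite baseline values")
    k = int(np.ceil((1.0 - config.cluster_def_p) * values.size))
    return float(values[max(k, 1) - 1])


def find_clusters(binary_map: np.ndarray, spatial_connectivity: int = 26) -> list:
    """Connected components of a boolean 4-D (x, y, z, t) map.

    Returns a list of (size, coordinates) sorted by decreasing size.
    """
    binary_map = np.asarray(binary_map, dtype=bool)
    if binary_map.ndim != 4:
        raise ValueError("binary map must be 4-D (x, y, z, t)")
    labels, n = ndimage.label(binary_map, structure=_connectivity_structure(spatial_connectivity))
    out = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        out.append((len(coords), coords))
    out.sort(key=lambda c: -c[0])
    return out


def _max_cluster_size(binary_map: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(binary_map, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def permutation_cluster_test(subject_maps: np.ndarray, time_axis: np.ndarray, config: ClusterConfig | None = None, mask: np.ndarray | None = None) -> ClusterResult:
    """Sign-flip max-cluster-size permutation test on subject (x, y, z, t) maps.

    ``subject_maps`` has shape (n_subjects, x, y, z, t).  NaN voxels (e.g.
    outside the analysis mask) never enter clusters.
    """
    config = config or ClusterConfig()
    subject_maps = np.asarray(subject_maps, dtype=float)
    if subject_maps.ndim != 5 or subject_maps.shape[0] < 2:
        raise ValueError("need (n_subjects >= 2, x, y, z, t) subject maps")
    if config.n_permutations < 1 / config.alpha:
        warnings.warn(
            f"{config.n_permutations} permutations cannot resolve alpha={config.alpha}",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    structure = _connectivity_structure(config.spatial_connectivity)

    mean_map = subject_maps.mean(axis=0)
    finite = np.isfinite(mean_map)
    threshold = baseline_cluster_threshold(mean_map, time_axis, config, mask)

    observed = finite & (mean_map > threshold)
    if mask is not None:
        observed &= np.asarray(mask, dtype=bool)[..., None]
    found = find_clusters(observed, config.spatial_connectivity)

    n_sub = subject_maps.shape[0]
    # NaN voxels are zero-filled here; they stay excluded via `finite`
    flat = np.nan_to_num(subject_maps, nan=0.0).reshape(n_sub, -1)
    null_max = np.empty(config.n_permutations, dtype=int)
    for perm in range(config.n_permutations):
        signs = rng.choice([-1.0, 1.0], size=n_sub)
        perm_mean = (signs[:, None] * flat).mean(axis=0).reshape(mean_map.shape)
        supra = finite & (perm_mean > threshold)
        if mask is not None:
            supra &= np.asarray(mask, dtype=bool)[..., None]
        null_max[perm] = _max_cluster_size(supra, structure)

    clusters = []
    sig_mask = np.zeros(mean_map.shape, dtype=bool)
    for size, coords in found:
        p = (1 + int((null_max >= size).sum())) / (1 + config.n_permutations)
        clusters.append(Cluster(coords, size, p))
        if p < config.alpha:
            sig_mask[tuple(coords.T)] = True
    return ClusterResult(clusters, null_max, threshold, sig_mask, config.alpha)
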
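"""Voxelwise searchlight RDMs from condition t-maps, and ROI-averaged RDMs.

For every voxel inside the brain mask a spherical neighborhood (default
radius 4 voxels) is centered on it, the per-condition t-values of all voxels
inside sphere ∩ mask are extracted as condition patterns, and the pairwise
1 − Pearson dissimilarities between condition patterns form that voxel's RDM.
ROI RDMs are the element-wise mean of the voxel RDMs inside an ROI mask.

Edge handling: spheres are clipped to the mask; centers whose clipped sphere
holds fewer than ``min_voxels`` voxels are marked missing (NaN), not errored.
Conditions whose pattern has zero variance within a sphere produce missing
entries for their pairs, with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .rdm import RDM, condensed_length, square_to_vector

logger = logging.getLogger(__name__)

__all__ = ["StatMapSet", "SearchlightConfig", "RDMMap", "sphere_offsets", "searchlight_rdms", "roi_rdm"]


@dataclass
class StatMapSet:
    """Per-condition t-value volumes on a common 3-D grid.

    ``t_values`` has shape ``(n_conditions, nx, ny, nz)``; ``brain_mask`` is a
    boolean volume of shape ``(nx, ny, nz)``; ``affine`` is the shared 4×4
    voxel-to-world transform.
    """

    t_values: np.ndarray
    brain_mask: np.ndarray
    affine: np.ndarray
    condition_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.t_values = np.asarray(self.t_values, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.t_values.ndim != 4:
            raise ValueError(f"t_values must be (conditions, x, y, z), got {self.t_values.shape}")
        if self.brain_mask.shape != self.t_values.shape[1:]:
            raise ValueError("brain_mask shape does not match t-map grid")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if len(self.condition_ids) != self.t_values.shape[0]:
            raise ValueError("condition_ids length does not match t_values")

    @property
    def n_conditions(self) -> int:
        return self.t_values.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.t_values.shape[1:]


@dataclass
class SearchlightConfig:
    radius_voxels: int = 4
    min_voxels: int = 10

    def __post_init__(self):
        if self.radius_voxels < 1:
            raise ValueError("radius_voxels must be >= 1")
        if self.min_voxels < 2:
            raise ValueError("min_voxels must be >= 2 (one voxel cannot yield a correlation)")


def sphere_offsets(radius: int) -> np.ndarray:
    """Integer 3-D offsets with Euclidean norm <= radius, center included.

    Deterministic lexicographic order; radius 4 yields 257 offsets.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius)
    ax = np.arange(-r, r + 1)
    i, j, k = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = i**2 + j**2 + k**2 <= radius**2
    return np.stack([i[keep], j[keep], k[keep]], axis=1)


@dataclass
class RDMMap:
    """Per-voxel condensed RDM vectors on a 3-D grid.

    ``vectors`` has shape ``(nx, ny, nz, n_pairs)``; voxels that were not
    computed (outside the mask, or below sphere occupancy) are all-NaN.
    """

    vectors: np.ndarray
    condition_ids: list
    brain_mask: np.ndarray
    affine: np.ndarray
    metric_tag: str = "one_minus_pearson"

    @property
    def grid_shape(self) -> tuple:
        return self.vectors.shape[:3]

    def computed_mask(self) -> np.ndarray:
        return np.isfinite(self.vectors).any(axis=-1)


def _pattern_rdm_vector(patterns: np.ndarray) -> np.ndarray:
    """Condensed 1 − Pearson RDM of condition patterns (conditions × voxels).

    Zero-variance condition rows yield NaN entries for all their pairs.
    """
    c = patterns - patterns.mean(axis=1, keepdims=True)
    sd = np.sqrt((c**2).sum(axis=1))
    bad = sd <= 0
    sd_safe = np.where(bad, 1.0, sd)
    corr = (c @ c.T) / np.outer(sd_safe, sd_safe)
    rdm = 1.0 - np.clip(corr, -1.0, 1.0)
    if bad.any():
        rdm[bad, :] = np.nan
        rdm[:, bad] = np.nan
    return square_to_vector(rdm)


def searchlight_rdms(
    maps: StatMapSet,
    config: SearchlightConfig | None = None,
    center_mask: np.ndarray | None = None,
) -> RDMMap:
    """Compute an RDM at every in-mask voxel from sphere-restricted patterns.

    ``center_mask`` optionally restricts which voxels get a searchlight
    centered on them (patterns are still drawn from the full brain mask);
    by default every in-mask voxel is a center.
    """
    config = config or SearchlightConfig()
    if maps.n_conditions < 2:
        raise ValueError("searchlight needs >= 2 conditions")
    if not maps.brain_mask.any():
        raise ValueError("empty brain mask")
    centers_mask = maps.brain_mask if center_mask is None else (maps.brain_mask & np.asarray(center_mask, dtype=bool))
    shape = maps.grid_shape
    offsets = sphere_offsets(config.radius_voxels)
    n_pairs = condensed_length(maps.n_conditions)
    out = np.full(shape + (n_pairs,), np.nan)

    # flat lookup of in-mask voxels for fast sphere ∩ mask extraction
    flat_mask = maps.brain_mask.ravel()
    t_flat = maps.t_values.reshape(maps.n_conditions, -1)
    strides = np.array([shape[1] * shape[2], shape[2], 1])

    centers = np.argwhere(centers_mask)
    n_zero_var = 0
    for center in centers:
        vox = center[None, :] + offsets
        ok = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
        vox = vox[ok]
        flat = vox @ strides
        flat = flat[flat_mask[flat]]
        if flat.size < config.min_voxels:
            continue
        vec = _pattern_rdm_vector(t_flat[:, flat])
        if np.isnan(vec).any():
            n_zero_var += 1
        out[center[0], center[1], center[2]] = vec
    if n_zero_var:
        logger.warning("searchlight: %d spheres had zero-variance condition patterns", n_zero_var)
    return RDMMap(out, list(maps.condition_ids), maps.brain_mask, maps.affine)


def roi_rdm(rdm_map: RDMMap, roi_mask: np.ndarray) -> RDM:
    """Element-wise mean over the non-missing voxel RDMs inside an ROI mask."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != rdm_map.grid_shape:
        raise ValueError("ROI mask shape does not match RDM map grid")
    usable = roi_mask & rdm_map.computed_mask()
    if not usable.any():
        raise ValueError("ROI does not intersect any computed searchlight voxel")
    vectors = rdm_map.vectors[usable]
    with np.errstate(invalid="ignore"):
        mean_vec = np.nanmean(vectors, axis=0)
    from .rdm import vector_to_square

    return RDM(vector_to_square(mean_vec), rdm_map.condition_ids, rdm_map.metric_tag)
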
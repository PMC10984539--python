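"""MEG-fMRI fusion and model RSA via partial Spearman correlation.

At every time point the (subject-averaged) MEG RDM is correlated with a
target RDM — a subject's fMRI ROI RDM, a voxel RDM, or a model RDM — using
Spearman partial correlation with a confound RDM (typically GIST) regressed
out.  The estimator is rank-then-residualize: all three condensed RDM
vectors are rank-transformed (average ranks for ties), the confound ranks
are regressed out of the other two by least squares with intercept, and the
Pearson correlation of the residuals is returned; in the three-variable case
this equals the closed form
``r_xy.z = (r_xy − r_xz·r_yz) / sqrt((1 − r_xz²)(1 − r_yz²))`` on ranks.

Missing RDM entries (NaN) are handled pairwise-complete: pairs missing in
any of the three vectors are dropped, requiring at least 4 and at least 50%
of pairs present, otherwise the output is missing (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .rdm import RDM, RDMSeries
from .searchlight import RDMMap

__all__ = ["FusionSeries", "FusionMap", "partial_spearman", "fusion_series", "whole_brain_fusion", "difference_contrast"]

MIN_PAIRS = 4
MIN_FRACTION_PRESENT = 0.5


@dataclass
class FusionSeries:
    """Per-subject ROI/model fusion time courses, shape (n_subjects, n_times)."""

    values: np.ndarray
    time_axis: np.ndarray
    label: str = "AllConditions"  # High | Low | Difference | AllConditions

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.values.shape[1] != self.time_axis.size:
            raise ValueError("values/time axis mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def grand_average(self) -> np.ndarray:
        return self.values.mean(axis=0)


@dataclass
class FusionMap:
    """Per-subject whole-brain fusion, shape (n_subjects, nx, ny, nz, n_times)."""

    values: np.ndarray
    time_axis: np.ndarray
    affine: np.ndarray
    label: str = "AllConditions"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 5 or self.values.shape[-1] != len(self.time_axis):
            raise ValueError("FusionMap values must be (subjects, x, y, z, times)")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


def _rank_standardize(v: np.ndarray) -> np.ndarray:
    """Rank rows (average ties), then center and scale to unit norm.

    Rows that are constant after ranking become all-NaN.
    """
    r = rankdata(v, axis=-1).astype(float)
    r -= r.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(r, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = r / norm
    out[np.broadcast_to(norm == 0, out.shape)] = np.nan
    return out


def partial_spearman(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Spearman correlation of ``x`` and ``y`` controlling for ``z``.

    Pairwise-complete over NaNs; returns NaN when fewer than 4 pairs (or
    fewer than half) remain, or when a vector is constant after ranking.
    """
    x, y, z = (np.asarray(v, dtype=float).ravel() for v in (x, y, z))
    if not (x.size == y.size == z.size):
        raise ValueError("vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    if ok.sum() < max(MIN_PAIRS, int(np.ceil(MIN_FRACTION_PRESENT * x.size))):
        return float("nan")
    rx, ry, rz = (rankdata(v[ok]) for v in (x, y, z))
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")  # constant after ranking: correlation undefined
    design = np.column_stack([np.ones(rz.size), rz])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    nx, ny = np.linalg.norm(res_x), np.linalg.norm(res_y)
    if nx == 0 or ny == 0:
        return float("nan")
    return float(np.clip(res_x @ res_y / (nx * ny), -1.0, 1.0))


def _check_order(meg: RDMSeries, confound: RDM, targets) -> None:
    ids = meg.condition_ids
    if confound.condition_ids != ids:
        raise ValueError("condition order mismatch between MEG series and confound RDM")
    for t in targets:
        if t.condition_ids != ids:
            raise ValueError("condition order mismatch between MEG series and target RDM")


def _partial_series(x_unit: np.ndarray, x_raw: np.ndarray, y: np.ndarray, z_unit: np.ndarray, z_raw: np.ndarray) -> np.ndarray:
    """Partial Spearman of each row of x with y given z (no-NaN fast path,
    scalar fallback otherwise).  x_unit/z_unit are rank-standardized."""
    if np.isfinite(y).all() and np.isfinite(x_raw).all() and np.isfinite(z_raw).all():
        yu = _rank_standardize(y)
        r_xy = x_unit @ yu
        r_xz = x_unit @ z_unit
        r_yz = yu @ z_unit
        denom = (1 - r_xz**2) * (1 - r_yz**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (r_xy - r_xz * r_yz) / np.sqrt(denom)
        out[denom <= 1e-12] = np.nan  # (near-)collinear with the confound
        return np.clip(out, -1.0, 1.0)
    return np.array([partial_spearman(xt, y, z_raw) for xt in x_raw])


def fusion_series(meg: RDMSeries, target_rdms, confound: RDM, label: str = "AllConditions") -> FusionSeries:
    """Correlate the subject-mean MEG RDM series with per-subject target RDMs.

    ``target_rdms`` is one RDM per subject (a single RDM is treated as one
    subject).  Output shape: (n_subjects, n_times).
    """
    if isinstance(target_rdms, RDM):
        target_rdms = [target_rdms]
    _check_order(meg, confound, target_rdms)
    x_raw = meg.vectors()  # (T, P)
    z_raw = confound.vector()
    x_unit = _rank_standardize(x_raw)
    z_unit = _rank_standardize(z_raw)
    rows = [
        _partial_series(x_unit, x_raw, t.vector(), z_unit, z_raw) for t in target_rdms
    ]
    return FusionSeries(np.vstack(rows), meg.time_axis, label)


def whole_brain_fusion(meg: RDMSeries, rdm_maps, confound: RDM, label: str = "AllConditions") -> FusionMap:
    """Per-voxel fusion: one (x, y, z, t) correlation volume per subject.

    ``rdm_maps`` is one searchlight :class:`RDMMap` per subject.  Voxels not
    computed in a subject's map stay NaN for that subject.
    """
    if isinstance(rdm_maps, RDMMap):
        rdm_maps = [rdm_maps]
    ids = meg.condition_ids
    for m in rdm_maps:
        if m.condition_ids != ids:
            raise ValueError("condition order mismatch between MEG series and RDM map")
    if confound.condition_ids != ids:
        raise ValueError("condition order mismatch between MEG series and confound RDM")
    x_raw = meg.vectors()
    x_unit = _rank_standardize(x_raw)
    z_raw = confound.vector()
    z_unit = _rank_standardize(z_raw)

    shape = rdm_maps[0].grid_shape
    n_t = meg.n_times
    out = np.full((len(rdm_maps), *shape, n_t), np.nan)
    for s, rmap in enumerate(rdm_maps):
        if rmap.grid_shape != shape:
            raise ValueError("grid shape mismatch across subjects")
        computed = rmap.computed_mask()
        vox = np.argwhere(computed)
        vecs = rmap.vectors[computed]  # (V, P)
        clean = np.isfinite(vecs).all(axis=1)
        if clean.any() and np.isfinite(x_raw).all():
            yu = _rank_standardize(vecs[clean])  # (Vc, P)
            r_xy = x_unit @ yu.T  # (T, Vc)
            r_xz = x_unit @ z_unit  # (T,)
            r_yz = yu @ z_unit  # (Vc,)
            denom = (1 - r_xz[:, None] ** 2) * (1 - r_yz[None, :] ** 2)
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = (r_xy - r_xz[:, None] * r_yz[None, :]) / np.sqrt(denom)
            vals[denom <= 1e-12] = np.nan
            vals = np.clip(vals, -1.0, 1.0)
            cv = vox[clean]
            out[s, cv[:, 0], cv[:, 1], cv[:, 2], :] = vals.T
        for v in vox[~clean]:
            y = rmap.vectors[v[0], v[1], v[2]]
            out[s, v[0], v[1], v[2], :] = [partial_spearman(xt, y, z_raw) for xt in x_raw]
    return FusionMap(out, meg.time_axis, rdm_maps[0].affine, label)


def difference_contrast(high, low):
    """Element-wise High − Low fusion contrast (series or maps), per subject."""
    if type(high) is not type(low):
        raise ValueError("high and low must be the same fusion type")
    if high.values.shape != low.values.shape:
        raise ValueError(f"shape mismatch {high.values.shape} vs {low.values.shape}")
    if not np.array_equal(high.time_axis, low.time_axis):
        raise ValueError("time axis mismatch")
    diff = high.values - low.values
    if isinstance(high, FusionSeries):
        return FusionSeries(diff, high.time_axis, "Difference")
    return FusionMap(diff, high.time_axis, high.affine, "Difference")
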
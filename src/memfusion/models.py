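"""Model RDMs: GIST descriptors, generic feature-matrix RDMs, memorability RDM.

The GIST descriptor summarizes an image by the pooled energies of a Gabor
filterbank — 8 orientations × 4 spatial-frequency scales, averaged over a
4 × 4 spatial grid, giving a 512-dimensional vector at the defaults.  The
dialect implemented here: convert to grayscale, resize to a fixed square,
globally standardize intensities (making the descriptor exactly invariant to
affine intensity rescaling), apply divisive local-contrast normalization,
filter in the frequency domain with log-Gabor-like transfer functions, and
average the filter-response magnitudes per grid cell.

Feature RDMs are 1 − Pearson correlation between condition feature vectors;
the memorability RDM is the absolute difference of scalar memorability
scores, |m_i − m_j|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .rdm import RDM
from .synth import StimulusSet

__all__ = ["GISTConfig", "compute_gist", "gabor_transfer_functions", "feature_rdm", "memorability_rdm"]


@dataclass
class GISTConfig:
    n_orientations: int = 8
    n_scales: int = 4
    grid: int = 4
    image_size: int = 128

    def __post_init__(self):
        if min(self.n_orientations, self.n_scales, self.grid) < 1:
            raise ValueError("GIST config fields must be positive")
        if self.image_size < 2 * self.grid:
            raise ValueError("image_size too small for the pooling grid")

    @property
    def descriptor_length(self) -> int:
        return self.n_orientations * self.n_scales * self.grid**2


def gabor_transfer_functions(config: GISTConfig) -> np.ndarray:
    """Frequency-domain filterbank, shape (n_scales·n_orientations, H, W).

    Each transfer function is a polar-separable Gabor: log-Gaussian in radial
    frequency around a per-scale center frequency (halving per scale) and
    Gaussian in orientation.  Filters cover both half-planes so responses to
    real images are real up to numerical error.
    """
    n = config.image_size
    fx = np.fft.fftfreq(n)
    fy = np.fft.fftfreq(n)
    gx, gy = np.meshgrid(fx, fy, indexing="ij")
    radius = np.hypot(gx, gy)
    radius[0, 0] = 1e-9  # avoid log(0) at DC
    theta = np.arctan2(gy, gx)

    sigma_f = 0.35  # radial log bandwidth
    sigma_t = (np.pi / config.n_orientations) / 1.7
    filters = []
    for s in range(config.n_scales):
        f0 = 0.25 / (2**s)  # cycles/pixel, halving per scale
        radial = np.exp(-((np.log(radius / f0)) ** 2) / (2 * sigma_f**2))
        radial[0, 0] = 0.0
        for o in range(config.n_orientations):
            t0 = o * np.pi / config.n_orientations
            # angular distance folded to [0, pi/2] (filters are symmetric)
            dt = np.angle(np.exp(1j * 2 * (theta - t0))) / 2
            angular = np.exp(-(dt**2) / (2 * sigma_t**2))
            filters.append(radial * angular)
    return np.stack(filters)


def _prefilter(img: np.ndarray, sigma: float = 4.0) -> np.ndarray:
    """Divisive local-contrast normalization (whitening surrogate)."""
    local_mean = ndimage.gaussian_filter(img, sigma)
    centered = img - local_mean
    local_energy = np.sqrt(ndimage.gaussian_filter(centered**2, sigma))
    return centered / (0.2 + local_energy)


def channel_energies(image: np.ndarray, config: GISTConfig | None = None) -> np.ndarray:
    """Mean filter-response magnitude per channel, shape (n_scales·n_orientations,).

    Pools each channel over the whole image (no spatial grid); used to test
    orientation/scale selectivity directly.
    """
    config = config or GISTConfig()
    img = _standardize_image(image, config)
    filters = gabor_transfer_functions(config)
    spectrum = np.fft.fft2(img)
    responses = np.abs(np.fft.ifft2(spectrum[None] * filters))
    return responses.mean(axis=(1, 2))


def _standardize_image(image: np.ndarray, config: GISTConfig) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:  # RGB -> grayscale (ITU-R 601 luma)
        image = image @ np.array([0.299, 0.587, 0.114])
    if image.ndim != 2 or min(image.shape) < 2:
        raise ValueError(f"degenerate image dimensions {image.shape}")
    zoom = (config.image_size / image.shape[0], config.image_size / image.shape[1])
    img = ndimage.zoom(image, zoom, order=1, grid_mode=True, mode="grid-mirror")
    sd = img.std()
    img = (img - img.mean()) / (sd if sd > 0 else 1.0)
    return _prefilter(img)


def compute_gist(image: np.ndarray, config: GISTConfig | None = None) -> np.ndarray:
    """GIST descriptor: mean filter-energy per (scale, orientation, grid cell).

    Returns a non-negative vector of length
    ``n_orientations · n_scales · grid²`` (512 at the defaults), ordered
    scale-major, then orientation, then grid cells row-major.
    """
    config = config or GISTConfig()
    img = _standardize_image(image, config)
    filters = gabor_transfer_functions(config)
    spectrum = np.fft.fft2(img)
    responses = np.abs(np.fft.ifft2(spectrum[None] * filters))  # (F, H, W)

    g = config.grid
    cell = config.image_size // g
    trimmed = responses[:, : cell * g, : cell * g]
    pooled = trimmed.reshape(len(filters), g, cell, g, cell).mean(axis=(2, 4))
    return pooled.reshape(-1)


def feature_rdm(features: np.ndarray, condition_ids=None) -> RDM:
    """1 − Pearson RDM from a conditions × dims feature matrix."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need a 2-D feature matrix with >= 2 conditions")
    if condition_ids is None:
        condition_ids = [f"cond{i:04d}" for i in range(features.shape[0])]
    sd = features.std(axis=1)
    if (sd == 0).any():
        bad = [condition_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance feature rows for conditions: {bad[:5]}")
    corr = np.corrcoef(features)
    values = 1.0 - np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(values, 0.0)
    return RDM(values, list(condition_ids), "one_minus_pearson")


def memorability_rdm(stimuli: StimulusSet, ids=None) -> RDM:
    """|m_i − m_j| RDM over ``ids`` (default: all conditions, in set order)."""
    ids = list(ids) if ids is not None else list(stimuli.condition_ids)
    m = stimuli.scores_for(ids)
    values = np.abs(m[:, None] - m[None, :])
    return RDM(values, ids, "abs_score_diff")
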
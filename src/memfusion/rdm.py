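"""Representational dissimilarity matrix (RDM) containers.

An RDM is a square symmetric matrix of pairwise condition dissimilarities,
indexed by an explicit, ordered list of condition labels.  Three metrics are
used throughout the package:

``decoding_accuracy``
    pairwise classifier accuracy in percent (chance = 50), from MEG decoding;
``one_minus_pearson``
    1 − Pearson correlation between feature/pattern vectors, in [0, 2];
``abs_score_diff``
    absolute difference of scalar condition scores in [0, 1].

Vectorized RDMs use a single package-wide convention: the lower triangle
excluding the diagonal, row-major in the fixed condition order (the order
produced by ``numpy.tril_indices(n, -1)``).  For 78 conditions this vector
has length 3003; for 156 conditions, 12090.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

METRICS = ("decoding_accuracy", "one_minus_pearson", "abs_score_diff")

__all__ = ["RDM", "RDMSeries", "condensed_length", "square_to_vector", "vector_to_square"]


def condensed_length(n_conditions: int) -> int:
    """Length of the vectorized lower triangle for ``n_conditions``."""
    return n_conditions * (n_conditions - 1) // 2


def square_to_vector(values: np.ndarray) -> np.ndarray:
    """Vectorize the strict lower triangle (row-major) of a square RDM.

    Works on a single matrix ``(n, n)`` or a stack ``(..., n, n)``.
    """
    values = np.asarray(values)
    n = values.shape[-1]
    if values.shape[-2] != n:
        raise ValueError(f"expected square trailing dimensions, got {values.shape}")
    i, j = np.tril_indices(n, -1)
    return values[..., i, j]


def vector_to_square(vector: np.ndarray, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`square_to_vector`; fills a symmetric matrix."""
    vector = np.asarray(vector)
    p = vector.shape[-1]
    n = int(round((1 + np.sqrt(1 + 8 * p)) / 2))
    if condensed_length(n) != p:
        raise ValueError(f"vector length {p} is not a triangular number")
    i, j = np.tril_indices(n, -1)
    out = np.full(vector.shape[:-1] + (n, n), diagonal, dtype=float)
    out[..., i, j] = vector
    out[..., j, i] = vector
    return out


def _check_labels(labels, n):
    labels = list(labels)
    if len(labels) != n:
        raise ValueError(f"{len(labels)} condition labels for matrix of size {n}")
    if len(set(labels)) != n:
        raise ValueError("condition labels must be unique")
    return labels


@dataclass
class RDM:
    """A symmetric condition-dissimilarity matrix with labeled conditions."""

    values: np.ndarray
    condition_ids: list = field(default_factory=list)
    metric_tag: str = "one_minus_pearson"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"RDM values must be square, got shape {self.values.shape}")
        if self.metric_tag not in METRICS:
            raise ValueError(f"unknown metric_tag {self.metric_tag!r}")
        self.condition_ids = _check_labels(self.condition_ids, self.n_conditions)
        finite = self.values[np.isfinite(self.values)]
        sym = self.values.copy()
        sym[~np.isfinite(self.values)] = 0.0
        if not np.allclose(sym, sym.T, atol=1e-10):
            raise ValueError("RDM values must be symmetric")
        if self.metric_tag == "one_minus_pearson" and finite.size:
            if finite.min() < -1e-9 or finite.max() > 2 + 1e-9:
                raise ValueError("one_minus_pearson entries must lie in [0, 2]")
        if self.metric_tag == "abs_score_diff" and finite.size:
            if finite.min() < -1e-9 or finite.max() > 1 + 1e-9:
                raise ValueError("abs_score_diff entries must lie in [0, 1]")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    def vector(self) -> np.ndarray:
        """Condensed lower-triangle vector (package convention)."""
        return square_to_vector(self.values)

    def subset(self, labels) -> "RDM":
        """Sub-RDM for ``labels``, in the order given (never silently reordered)."""
        index = {c: k for k, c in enumerate(self.condition_ids)}
        missing = [c for c in labels if c not in index]
        if missing:
            raise KeyError(f"conditions not in RDM: {missing[:5]}")
        idx = np.array([index[c] for c in labels])
        return RDM(self.values[np.ix_(idx, idx)], list(labels), self.metric_tag)


@dataclass
class RDMSeries:
    """One RDM per time point on a millisecond time axis.

    ``values`` has shape ``(n_times, n_conditions, n_conditions)``.
    """

    values: np.ndarray
    time_axis: np.ndarray
    condition_ids: list = field(default_factory=list)
    metric_tag: str = "decoding_accuracy"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError(f"RDMSeries values must be (T, n, n), got {self.values.shape}")
        if self.time_axis.shape != (self.values.shape[0],):
            raise ValueError("time axis length does not match number of RDMs")
        if self.metric_tag not in METRICS:
            raise ValueError(f"unknown metric_tag {self.metric_tag!r}")
        self.condition_ids = _check_labels(self.condition_ids, self.n_conditions)

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def rdm_at(self, time_ms: float) -> RDM:
        t = int(np.argmin(np.abs(self.time_axis - time_ms)))
        return RDM(self.values[t], self.condition_ids, self.metric_tag)

    def vectors(self) -> np.ndarray:
        """Condensed vectors, shape ``(n_times, n_pairs)``."""
        return square_to_vector(self.values)

    def subset(self, labels) -> "RDMSeries":
        index = {c: k for k, c in enumerate(self.condition_ids)}
        missing = [c for c in labels if c not in index]
        if missing:
            raise KeyError(f"conditions not in RDMSeries: {missing[:5]}")
        idx = np.array([index[c] for c in labels])
        return RDMSeries(
            self.values[:, idx[:, None], idx[None, :]],
            self.time_axis,
            list(labels),
            self.metric_tag,
        )

    def mean_with(self, others) -> "RDMSeries":
        """Arithmetic mean of this series with ``others`` (e.g. across subjects)."""
        stack = [self.values] + [o.values for o in others]
        for o in others:
            if o.condition_ids != self.condition_ids:
                raise ValueError("condition order mismatch across averaged series")
            if not np.array_equal(o.time_axis, self.time_axis):
                raise ValueError("time axis mismatch across averaged series")
        return RDMSeries(np.mean(stack, axis=0), self.time_axis, self.condition_ids, self.metric_tag)


def time_axis_ms(start: float = -200.0, end: float = 1000.0, step: float = 1.0) -> np.ndarray:
    """Millisecond time axis with ``(end - start) / step + 1`` samples."""
    n = int(round((end - start) / step)) + 1
    return start + step * np.arange(n)
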
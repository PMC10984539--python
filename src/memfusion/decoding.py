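"""MEG RDM time series via pairwise linear-SVM decoding of pseudo-trials.

For every unordered pair of conditions and every time point, the single-trial
sensor patterns of the two conditions are randomly binned into groups of
``bin_size`` trials and bin-averaged into M pseudo-trials per condition.
A linear SVM is trained on M−1 pseudo-trials per condition and tested on the
held-out pair; held-out assignment is rotated over all M folds.  The whole
procedure (random binning included) is repeated ``n_iterations`` times and
the mean decoding accuracy (percent) populates entry (i, j) of that time
point's RDM.  Chance is 50%.

With one training pseudo-trial per class (M = 2, the scaled-down test
profile) the C-SVM decision boundary is analytically the perpendicular
bisector of the two training points for any C > 0, so this case is computed
vectorised as a nearest-centroid rule; equality with the generic SVM path is
asserted in the test suite.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .rdm import RDMSeries

__all__ = ["TrialSet", "DecodingConfig", "bin_pseudotrials", "pairwise_decode", "decode_rdm_series"]


@dataclass
class TrialSet:
    """Per-condition single-trial sensor patterns on a common time axis.

    ``patterns`` has shape ``(n_conditions, n_trials, n_sensors, n_times)``.
    """

    patterns: np.ndarray
    time_axis: np.ndarray
    condition_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.patterns = np.asarray(self.patterns)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.patterns.ndim != 4:
            raise ValueError(f"patterns must be (conditions, trials, sensors, times), got {self.patterns.shape}")
        if self.time_axis.shape != (self.patterns.shape[3],):
            raise ValueError("time axis length does not match patterns")
        if len(self.condition_ids) != self.patterns.shape[0]:
            raise ValueError("condition_ids length does not match patterns")

    def subset(self, labels) -> "TrialSet":
        index = {c: k for k, c in enumerate(self.condition_ids)}
        idx = np.array([index[c] for c in labels])
        return TrialSet(self.patterns[idx], self.time_axis, list(labels))


@dataclass
class DecodingConfig:
    bin_size: int = 3
    n_iterations: int = 100
    svm_c: float = 1.0
    standardize: bool = False  # per-feature z-scoring from training pseudo-trials
    rotate_folds: bool = True  # rotate the held-out pseudo-trial over all M folds
    seed: int = 0

    def __post_init__(self):
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def bin_pseudotrials(trials: np.ndarray, bin_size: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly assign trials to bins of ``bin_size`` and average each bin.

    Returns ``M = floor(N / bin_size)`` pseudo-trials; the ``N mod bin_size``
    leftover trials are discarded for this draw (a fresh random assignment —
    hence fresh leftovers — is made on every iteration).
    """
    trials = np.asarray(trials)
    n = trials.shape[0]
    if n < bin_size:
        raise ValueError(f"too few trials ({n}) for bin size {bin_size}")
    m = n // bin_size
    order = rng.permutation(n)[: m * bin_size]
    grouped = trials[order].reshape((m, bin_size) + trials.shape[1:])
    return grouped.mean(axis=1)


def _fold_accuracy(train_a, train_b, test_a, test_b, config: DecodingConfig) -> float:
    x_train = np.vstack([train_a, train_b])
    if config.standardize:
        mu = x_train.mean(axis=0)
        sd = x_train.std(axis=0)
        sd[sd == 0] = 1.0
        x_train = (x_train - mu) / sd
        test_a = (test_a - mu) / sd
        test_b = (test_b - mu) / sd
    y = np.r_[np.zeros(len(train_a)), np.ones(len(train_b))]
    clf = SVC(kernel="linear", C=config.svm_c)
    clf.fit(x_train, y)
    pred = clf.predict(np.vstack([test_a, test_b]))
    return float(pred[0] == 0) + float(pred[1] == 1)


def pairwise_decode(pseudo_a: np.ndarray, pseudo_b: np.ndarray, config: DecodingConfig | None = None) -> float:
    """Leave-one-pseudo-trial-out linear-SVM accuracy (percent) for one pair.

    ``pseudo_a`` and ``pseudo_b`` are (M, n_features) pseudo-trial matrices
    for a single time point; this scores one binning draw (no iteration loop).
    """
    config = config or DecodingConfig()
    pseudo_a = np.asarray(pseudo_a, dtype=float)
    pseudo_b = np.asarray(pseudo_b, dtype=float)
    m = pseudo_a.shape[0]
    if m < 2 or pseudo_b.shape[0] != m:
        raise ValueError("both classes need the same M >= 2 pseudo-trials")
    folds = range(m) if config.rotate_folds else [m - 1]
    correct = 0.0
    for f in folds:
        keep = np.arange(m) != f
        correct += _fold_accuracy(
            pseudo_a[keep], pseudo_b[keep], pseudo_a[f], pseudo_b[f], config
        )
    return 100.0 * correct / (2 * len(list(folds)))


def _decode_all_pairs_m2(pseudo: np.ndarray, pair_i: np.ndarray, pair_j: np.ndarray) -> np.ndarray:
    """Vectorised exact SVM decoding for M = 2 over all pairs and time points.

    ``pseudo``: (n_conditions, 2, n_sensors, n_times) for one binning draw.
    Returns correct-classification counts, shape (n_pairs, n_times), out of 4.
    """
    a = pseudo[pair_i]  # (P, 2, p, T)
    b = pseudo[pair_j]
    correct = np.zeros((len(pair_i), pseudo.shape[-1]))
    for held in (0, 1):
        tr = 1 - held
        w = a[:, tr] - b[:, tr]  # (P, p, T)
        mid = 0.5 * (a[:, tr] + b[:, tr])
        score_a = np.einsum("ipt,ipt->it", w, a[:, held] - mid)
        score_b = np.einsum("ipt,ipt->it", w, b[:, held] - mid)
        correct += (score_a > 0).astype(float) + (score_b < 0).astype(float)
    return correct


def decode_rdm_series(trial_set: TrialSet, config: DecodingConfig | None = None) -> RDMSeries:
    """Pairwise-decoding RDM at every time point, averaged over iterations.

    Bin assignment is redrawn per iteration and shared across condition pairs
    within an iteration.  Entries are percent accuracy; the (undefined)
    diagonal is set to 0.  Symmetry is exact: each unordered pair is computed
    once.
    """
    config = config or DecodingConfig()
    n_cond, n_trials, n_sens, n_t = trial_set.patterns.shape
    if n_cond < 2:
        raise ValueError("need >= 2 conditions to decode")
    m = n_trials // config.bin_size
    if m < 2:
        raise ValueError(
            f"{n_trials} trials with bin size {config.bin_size} give M={m} pseudo-trials; need M >= 2"
        )
    pair_i, pair_j = np.tril_indices(n_cond, -1)
    patterns = np.asarray(trial_set.patterns, dtype=float)

    # bin draws keyed by (seed, iteration, condition id) so that decoding a
    # condition subset reproduces the corresponding sub-block of the full RDM
    cond_keys = [zlib.crc32(str(c).encode()) for c in trial_set.condition_ids]

    fast = m == 2 and config.rotate_folds and not config.standardize
    acc = np.zeros((len(pair_i), n_t))
    for it in range(config.n_iterations):
        pseudo = np.stack(
            [
                bin_pseudotrials(
                    patterns[c],
                    config.bin_size,
                    np.random.default_rng([config.seed, it, cond_keys[c]]),
                )
                for c in range(n_cond)
            ]
        )
        if fast:
            acc += _decode_all_pairs_m2(pseudo, pair_i, pair_j)
        else:
            for p, (i, j) in enumerate(zip(pair_i, pair_j)):
                for t in range(n_t):
                    acc[p, t] += pairwise_decode(pseudo[i, :, :, t], pseudo[j, :, :, t], config)
    if fast:
        acc *= 100.0 / (4 * config.n_iterations)
    else:
        acc /= config.n_iterations

    values = np.zeros((n_t, n_cond, n_cond))
    values[:, pair_i, pair_j] = acc.T
    values[:, pair_j, pair_i] = acc.T
    return RDMSeries(values, trial_set.time_axis, list(trial_set.condition_ids), "decoding_accuracy")
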
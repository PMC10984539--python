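"""Partial Spearman fusion: estimator, series, maps, contrasts."""

import numpy as np
import pytest
from scipy.stats import rankdata, spearmanr

from memfusion.fusion import (
    FusionSeries,
    difference_contrast,
    fusion_series,
    partial_spearman,
    whole_brain_fusion,
)
from memfusion.rdm import RDM, RDMSeries, time_axis_ms, vector_to_square
from memfusion.searchlight import RDMMap


def closed_form_partial(x, y, z):
    """r_xy.z = (r_xy − r_xz r_yz) / sqrt((1−r_xz²)(1−r_yz²)) on ranks."""
    rx, ry, rz = rankdata(x), rankdata(y), rankdata(z)
    r = np.corrcoef([rx, ry, rz])
    return (r[0, 1] - r[0, 2] * r[1, 2]) / np.sqrt((1 - r[0, 2] ** 2) * (1 - r[1, 2] ** 2))


def rdm_from_vector(vec, ids):
    return RDM(vector_to_square(np.asarray(vec, dtype=float)), ids)


class TestPartialSpearman:
    def test_self_correlation_is_one(self, rng):
        x = rng.random(20)
        z = rng.random(20)
        assert partial_spearman(x, x, z) == pytest.approx(1.0, abs=1e-9)

    def test_confound_fully_removed(self, rng):
        z = rng.random(500)
        y = np.exp(z)  # monotone transform of the confound
        x = rng.random(500)
        assert abs(partial_spearman(x, y, z)) < 0.1

    def test_matches_closed_form_on_random_triples(self, rng):
        for _ in range(100):
            x, y, z = rng.random((3, 8))
            assert partial_spearman(x, y, z) == pytest.approx(closed_form_partial(x, y, z), abs=1e-10)

    def test_constant_confound_equals_plain_spearman(self, rng):
        for _ in range(100):
            x, y = rng.random((2, 15))
            got = partial_spearman(x, y, np.ones(15))
            assert got == pytest.approx(spearmanr(x, y).statistic, abs=1e-10)

    def test_rank_invariance_to_monotone_transforms(self, rng):
        x, y, z = rng.random((3, 30))
        base = partial_spearman(x, y, z)
        assert partial_spearman(np.exp(x), y**3 + y, z) == pytest.approx(base, abs=1e-10)

    def test_missing_entries_pairwise_complete(self, rng):
        x, y, z = rng.random((3, 40))
        x2 = x.copy()
        x2[:3] = np.nan
        expected = closed_form_partial(x[3:], y[3:], z[3:])
        assert partial_spearman(x2, y, z) == pytest.approx(expected, abs=1e-10)

    def test_too_many_missing_returns_nan(self, rng):
        x, y, z = rng.random((3, 10))
        x[:6] = np.nan  # fewer than half present
        assert np.isnan(partial_spearman(x, y, z))

    def test_constant_vector_returns_nan(self, rng):
        assert np.isnan(partial_spearman(np.ones(10), rng.random(10), rng.random(10)))


class TestFusionSeries:
    def make_series(self, rng, n_cond=6, n_t=40):
        t = np.arange(n_t, dtype=float)
        ids = [f"c{i}" for i in range(n_cond)]
        n_pairs = n_cond * (n_cond - 1) // 2
        vecs = rng.random((n_t, n_pairs))
        values = vector_to_square(vecs)
        return RDMSeries(values, t, ids, "decoding_accuracy"), ids

    def test_planted_peak_recovered(self, rng):
        series, ids = self.make_series(rng)
        target = series.rdm_at(17.0)
        confound = rdm_from_vector(rng.random(15), ids)
        fs = fusion_series(series, [target], confound)
        assert int(np.argmax(fs.values[0])) == 17

    def test_output_shape_full_axis(self, rng):
        t = time_axis_ms(-200, 1000, 1)
        ids = list("abcde")
        series = RDMSeries(vector_to_square(rng.random((t.size, 10))), t, ids)
        targets = [rdm_from_vector(rng.random(10), ids) for _ in range(15)]
        fs = fusion_series(series, targets, rdm_from_vector(rng.random(10), ids))
        assert fs.values.shape == (15, 1201)

    def test_confound_structure_yields_zero_series(self, rng):
        series, ids = self.make_series(rng, n_cond=12, n_t=200)
        confound_vec = rng.random(66)
        confound = rdm_from_vector(confound_vec, ids)
        # an exact monotone copy has zero residual: undefined by contract
        exact = rdm_from_vector(0.5 * confound_vec + 0.5, ids)
        assert np.isnan(fusion_series(series, [exact], confound).values).all()
        # confound-dominated target: the partialled series is centred on zero
        target = rdm_from_vector(confound_vec + 0.2 * rng.random(66), ids)
        fs = fusion_series(series, [target], confound)
        assert abs(fs.values.mean()) < 0.05

    def test_condition_order_mismatch_is_hard_error(self, rng):
        series, ids = self.make_series(rng)
        shuffled = list(reversed(ids))
        target = rdm_from_vector(rng.random(15), shuffled)
        confound = rdm_from_vector(rng.random(15), ids)
        with pytest.raises(ValueError, match="order"):
            fusion_series(series, [target], confound)

    def test_vectorized_path_matches_scalar_estimator(self, rng):
        series, ids = self.make_series(rng, n_cond=7, n_t=12)
        target = rdm_from_vector(rng.random(21), ids)
        confound = rdm_from_vector(rng.random(21), ids)
        fs = fusion_series(series, [target], confound)
        expected = [
            partial_spearman(series.vectors()[t], target.vector(), confound.vector())
            for t in range(12)
        ]
        assert np.allclose(fs.values[0], expected, atol=1e-10)


class TestWholeBrain:
    def test_voxels_outside_mask_absent_and_planted_region_found(self, rng):
        shape = (5, 5, 5)
        n_t, ids = 30, list("abcdef")
        t = np.arange(n_t, dtype=float)
        meg_vecs = rng.random((n_t, 15))
        series = RDMSeries(vector_to_square(meg_vecs), t, ids)
        confound = rdm_from_vector(rng.random(15), ids)

        vectors = np.full(shape + (15,), np.nan)
        mask = np.zeros(shape, dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        for v in np.argwhere(mask):
            vectors[tuple(v)] = rng.random(15)
        # plant the MEG geometry at time 10 into one voxel
        vectors[2, 2, 2] = meg_vecs[10]
        rmap = RDMMap(vectors, ids, mask, np.eye(4))
        fmap = whole_brain_fusion(series, [rmap], confound)
        assert np.isnan(fmap.values[0, 0, 0, 0]).all()  # outside mask
        assert np.unravel_index(np.nanargmax(fmap.values[0, ..., 10]), shape) == (2, 2, 2)


class TestDifferenceContrast:
    def test_self_difference_zero_and_antisymmetry(self, rng):
        t = np.arange(10.0)
        a = FusionSeries(rng.random((4, 10)), t, "High")
        b = FusionSeries(rng.random((4, 10)), t, "Low")
        assert np.all(difference_contrast(a, a).values == 0)
        assert np.allclose(difference_contrast(a, b).values, -difference_contrast(b, a).values)
        assert difference_contrast(a, b).label == "Difference"

    def test_shape_mismatch_rejected(self, rng):
        t = np.arange(10.0)
        a = FusionSeries(rng.random((4, 10)), t)
        b = FusionSeries(rng.random((3, 10)), t)
        with pytest.raises(ValueError, match="shape"):
            difference_contrast(a, b)

    def test_planted_effect_monotone_in_amplitude(self, rng):
        """A High-only additive fusion effect grows with its amplitude."""
        t = np.arange(20.0)
        low = rng.standard_normal((5, 20)) * 0.1
        gaps = []
        for amplitude in (0.1, 0.3, 0.9):
            high = low + amplitude
            diff = difference_contrast(FusionSeries(high, t, "High"), FusionSeries(low, t, "Low"))
            gaps.append(diff.values.mean())
        assert gaps[0] < gaps[1] < gaps[2]
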
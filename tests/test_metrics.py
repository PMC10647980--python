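"""Surface-distance metrics against brute-force oracles, plus summaries."""

import math

import numpy as np
import pytest
from scipy import ndimage

from scos.metrics import (MetricRecord, asd, binarize, dice_coefficient,
                          directed_distances, evaluate, evaluate_case, hd95,
                          largest_cc_3d, max_hd, n_inf, summarize)
from .oracles import brute_surface_metrics


def _random_mask(rng, shape=(15, 15), p=0.25):
    return rng.random(shape) < p


class TestBinarize:
    def test_below_threshold_gives_empty(self):
        assert not binarize(np.full((3, 3), 0.4), 0.5).any()

    def test_boundary_inclusive(self):
        out = binarize(np.array([0.49, 0.5, 0.51]), 0.5)
        np.testing.assert_array_equal(out, [False, True, True])

    def test_idempotent_on_binary(self):
        m = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(binarize(binarize(m, 0.5), 0.5),
                                      binarize(m, 0.5))

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), 1.0)


class TestDirectedDistances:
    def test_identical_sets_all_zero(self):
        a = np.array([[0, 0], [2, 3]])
        np.testing.assert_array_equal(directed_distances(a, a), [0.0, 0.0])

    def test_three_four_five(self):
        d = directed_distances(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]))
        np.testing.assert_allclose(d, [5.0])

    def test_output_length_matches_source(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((7, 2)), rng.random((4, 2))
        assert len(directed_distances(a, b)) == 7

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            directed_distances(np.empty((0, 2)), np.array([[0.0, 0.0]]))


class TestSurfaceMetrics:
    def test_identical_masks_give_zero(self, unrotated_slice):
        m = unrotated_slice.masks["heart"]
        assert max_hd(m, m) == 0.0
        assert hd95(m, m) == 0.0
        assert asd(m, m) == 0.0

    def test_empty_prediction_is_infinite(self):
        y = np.zeros((6, 6), bool)
        y[2:4, 2:4] = True
        x = np.zeros_like(y)
        assert math.isinf(max_hd(x, y))
        assert math.isinf(hd95(x, y))
        assert math.isinf(asd(x, y))

    def test_empty_truth_is_an_error(self):
        x = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            max_hd(x, np.zeros((4, 4), bool))

    def test_single_pixel_masks_two_apart(self):
        x = np.zeros((5, 5), bool)
        y = np.zeros((5, 5), bool)
        x[2, 0] = True
        y[2, 2] = True
        assert asd(x, y) == pytest.approx(2.0)
        assert max_hd(x, y) == pytest.approx(2.0)

    def test_agrees_with_brute_force_oracle(self):
        """200 random mask pairs <=20x20: exact agreement with the
        all-pairs implementation, including the infinity convention."""
        rng = np.random.default_rng(42)
        for trial in range(200):
            shape = tuple(rng.integers(5, 21, size=2))
            x = _random_mask(rng, shape, p=rng.uniform(0.0, 0.5))
            y = _random_mask(rng, shape, p=rng.uniform(0.05, 0.5))
            if not y.any():
                continue
            ref = brute_surface_metrics(x, y)
            got = (max_hd(x, y), hd95(x, y), asd(x, y))
            if math.isinf(ref[0]):
                assert all(math.isinf(g) for g in got)
            else:
                np.testing.assert_allclose(got, ref, rtol=0, atol=1e-9)

    def test_oracle_agreement_with_anisotropic_spacing(self):
        rng = np.random.default_rng(3)
        spacing = (0.7, 1.3)
        for _ in range(30):
            x = _random_mask(rng, (12, 12), 0.3)
            y = _random_mask(rng, (12, 12), 0.3)
            if not (x.any() and y.any()):
                continue
            ref = brute_surface_metrics(x, y, spacing)
            got = (max_hd(x, y, spacing), hd95(x, y, spacing), asd(x, y, spacing))
            np.testing.assert_allclose(got, ref, atol=1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        x = np.zeros((20, 20), bool)
        y = np.zeros((20, 20), bool)
        x[3:8, 4:9] = rng.random((5, 5)) < 0.6
        y[4:9, 3:8] = rng.random((5, 5)) < 0.6
        xs, ys = np.roll(x, (5, 6), (0, 1)), np.roll(y, (5, 6), (0, 1))
        for f in (max_hd, hd95, asd):
            assert f(x, y) == pytest.approx(f(xs, ys), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = _random_mask(rng), _random_mask(rng)
        assert max_hd(x, y) == pytest.approx(max_hd(y, x))
        assert asd(x, y) == pytest.approx(asd(y, x))

    def test_hd95_never_exceeds_max_hd(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x, y = _random_mask(rng), _random_mask(rng)
            if x.any() and y.any():
                assert hd95(x, y) <= max_hd(x, y) + 1e-12

    def test_dilation_strictly_degrades_asd(self):
        y = np.zeros((21, 21), bool)
        y[8:13, 8:13] = True
        x = y.copy()
        prev = asd(x, y)
        for _ in range(3):
            x = ndimage.binary_dilation(x)
            cur = asd(x, y)
            assert cur > prev
            prev = cur


class TestLargestCC:
    def test_single_component_identity(self):
        v = np.zeros((4, 5, 5), bool)
        v[1:3, 1:4, 1:4] = True
        np.testing.assert_array_equal(largest_cc_3d(v), v)

    def test_keeps_largest_of_two(self):
        v = np.zeros((3, 8, 8), bool)
        v[0:2, 0:3, 0:3] = True          # 18 voxels
        v[2, 6:8, 6:8] = True            # 4 voxels
        out = largest_cc_3d(v)
        assert out.sum() == 18
        assert not out[2, 6, 6]

    def test_tie_break_is_deterministic(self):
        v = np.zeros((1, 5, 5), bool)
        v[0, 0, 0:2] = True
        v[0, 4, 3:5] = True
        out = largest_cc_3d(v)
        assert out.sum() == 2
        assert out[0, 0, 0]              # raster-first component survives
        np.testing.assert_array_equal(out, largest_cc_3d(v))

    def test_empty_passes_through(self):
        v = np.zeros((2, 3, 3), bool)
        assert not largest_cc_3d(v).any()


class TestEvaluate:
    def test_perfect_prediction(self, unrotated_slice):
        recs = evaluate_case(unrotated_slice.masks, unrotated_slice.masks)
        assert len(recs) == 3
        for r in recs:
            assert r.dice == 1.0
            assert r.max_hd == r.hd95 == r.asd == 0.0
        assert n_inf(recs) == 0

    def test_one_empty_organ_isolated(self, unrotated_slice):
        pred = {o: m.copy() for o, m in unrotated_slice.masks.items()}
        pred["cord"][:] = False
        recs = {r.organ: r for r in evaluate_case(pred, unrotated_slice.masks)}
        assert recs["cord"].is_inf and recs["cord"].dice == 0.0
        assert not recs["lung"].is_inf and recs["lung"].dice == 1.0

    def test_2d_cardinality(self, rotated_slices):
        preds = [s.masks for s in rotated_slices]
        truths = [s.masks for s in rotated_slices]
        recs = evaluate(preds, truths, mode="2d")
        assert len(recs) == 3 * len(rotated_slices)

    def test_empty_truth_skipped(self, unrotated_slice):
        truth = {o: m.copy() for o, m in unrotated_slice.masks.items()}
        truth["heart"][:] = False
        recs = evaluate_case(unrotated_slice.masks, truth)
        assert {r.organ for r in recs} == {"lung", "cord"}


class TestSummaries:
    def test_quartiles_linear_interpolation(self):
        s = summarize([1, 2, 3, 4])
        assert (s.q1, s.median, s.q3) == pytest.approx((1.75, 2.5, 3.25))
        assert s.iqr == pytest.approx(1.5)

    def test_all_infinite(self):
        s = summarize([math.inf] * 4)
        assert s.n_inf == s.n == 4
        assert math.isnan(s.median)

    def test_infinities_excluded_from_quartiles(self):
        s = summarize([1.0, math.inf, 3.0])
        assert s.n_inf == 1
        assert s.median == pytest.approx(2.0)

    def test_n_inf_counting(self):
        recs = [MetricRecord("c", "lung", 0.5, 1, 1, v)
                for v in (0.5, math.inf, 1.2, math.inf)]
        assert n_inf(recs) == 2
        assert n_inf(recs[::-1]) == 2
        assert n_inf([]) == 0
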
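"""Loss identities for all four task settings."""

import numpy as np
import pytest

from scos.losses import (LossReport, compute_loss, loss_distance, loss_scos,
                         loss_stl, loss_tasks1, loss_tasks2, soft_dice)
from scos.model import get_setting

ORGANS = ("lung", "heart", "cord")


def _mask_batch(rng, n=2, shape=(1, 6, 6), p=0.4):
    return (rng.random((n,) + shape) < p).astype(np.float64)


class TestSoftDice:
    def test_perfect_binary_prediction(self):
        t = np.zeros((5, 5))
        t[1:4, 1:4] = 1
        assert soft_dice(t, t, smooth=0.0) == pytest.approx(1.0)

    def test_empty_prediction_tends_to_zero(self):
        t = np.ones((4, 4))
        assert soft_dice(np.zeros_like(t), t) == pytest.approx(0.0, abs=1e-6)

    def test_half_confidence_gives_two_thirds(self):
        t = np.zeros((6, 6))
        t[2:5, 2:5] = 1
        assert soft_dice(0.5 * t, t, smooth=0.0) == pytest.approx(2.0 / 3.0)


class TestSingleTaskLoss:
    def test_perfect_batch_gives_minus_one(self):
        rng = np.random.default_rng(0)
        t = _mask_batch(rng)
        rep = loss_stl(t, t)
        assert rep.total == pytest.approx(-1.0, abs=1e-6)

    def test_mean_of_known_dice_values(self):
        # sample 1: perfect (dice 1); sample 2: X covers Y plus an
        # equal-sized disjoint region twice over -> dice 0.5
        t = np.zeros((2, 1, 4, 4))
        p = np.zeros((2, 1, 4, 4))
        t[0, 0, 0, 0:2] = 1
        p[0, 0, 0, 0:2] = 1
        t[1, 0, 1, 0] = 1
        p[1, 0, 1, 0] = 1
        p[1, 0, 2, 0:2] = 1          # |X|=3, |Y|=1, overlap 1 -> 2/4 = 0.5
        rep = loss_stl(p, t, smooth=0.0)
        assert rep.total == pytest.approx(-0.75)

    def test_single_sample_reduces_to_negative_dice(self):
        rng = np.random.default_rng(1)
        t = _mask_batch(rng, n=1)
        p = np.clip(t * 0.8 + 0.05, 0, 1)
        rep = loss_stl(p, t)
        assert rep.total == pytest.approx(-soft_dice(p[0], t[0]))

    def test_empty_batch_raises(self):
        with pytest.raises(ValueError):
            loss_stl(np.empty((0, 1, 4, 4)), np.empty((0, 1, 4, 4)))


class TestJointLoss:
    def test_perfect_predictions_give_minus_three(self):
        rng = np.random.default_rng(2)
        truths = {o: _mask_batch(rng) for o in ORGANS}
        rep = loss_scos(truths, truths)
        assert rep.total == pytest.approx(-3.0, abs=1e-5)

    def test_all_zero_predictions_vanish(self):
        rng = np.random.default_rng(3)
        truths = {o: _mask_batch(rng) for o in ORGANS}
        zeros = {o: np.zeros_like(v) for o, v in truths.items()}
        rep = loss_scos(zeros, truths)
        assert rep.total == pytest.approx(0.0, abs=1e-5)

    def test_per_term_bookkeeping(self):
        rng = np.random.default_rng(4)
        truths = {o: _mask_batch(rng) for o in ORGANS}
        preds = {o: np.clip(v + rng.normal(0, 0.1, v.shape), 0, 1)
                 for o, v in truths.items()}
        rep = loss_scos(preds, truths)
        assert set(rep.per_term) == {"dice_lung", "dice_heart", "dice_cord"}
        assert rep.total == pytest.approx(-sum(rep.per_term.values()), abs=1e-9)

    def test_missing_head_raises(self):
        rng = np.random.default_rng(5)
        truths = {o: _mask_batch(rng) for o in ORGANS}
        with pytest.raises(KeyError):
            loss_scos({"lung": truths["lung"]}, truths)

    def test_gradient_wrt_one_head_ignores_other_heads(self):
        """Additivity: finite-difference gradient of the joint loss w.r.t.
        a lung pixel is identical under different heart predictions."""
        rng = np.random.default_rng(6)
        truths = {o: (rng.random((1, 1, 4, 4)) > 0.5).astype(float) for o in ORGANS}
        preds = {o: rng.random((1, 1, 4, 4)) for o in ORGANS}

        def fd(preds, idx, eps=1e-6):
            hi = {o: v.copy() for o, v in preds.items()}
            lo = {o: v.copy() for o, v in preds.items()}
            hi["lung"].reshape(-1)[idx] += eps
            lo["lung"].reshape(-1)[idx] -= eps
            return (loss_scos(hi, truths).total - loss_scos(lo, truths).total) / (2 * eps)

        other = dict(preds)
        other["heart"] = rng.random((1, 1, 4, 4))
        for idx in (0, 5, 11):
            assert fd(preds, idx) == pytest.approx(fd(other, idx), rel=1e-6)


class TestDistanceLoss:
    def test_perfect_is_zero(self):
        g = np.random.default_rng(7).random((5, 5))
        assert loss_distance(g, g) == 0.0

    def test_single_squared_difference(self):
        g = np.array([[1.0, 0.0], [0.0, 0.0]])
        assert loss_distance(np.zeros((2, 2)), g) == pytest.approx(1.0)

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(8)
        g, p = rng.random((4, 4)), rng.random((4, 4))
        assert loss_distance(3 * p, 3 * g) == pytest.approx(9 * loss_distance(p, g))


class TestCombinedSettings:
    def _perfect(self, rng, setting_name):
        setting = get_setting(setting_name)
        targets = {}
        for h, _, _, loss in setting.heads:
            if loss == "sse_distance":
                targets[h] = rng.random((2, 1, 6, 6))
            else:
                targets[h] = _mask_batch(rng)
        return targets

    def test_perfect_totals(self):
        rng = np.random.default_rng(9)
        t1 = self._perfect(rng, "TASKS1")
        assert loss_tasks1(t1, t1).total == pytest.approx(-3.0, abs=1e-5)
        t2 = self._perfect(rng, "TASKS2")
        assert loss_tasks2(t2, t2).total == pytest.approx(-6.0, abs=1e-5)

    def test_distance_head_only_changes_distance_term(self):
        rng = np.random.default_rng(10)
        t = self._perfect(rng, "TASKS1")
        preds = {k: v.copy() for k, v in t.items()}
        base = loss_tasks1(preds, t)
        preds["distance"] = np.zeros_like(preds["distance"])
        perturbed = loss_tasks1(preds, t)
        for k in base.per_term:
            if k != "distance":
                assert perturbed.per_term[k] == pytest.approx(base.per_term[k])
        assert perturbed.per_term["distance"] > base.per_term["distance"]

    def test_per_term_keys(self):
        rng = np.random.default_rng(11)
        t2 = self._perfect(rng, "TASKS2")
        rep = loss_tasks2(t2, t2)
        assert set(rep.per_term) == {"dice_lung", "dice_heart", "dice_cord",
                                     "distance", "contour_lung", "contour_heart",
                                     "contour_cord"}

    def test_head_mismatch_raises(self):
        rng = np.random.default_rng(12)
        t1 = self._perfect(rng, "TASKS1")
        del t1["distance"]
        with pytest.raises(KeyError):
            loss_tasks1(t1, t1)

    def test_dice_losses_bounded(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            truths = {o: _mask_batch(rng) for o in ORGANS}
            preds = {o: rng.random(v.shape) for o, v in truths.items()}
            rep = loss_scos(preds, truths)
            assert -3.0 - 1e-9 <= rep.total <= 0.0 + 1e-9


def test_report_total_consistency():
    rng = np.random.default_rng(14)
    truths = {o: _mask_batch(rng) for o in ORGANS}
    truths["distance"] = rng.random((2, 1, 6, 6))
    preds = {k: np.clip(v + rng.normal(0, 0.2, v.shape), 0, 1)
             for k, v in truths.items()}
    rep = compute_loss("TASKS1", preds, truths)
    expected = -sum(v for k, v in rep.per_term.items() if k.startswith("dice")) \
        + rep.per_term["distance"]
    assert rep.total == pytest.approx(expected, abs=1e-6)
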
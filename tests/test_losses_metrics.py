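"""Unit and property tests for the compound loss and region metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from maunet.losses_metrics import (LBL_ED, LBL_ET, LBL_NCR, ConfusionCounts,
                                   LossWeights, bce_loss, combined_loss,
                                   confusion, decode_regions, dice_loss,
                                   encode_regions, metrics, metrics_table,
                                   region_metrics)


class TestEncodeRegions:
    def test_background_volume_gives_empty_masks(self):
        masks = encode_regions(np.zeros((2, 2, 2), dtype=int))
        assert masks.wt.sum() == masks.tc.sum() == masks.et.sum() == 0

    def test_single_et_voxel_sets_all_regions(self):
        labels = np.zeros((2, 2, 2), dtype=int)
        labels[0, 0, 0] = LBL_ET
        masks = encode_regions(labels)
        assert masks.wt[0, 0, 0] and masks.tc[0, 0, 0] and masks.et[0, 0, 0]
        assert masks.wt.sum() == 1

    def test_one_voxel_per_compartment_counts(self):
        labels = np.zeros((2, 2, 2), dtype=int)
        labels.flat[0], labels.flat[1], labels.flat[2] = LBL_NCR, LBL_ED, LBL_ET
        masks = encode_regions(labels)
        assert (masks.wt.sum(), masks.tc.sum(), masks.et.sum()) == (3, 2, 1)
        assert masks.check_nesting()

    def test_unknown_label_raises_with_value(self):
        with pytest.raises(ValueError, match="3"):
            encode_regions(np.full((2, 2), 3))

    @given(st.lists(st.sampled_from([0, LBL_NCR, LBL_ED, LBL_ET]),
                    min_size=8, max_size=8))
    @settings(derandomize=True, max_examples=50)
    def test_roundtrip_and_nesting_for_any_label_volume(self, flat):
        labels = np.array(flat).reshape(2, 2, 2)
        masks = encode_regions(labels)
        assert masks.check_nesting()
        np.testing.assert_array_equal(decode_regions(masks.stack()), labels)


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self):
        t = np.zeros((2, 2, 2))
        t[0] = 1
        assert dice_loss(t, t).item() == pytest.approx(0.0, abs=1e-5)

    def test_disjoint_masks_score_one(self):
        a = np.array([1.0, 1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, 1.0])
        assert dice_loss(a, b).item() == pytest.approx(1.0, abs=1e-5)

    def test_half_overlap_scores_half(self):
        # |A| = |B| = 4, overlap 2 -> Dice 0.5 -> loss 0.5
        a = np.array([1, 1, 1, 1, 0, 0], dtype=float)
        b = np.array([1, 1, 0, 0, 1, 1], dtype=float)
        assert dice_loss(a, b).item() == pytest.approx(0.5, abs=1e-5)


class TestCombinedLoss:
    def test_equals_weighted_sum_of_parts(self, rng):
        pred = rng.random((3, 2, 2, 2))
        target = (rng.random((3, 2, 2, 2)) > 0.5).astype(float)
        w = LossWeights(alpha=1.0, beta=0.5)
        total = combined_loss(pred, target, w).item()
        bce = bce_loss(pred, target).item()
        dice = np.mean([dice_loss(pred[i], target[i]).item() for i in range(3)])
        assert total == pytest.approx(1.0 * bce + 0.5 * dice, abs=1e-7)

    def test_matches_scalar_loop_oracle(self, rng):
        pred = rng.random((3, 2, 2, 2))
        target = (rng.random((3, 2, 2, 2)) > 0.5).astype(float)
        got = combined_loss(pred, target).item()
        want = oracles.combined_loss(pred, target)
        assert got == pytest.approx(want, abs=1e-7)

    def test_perfect_prediction_approaches_zero(self):
        target = np.zeros((3, 2, 2, 2))
        target[:, 0] = 1.0
        assert combined_loss(target, target).item() < 1e-5

    def test_invariant_under_joint_voxel_permutation(self, rng):
        pred = rng.random((3, 2, 2, 2))
        target = (rng.random((3, 2, 2, 2)) > 0.5).astype(float)
        perm = rng.permutation(8)
        pred_p = pred.reshape(3, -1)[:, perm].reshape(pred.shape)
        target_p = target.reshape(3, -1)[:, perm].reshape(target.shape)
        assert combined_loss(pred, target).item() == pytest.approx(
            combined_loss(pred_p, target_p).item(), abs=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-1.0)


class TestConfusion:
    def test_identical_masks_have_no_errors(self):
        m = np.array([[1, 0], [1, 1]])
        c = confusion(m, m)
        assert c.fp == c.fn == 0 and c.tp == 3 and c.tn == 1

    def test_all_ones_vs_half(self):
        pred = np.ones(8, dtype=int)
        target = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        c = confusion(pred, target)
        assert (c.tp, c.fp, c.tn, c.fn) == (4, 4, 0, 0)

    def test_matches_voxel_loop_oracle(self, rng):
        pred = (rng.random((4, 4, 4)) > 0.5).astype(int)
        target = (rng.random((4, 4, 4)) > 0.5).astype(int)
        c = confusion(pred, target)
        tp = tn = fp = fn = 0
        for p, t in zip(pred.ravel(), target.ravel()):
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
        assert c.total == 64

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion(np.array([0, 2]), np.array([0, 1]))


class TestMetrics:
    def test_formula_arithmetic(self):
        m = metrics(ConfusionCounts(tp=2, fp=1, fn=1, tn=4))
        assert m["dice"] == pytest.approx(4 / 6)
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(4 / 5)

    def test_empty_masks_score_one_by_convention(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=0))
        assert all(v == 1.0 for v in m.values())

    def test_printed_specificity_variant(self):
        c = ConfusionCounts(tp=2, fp=1, fn=1, tn=4)
        assert metrics(c, printed_specificity=True)["specificity"] == pytest.approx(4 / 3)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(derandomize=True, max_examples=100)
    def test_matches_independent_formula_evaluation(self, tp, tn, fp, fn):
        m = metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        both_empty = tp + fp + fn == 0
        for key, num, den in (("dice", 2 * tp, 2 * tp + fp + fn),
                              ("sensitivity", tp, tp + fn),
                              ("precision", tp, tp + fp)):
            want = num / den if den else (1.0 if both_empty else 0.0)
            assert m[key] == pytest.approx(want)
        want_spec = tn / (tn + fp) if tn + fp else (1.0 if tn == 0 else 0.0)
        assert m["specificity"] == pytest.approx(want_spec)
        assert 0.0 <= m["dice"] <= 1.0
        assert (m["dice"] == 1.0) == (fp == 0 and fn == 0 and (tp > 0 or both_empty))

    def test_self_comparison_is_perfect(self, rng):
        m = (rng.random((3, 3, 3)) > 0.4).astype(int)
        r = metrics(confusion(m, m))
        assert r["dice"] == r["sensitivity"] == r["precision"] == 1.0


def test_region_metrics_and_table_export(rng):
    labels = np.zeros((4, 4, 4), dtype=int)
    labels[1, 1, 1] = LBL_ET
    labels[1, 1, 2] = LBL_NCR
    labels[1, 2, 2] = LBL_ED
    target = encode_regions(labels)
    per_case = {"case_000": region_metrics(target.stack(), target)}
    table = metrics_table(per_case)
    assert list(table.columns) == ["case_id", "region", "dice", "sensitivity",
                                   "specificity", "precision"]
    assert len(table) == 3
    assert (table["dice"] == 1.0).all()
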
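"""DSC, V-score, recall, and binarization against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from angioseg.metrics import (binarize, case_accuracy, dsc, evaluate_masks,
                              recall, v_score)
from angioseg.phantom import make_toy_tube, vessel_weight_map


def _set_oracle(mask):
    """Brute-force set of voxel coordinate tuples."""
    return {tuple(ix) for ix in np.argwhere(np.asarray(mask, dtype=bool))}


def oracle_dsc(pred, truth):
    p, t = _set_oracle(pred), _set_oracle(truth)
    if not p and not t:
        return 1.0
    return 2 * len(p & t) / (len(p) + len(t))


def oracle_recall(pred, truth):
    p, t = _set_oracle(pred), _set_oracle(truth)
    return len(p & t) / len(t)


def oracle_v_score(pred, truth, weights):
    p, t = _set_oracle(pred), _set_oracle(truth)
    num = sum(weights[ix] for ix in (p & t))
    den = sum(weights[ix] for ix in t)
    return num / den


class TestDsc:
    def test_identity_is_one(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        assert dsc(m, m) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert dsc(a, b) == 0.0

    def test_partial_overlap_count_oracle(self):
        truth = np.zeros((4, 4, 4), bool)
        truth[0, 0, :4] = True
        truth[1, 0, :4] = True  # 8 voxels
        pred = np.zeros_like(truth)
        pred[0, 0, :4] = True   # 4 of them, no false positives
        assert dsc(pred, truth) == pytest.approx(2 * 4 / (8 + 4))

    def test_empty_empty_convention(self):
        e = np.zeros((3, 3, 3), bool)
        assert dsc(e, e) == 1.0
        assert dsc(e, e, empty_value=0.0) == 0.0

    def test_symmetry_and_shape_check(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((5, 5, 5)) > 0.5, rng.random((5, 5, 5)) > 0.5
        assert dsc(a, b) == dsc(b, a)
        with pytest.raises(ValueError):
            dsc(a, b[:4])


class TestRecall:
    def test_superset_prediction_is_one(self):
        truth = np.zeros((4, 4, 4), bool)
        truth[1, 1, 1] = True
        assert recall(np.ones((4, 4, 4), bool), truth) == 1.0

    def test_count_oracle(self):
        truth = np.zeros((10, 1, 1), bool)
        truth[:10] = True
        pred = np.zeros_like(truth)
        pred[:7] = True
        assert recall(pred, truth) == pytest.approx(0.7)

    def test_empty_pred_is_zero(self):
        truth = np.zeros((3, 3, 3), bool)
        truth[0, 0, 0] = True
        assert recall(np.zeros_like(truth), truth) == 0.0

    def test_empty_truth_raises(self):
        with pytest.raises(ValueError):
            recall(np.ones((3, 3, 3), bool), np.zeros((3, 3, 3), bool))

    def test_monotone_under_added_true_positives(self):
        rng = np.random.default_rng(1)
        truth = rng.random((6, 6, 6)) > 0.5
        pred = truth & (rng.random((6, 6, 6)) > 0.5)
        r0 = recall(pred, truth)
        missing = np.argwhere(truth & ~pred)
        pred2 = pred.copy()
        pred2[tuple(missing[0])] = True
        assert recall(pred2, truth) >= r0


class TestVScore:
    def test_identity_is_one(self):
        truth = np.zeros((4, 4, 4), bool)
        truth[1, 1, :3] = True
        w = truth.astype(float) * 2.0
        assert v_score(truth, truth, w) == 1.0

    def test_empty_pred_is_zero(self):
        truth = np.zeros((4, 4, 4), bool)
        truth[1, 1, :3] = True
        assert v_score(np.zeros_like(truth), truth, truth.astype(float)) == 0.0

    def test_hand_weighted_case(self):
        # truth weights {3,3,1,1}; prediction misses one weight-3 voxel
        truth = np.zeros((1, 1, 4), bool)
        truth[0, 0, :] = True
        w = np.zeros((1, 1, 4))
        w[0, 0] = [3, 3, 1, 1]
        pred = truth.copy()
        pred[0, 0, 0] = False
        assert v_score(pred, truth, w) == pytest.approx((3 + 1 + 1) / 8)

    def test_uniform_weights_reduce_to_recall(self):
        rng = np.random.default_rng(2)
        truth = rng.random((6, 6, 6)) > 0.6
        pred = rng.random((6, 6, 6)) > 0.5
        w = truth.astype(float)
        assert v_score(pred, truth, w) == pytest.approx(recall(pred, truth))

    def test_negate_flag(self):
        truth = np.zeros((2, 2, 2), bool)
        truth[0, 0, 0] = True
        assert v_score(truth, truth, truth.astype(float), negate=True) == -1.0

    def test_zero_weight_on_truth_raises(self):
        truth = np.zeros((3, 3, 3), bool)
        truth[0, 0, 0] = True
        with pytest.raises(ValueError):
            v_score(truth, truth, np.zeros((3, 3, 3)))

    def test_proximal_gap_scores_below_distal_gap(self):
        """A missing proximal segment hurts continuity more than a distal one."""
        lab, branch = make_toy_tube(length=24, radius=1.5)
        truth = lab.data > 0
        w = vessel_weight_map(lab, [branch], root_point=branch.points[0], decay=0.3)
        zs = np.nonzero(truth.any(axis=(1, 2)))[0]
        proximal = truth.copy()
        proximal[zs[2]:zs[2] + 3] = False  # gap near the root
        distal = truth.copy()
        distal[zs[-5]:zs[-5] + 3] = False  # equal-thickness gap near the tip
        assert v_score(proximal, truth, w) < v_score(distal, truth, w)


class TestBinarize:
    def test_threshold_zero_keeps_everything(self):
        p = np.random.default_rng(3).random((4, 4, 4))
        assert binarize(p, 0.0).all()

    def test_threshold_above_max_empties(self):
        p = np.full((4, 4, 4), 0.4)
        assert not binarize(p, 0.401).any()

    def test_matches_per_voxel_loop(self):
        p = np.random.default_rng(4).random((4, 4, 4))
        mask = binarize(p, 0.5)
        for ix in np.ndindex(p.shape):
            assert mask[ix] == (p[ix] >= 0.5)

    def test_monotone_in_threshold(self):
        p = np.random.default_rng(5).random((5, 5, 5))
        low, high = binarize(p, 0.3), binarize(p, 0.7)
        assert not (high & ~low).any()

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2, 2)), 1.5)


class TestPropertyOracles:
    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), edge=st.integers(2, 8))
    def test_metrics_match_set_arithmetic_oracles(self, seed, edge):
        rng = np.random.default_rng(seed)
        pred = rng.random((edge,) * 3) > 0.5
        truth = rng.random((edge,) * 3) > 0.5
        assert dsc(pred, truth) == pytest.approx(oracle_dsc(pred, truth), abs=1e-12)
        if truth.any():
            assert recall(pred, truth) == pytest.approx(
                oracle_recall(pred, truth), abs=1e-12)
            w = rng.random((edge,) * 3) * truth
            if w[truth].sum() > 0:
                assert v_score(pred, truth, w) == pytest.approx(
                    oracle_v_score(pred, truth, w), abs=1e-12)


class TestAggregation:
    def test_case_accuracy_counts_passing_cases(self):
        cases = [{"dsc": 0.95}, {"dsc": 0.7}, {"dsc": 0.85}, {"dsc": 0.99}]
        assert case_accuracy(cases, dsc_threshold=0.8) == pytest.approx(0.75)

    def test_evaluate_masks_bundles_metrics(self):
        truth = np.zeros((4, 4, 4), bool)
        truth[1, 1, :3] = True
        report = evaluate_masks(truth, truth, truth.astype(float))
        assert report == {"dsc": 1.0, "recall": 1.0, "v_score": 1.0}
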
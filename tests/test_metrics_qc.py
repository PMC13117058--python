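import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment

from paintseg.io_plate import FeatureTable
from paintseg.metrics_qc import (
    MatchResult,
    compare_feature_tables,
    detection_metrics,
    match_instances,
    metrics_from_counts,
    pairwise_iou,
    prioritize_features,
)


def random_label_mask(rng, shape=(48, 48), max_objects=8):
    """Random internally-disjoint label mask via nearest-point partition."""
    k = rng.integers(1, max_objects + 1)
    pts = rng.uniform(0, shape[0], size=(k, 2))
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    d = (yy[..., None] - pts[:, 0]) ** 2 + (xx[..., None] - pts[:, 1]) ** 2
    labels = np.argmin(d, axis=-1) + 1
    keep = rng.random(k) > 0.3
    for lab in range(1, k + 1):
        if not keep[lab - 1]:
            labels[labels == lab] = 0
    return labels


def optimal_match_counts(gt, pred, threshold):
    """Exhaustive maximum-cardinality matching oracle (Hungarian on the
    feasibility matrix)."""
    ious = pairwise_iou(gt, pred)
    gts = sorted({g for g, _ in ious})
    preds = sorted({p for _, p in ious})
    n_gt = np.unique(gt[gt > 0]).size
    n_pred = np.unique(pred[pred > 0]).size
    if not gts or not preds:
        return 0, n_pred, n_gt
    cost = np.zeros((len(gts), len(preds)))
    for (g, p), v in ious.items():
        if v >= threshold:
            cost[gts.index(g), preds.index(p)] = -1.0
    rows, cols = linear_sum_assignment(cost)
    tp = int(-cost[rows, cols].sum())
    return tp, n_pred - tp, n_gt - tp


class TestMatchInstances:
    def test_identical_masks_match_perfectly(self, small_scene):
        match = match_instances(small_scene.cells, small_scene.cells)
        assert match.fp == match.fn == 0
        assert all(iou == 1.0 for _, _, iou in match.pairs)

    def test_low_overlap_pair_unmatched_at_half(self):
        gt = np.zeros((4, 4), dtype=np.int32)
        pred = np.zeros((4, 4), dtype=np.int32)
        gt[0, 0:2] = 1
        pred[0, 1:3] = 1  # 1 px shared, union 3 -> IoU 1/3
        assert pairwise_iou(gt, pred)[(1, 1)] == pytest.approx(1 / 3)
        match = match_instances(gt, pred, 0.5)
        assert (match.tp, match.fp, match.fn) == (0, 1, 1)

    def test_shifted_objects_against_brute_force(self):
        rng = np.random.default_rng(1)
        gt = np.zeros((40, 120), dtype=np.int32)
        for i in range(5):
            gt[8:18, 4 + 24 * i : 14 + 24 * i] = i + 1
        shifts = [1, 2, 2, 6, 7]  # IoU 10x10 squares shifted by s columns
        pred = np.zeros_like(gt)
        for i, s in enumerate(shifts):
            pred[8:18, 4 + 24 * i + s : 14 + 24 * i + s] = i + 1
        match = match_instances(gt, pred, 0.5)
        expected_tp = sum(1 for s in shifts if (10 - s) / (10 + s) >= 0.5)
        assert match.tp == expected_tp == 3
        assert match.fp == match.fn == 2

    @pytest.mark.parametrize("trial", range(5))
    def test_greedy_equals_optimal_on_random_masks(self, trial):
        rng = np.random.default_rng(100 + trial)
        gt = random_label_mask(rng)
        pred = random_label_mask(rng)
        match = match_instances(gt, pred, 0.5)
        tp, fp, fn = optimal_match_counts(gt, pred, 0.5)
        assert (match.tp, match.fp, match.fn) == (tp, fp, fn)

    def test_one_to_one_invariant_enforced(self):
        with pytest.raises(ValueError):
            MatchResult(pairs=[(1, 1, 0.9), (1, 2, 0.8)], fp=0, fn=0, iou_threshold=0.5)


class TestDetectionMetrics:
    def test_printed_nucleus_counts_reproduce_ap(self):
        """TP/FN recovered from the published nucleus precision (98.27%),
        recall (93.69%) and false-positive count (961) give AP 0.92."""
        fp = 961
        precision, recall = 0.9827, 0.9369
        tp = round(fp * precision / (1 - precision))
        fn = round(tp * (1 - recall) / recall)
        assert (tp, fn) == (54588, 3676)
        m = metrics_from_counts(tp, fp, fn)
        assert round(m.ap, 2) == 0.92
        assert round(m.precision, 4) == pytest.approx(0.9827, abs=5e-4)
        assert round(m.recall, 4) == pytest.approx(0.9369, abs=5e-4)

    def test_perfect_single_object(self):
        m = metrics_from_counts(1, 0, 0)
        assert (m.precision, m.recall, m.f1, m.ap) == (1, 1, 1, 1)

    def test_balanced_triple(self):
        m = metrics_from_counts(1, 1, 1)
        assert (m.precision, m.recall, m.f1) == (0.5, 0.5, 0.5)
        assert m.ap == pytest.approx(1 / 3)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_counts(0, 0, 0)

    @settings(max_examples=200, deadline=None)
    @given(
        tp=st.integers(0, 1000), fp=st.integers(0, 1000), fn=st.integers(0, 1000)
    )
    def test_ap_bounded_by_precision_recall_and_f1(self, tp, fp, fn):
        if tp + fp + fn == 0:
            return
        m = metrics_from_counts(tp, fp, fn)
        assert m.ap <= min(m.precision, m.recall) + 1e-12
        assert m.f1 >= m.ap - 1e-12
        for v in (m.precision, m.recall, m.f1, m.ap):
            assert 0 <= v <= 1


def _table(values: np.ndarray, columns, compartment="cell"):
    n = len(values)
    frame = pd.DataFrame(values, columns=columns)
    frame.insert(0, "plate", "P")
    frame.insert(1, "well", "A01")
    frame.insert(2, "site", 5)
    frame.insert(3, "compartment", compartment)
    frame.insert(4, "object_id", np.arange(1, n + 1))
    return FeatureTable(frame)


class TestCompareFeatureTables:
    def test_identical_tables_all_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(6, 4))
        cols = ["AreaShape_Area", "AreaShape_Extent", "Intensity_MeanIntensity_DNA", "Neighbors_NumberOfNeighbors"]
        report = compare_feature_tables(_table(vals, cols), _table(vals.copy(), cols))
        assert (report.groups["mse"] == 0).all()
        assert (report.groups["mae"] == 0).all()

    def test_hand_worked_normalized_errors(self):
        cols = ["Intensity_MeanIntensity_DNA"]
        measured = _table(np.array([[0.0], [0.5]]), cols)
        reference = _table(np.array([[0.0], [1.0]]), cols)
        report = compare_feature_tables(measured, reference)
        mse, mae = report.overall()
        assert mae == pytest.approx(0.25)
        assert mse == pytest.approx(0.125)

    def test_disjoint_object_keys_rejected(self):
        cols = ["AreaShape_Area"]
        a = _table(np.ones((2, 1)), cols)
        b = _table(np.ones((2, 1)), cols, compartment="nucleus")
        with pytest.raises(ValueError, match="keys"):
            compare_feature_tables(a, b)

    def test_column_mismatch_reported_by_name(self):
        a = _table(np.ones((2, 1)), ["AreaShape_Area"])
        b = _table(np.ones((2, 1)), ["AreaShape_Extent"])
        with pytest.raises(ValueError, match="AreaShape_"):
            compare_feature_tables(a, b)

    def test_mae_squared_bounded_by_mse(self):
        rng = np.random.default_rng(5)
        cols = [f"Intensity_F{i}_DNA" for i in range(6)]
        a = _table(rng.normal(size=(20, 6)), cols)
        b = _table(rng.normal(size=(20, 6)), cols)
        report = compare_feature_tables(a, b)
        for _, row in report.groups.iterrows():
            assert row["mae"] ** 2 <= row["mse"] + 1e-12

    def test_zero_range_reference_feature_convention(self):
        cols = ["AreaShape_EulerNumber"]
        measured = _table(np.array([[1.0], [2.0]]), cols)
        reference = _table(np.array([[1.0], [1.0]]), cols)
        mse, mae = compare_feature_tables(measured, reference).overall()
        assert mae == pytest.approx(0.5)  # one equal (0), one different (1)


class TestPrioritizeFeatures:
    def test_duplicate_column_keeps_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 1))
        table = _table(np.hstack([x, x]), ["Intensity_A_DNA", "Intensity_B_DNA"])
        assert len(prioritize_features(table, 0.9)) == 1

    def test_orthogonal_columns_all_kept(self):
        x = np.array([[1.0, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]])
        table = _table(x, ["F_a", "F_b", "F_c"])
        assert len(prioritize_features(table, 0.9)) == 3

    def test_five_correlated_blocks_keep_five(self):
        rng = np.random.default_rng(7)
        n, per_block = 60, 4
        cols, data = [], []
        for b in range(5):
            base = rng.normal(size=n)
            for j in range(per_block):
                data.append(base + rng.normal(scale=0.05, size=n))
                cols.append(f"F_block{b}_{j}")
        x = np.array(data).T
        corr = np.corrcoef(x, rowvar=False)
        for b in range(5):  # confirm the planted structure
            block = corr[b * per_block : (b + 1) * per_block, b * per_block : (b + 1) * per_block]
            assert np.abs(block).min() > 0.95
        assert len(prioritize_features(_table(x, cols), 0.9)) == 5

    def test_zero_variance_always_dropped(self):
        x = np.hstack([np.ones((10, 1)), np.random.default_rng(0).normal(size=(10, 1))])
        table = _table(x, ["F_const", "F_var"])
        assert prioritize_features(table, 0.9) == ["F_var"]

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(30, 6))
        cols = [f"F_{i}" for i in range(6)]
        t1 = _table(x, cols)
        perm = rng.permutation(30)
        t2 = _table(x[perm], cols)
        assert prioritize_features(t1, 0.8) == prioritize_features(t2, 0.8)

    def test_too_few_objects_rejected(self):
        with pytest.raises(ValueError):
            prioritize_features(_table(np.ones((1, 2)), ["F_a", "F_b"]), 0.9)
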
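"""Detection metrics, feature quality control, and feature prioritization.

Object-level segmentation quality is scored by matching predicted to
ground-truth instances at an IoU threshold (default 0.5, inclusive) and
summarizing the TP / FP / FN counts as precision P = TP/(TP+FP), recall
R = TP/(TP+FN), F1 = 2PR/(P+R) and the Jaccard-style average precision
AP = TP/(TP+FP+FN) — an object-level detection score, *not* the
ranked-precision AP of the object-detection literature.

Feature quality control compares a measured feature table against a
reference (e.g. CellProfiler output) via normalized MSE and MAE pooled per
feature group; prioritization removes redundant features by greedy
correlation filtering in descending variance order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from paintseg.io_plate import KEY_COLUMNS, FeatureTable
from paintseg.features import FeatureCatalog

DEFAULT_IOU_THRESHOLD = 0.5
DEFAULT_CORR_THRESHOLD = 0.9


@dataclass
class MatchResult:
    """One-to-one instance matching between ground truth and prediction."""

    pairs: list[tuple[int, int, float]]
    fp: int
    fn: int
    iou_threshold: float

    def __post_init__(self) -> None:
        gts = [g for g, _, _ in self.pairs]
        preds = [p for _, p, _ in self.pairs]
        if len(set(gts)) != len(gts) or len(set(preds)) != len(preds):
            raise ValueError("matching is not one-to-one")
        for _, _, iou in self.pairs:
            if iou < self.iou_threshold:
                raise ValueError("matched pair below the IoU threshold")

    @property
    def tp(self) -> int:
        return len(self.pairs)


@dataclass
class DetectionMetrics:
    precision: float
    recall: float
    f1: float
    ap: float
    mean_matched_iou: float

    def to_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "ap": self.ap,
            "mean_matched_iou": self.mean_matched_iou,
        }


def pairwise_iou(gt: np.ndarray, pred: np.ndarray) -> dict[tuple[int, int], float]:
    """IoU of every (gt, pred) label pair with nonzero pixel overlap."""
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"mask shapes differ: {gt.shape} vs {pred.shape}")
    gt_areas = {int(k): int(v) for k, v in zip(*np.unique(gt[gt > 0], return_counts=True))}
    pred_areas = {int(k): int(v) for k, v in zip(*np.unique(pred[pred > 0], return_counts=True))}
    both = (gt > 0) & (pred > 0)
    pairs, counts = np.unique(
        np.stack([gt[both], pred[both]]), axis=1, return_counts=True
    )
    out = {}
    for (g, p), inter in zip(pairs.T, counts):
        g, p, inter = int(g), int(p), int(inter)
        union = gt_areas[g] + pred_areas[p] - inter
        out[(g, p)] = inter / union
    return out


def match_instances(
    gt: np.ndarray, pred: np.ndarray, iou_threshold: float = DEFAULT_IOU_THRESHOLD
) -> MatchResult:
    """Greedy one-to-one matching of predicted to ground-truth instances.

    Candidate pairs (all label pairs with nonzero overlap) are accepted in
    descending IoU order (ties: lower gt label, then lower pred label) when
    their IoU meets the threshold.  At thresholds >= 0.5 a prediction can
    overlap at most one ground-truth object that well, so greedy matching
    coincides with optimal matching.  Unmatched predictions are false
    positives, unmatched ground-truth objects false negatives.
    """
    if not 0 < iou_threshold <= 1:
        raise ValueError(f"iou_threshold must be in (0, 1], got {iou_threshold}")
    ious = pairwise_iou(gt, pred)
    candidates = sorted(
        ((g, p, v) for (g, p), v in ious.items() if v >= iou_threshold),
        key=lambda t: (-t[2], t[0], t[1]),
    )
    used_gt: set[int] = set()
    used_pred: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for g, p, v in candidates:
        if g in used_gt or p in used_pred:
            continue
        pairs.append((g, p, v))
        used_gt.add(g)
        used_pred.add(p)
    n_gt = np.unique(np.asarray(gt)[np.asarray(gt) > 0]).size
    n_pred = np.unique(np.asarray(pred)[np.asarray(pred) > 0]).size
    return MatchResult(
        pairs=pairs,
        fp=n_pred - len(pairs),
        fn=n_gt - len(pairs),
        iou_threshold=iou_threshold,
    )


def detection_metrics(match: MatchResult) -> DetectionMetrics:
    """Summarize TP/FP/FN counts into P, R, F1 and Jaccard-style AP."""
    tp, fp, fn = match.tp, match.fp, match.fn
    if tp + fp + fn == 0:
        raise ValueError("no objects in ground truth or prediction")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    ap = tp / (tp + fp + fn)
    mean_iou = float(np.mean([iou for _, _, iou in match.pairs])) if match.pairs else 0.0
    return DetectionMetrics(precision, recall, f1, ap, mean_iou)


def metrics_from_counts(tp: int, fp: int, fn: int) -> DetectionMetrics:
    """Detection metrics directly from a count triple (no pair IoUs)."""
    pairs = [(i + 1, i + 1, 1.0) for i in range(tp)]
    return detection_metrics(MatchResult(pairs=pairs, fp=fp, fn=fn, iou_threshold=1.0))


def pixelwise_foreground_iou(gt: np.ndarray, pred: np.ndarray) -> float:
    """Foreground IoU ignoring instance identity (semantic overlap)."""
    gt_fg = np.asarray(gt) > 0
    pred_fg = np.asarray(pred) > 0
    union = int((gt_fg | pred_fg).sum())
    if union == 0:
        return 1.0
    return int((gt_fg & pred_fg).sum()) / union


def evaluation_report(
    gt: np.ndarray, pred: np.ndarray, iou_threshold: float = DEFAULT_IOU_THRESHOLD
) -> dict:
    """Full JSON-ready metrics report for one mask pair.

    Both the mean matched-pair IoU and the pixelwise foreground IoU are
    reported, since summary 'IoU' figures in the literature may refer to
    either.
    """
    match = match_instances(gt, pred, iou_threshold)
    m = detection_metrics(match)
    return {
        "counts": {"tp": match.tp, "fp": match.fp, "fn": match.fn},
        "iou_threshold": iou_threshold,
        **m.to_dict(),
        "pixelwise_foreground_iou": pixelwise_foreground_iou(gt, pred),
    }


def write_metrics_json(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# feature quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-group normalized MSE / MAE between measured and reference tables."""

    groups: pd.DataFrame  # columns: group, n_features, mse, mae (+ overall row)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.groups.to_csv(path, index=False)
        return path

    def overall(self) -> tuple[float, float]:
        row = self.groups[self.groups["group"] == "Overall"].iloc[0]
        return float(row["mse"]), float(row["mae"])


def _normalize_pair(
    measured: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Min-max normalize both columns with the reference column's bounds.

    A zero-range reference feature contributes residual 0 where the
    measured value equals the reference and 1 where it differs.
    """
    lo, hi = float(np.min(reference)), float(np.max(reference))
    if hi > lo:
        return (measured - lo) / (hi - lo), (reference - lo) / (hi - lo)
    same = measured == reference
    return np.where(same, 0.0, 1.0), np.zeros_like(reference, dtype=float)


def compare_feature_tables(
    measured: FeatureTable,
    reference: FeatureTable,
    grouping=FeatureCatalog.group_of,
) -> QCReport:
    """Quality-control a measured feature table against a reference.

    Objects are aligned by (plate, well, site, compartment, object_id);
    every feature column is min-max normalized to [0, 1] using the
    reference column's bounds, then squared / absolute residuals are pooled
    over all objects x features within each feature group.  ``grouping``
    maps a column name to its group (default: prefix before '_').
    """
    meas = measured.keyed().sort_index()
    ref = reference.keyed().sort_index()
    only_meas = meas.index.difference(ref.index)
    only_ref = ref.index.difference(meas.index)
    if len(only_meas) or len(only_ref):
        raise ValueError(
            "object keys differ between tables; "
            f"only in measured: {list(only_meas[:5])}, only in reference: {list(only_ref[:5])}"
        )
    cols_meas = set(measured.feature_columns)
    cols_ref = set(reference.feature_columns)
    if cols_meas != cols_ref:
        raise ValueError(
            f"feature columns differ: only measured {sorted(cols_meas - cols_ref)[:5]}, "
            f"only reference {sorted(cols_ref - cols_meas)[:5]}"
        )
    residuals: dict[str, list[np.ndarray]] = {}
    for col in measured.feature_columns:
        m_norm, r_norm = _normalize_pair(
            meas[col].to_numpy(dtype=float), ref[col].to_numpy(dtype=float)
        )
        residuals.setdefault(grouping(col), []).append(m_norm - r_norm)
    rows = []
    all_res: list[np.ndarray] = []
    n_feats_per_group: dict[str, int] = {}
    for col in measured.feature_columns:
        g = grouping(col)
        n_feats_per_group[g] = n_feats_per_group.get(g, 0) + 1
    for group in sorted(residuals):
        res = np.concatenate(residuals[group])
        all_res.append(res)
        rows.append(
            {
                "group": group,
                "n_features": n_feats_per_group[group],
                "mse": float(np.mean(res**2)),
                "mae": float(np.mean(np.abs(res))),
            }
        )
    pooled = np.concatenate(all_res)
    rows.append(
        {
            "group": "Overall",
            "n_features": len(measured.feature_columns),
            "mse": float(np.mean(pooled**2)),
            "mae": float(np.mean(np.abs(pooled))),
        }
    )
    return QCReport(pd.DataFrame(rows, columns=["group", "n_features", "mse", "mae"]))


def prioritize_features(
    table: FeatureTable, corr_threshold: float = DEFAULT_CORR_THRESHOLD
) -> list[str]:
    """Correlation-based redundancy reduction over a feature table.

    Features are scanned in descending variance order (ties broken by
    catalog/column order); a feature is retained iff its absolute Pearson
    correlation with every already-retained feature stays below the
    threshold.  Zero-variance features are always dropped.  Returns the
    retained feature identifiers in scan order; the result is invariant to
    the ordering of object rows.
    """
    if not 0 < corr_threshold <= 1:
        raise ValueError(f"corr_threshold must be in (0, 1], got {corr_threshold}")
    if table.n_objects < 2:
        raise ValueError("prioritization requires at least 2 objects")
    cols = table.feature_columns
    x = table.values()
    var = x.var(axis=0)
    # stable sort keeps catalog order among equal variances
    order = np.argsort(-var, kind="stable")
    retained: list[int] = []
    centered = x - x.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    for idx in order:
        if var[idx] <= 0:
            continue
        ok = True
        for kept in retained:
            r = float(centered[:, idx] @ centered[:, kept]) / (norms[idx] * norms[kept])
            if abs(r) >= corr_threshold:
                ok = False
                break
        if ok:
            retained.append(int(idx))
    return [cols[i] for i in retained]
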
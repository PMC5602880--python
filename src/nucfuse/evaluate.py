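"""Segmentation and classification scoring, and report-table assembly.

Pixel scores use the set formulas TP = |G ∩ S|, FP = |S| − TP,
FN = |G| − TP with precision TP/(TP+FP) and sensitivity TP/(TP+FN).
Object-level outcomes are sorted into correctly / over / under-segmented
with an automated IoU-based proxy for the published manual criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from decimal import ROUND_HALF_UP, Decimal

from .classify import mca_from_class_accuracies


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, matching how printed tables round .5 cases."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SegScore:
    TP: int
    FP: int
    FN: int
    defined: bool = True

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if (self.TP + self.FP) else float("nan")

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else float("nan")


def seg_score(truth: np.ndarray, pred: np.ndarray) -> SegScore:
    """Pixel-level precision/sensitivity of a predicted mask."""
    truth = np.asarray(truth) > 0
    pred = np.asarray(pred) > 0
    if truth.shape != pred.shape:
        raise ValueError("mask shape mismatch")
    tp = int((truth & pred).sum())
    fp = int(pred.sum()) - tp
    fn = int(truth.sum()) - tp
    return SegScore(tp, fp, fn, defined=bool(truth.any() or pred.any()))


@dataclass
class SegCategoryCounts:
    correct: int
    over: int
    under: int
    unmatched: int = 0

    @property
    def total(self) -> int:
        return self.correct + self.over + self.under + self.unmatched

    @property
    def percentages(self) -> dict[str, float]:
        """Percentages of total truth objects, rounded to two decimals."""
        t = self.total
        if t == 0:
            return {"correct": float("nan"), "over": float("nan"), "under": float("nan")}
        return {
            "correct": round_half_up(100.0 * self.correct / t),
            "over": round_half_up(100.0 * self.over / t),
            "under": round_half_up(100.0 * self.under / t),
        }


def category_percentages(correct: int, over: int, under: int, total: int) -> dict[str, float]:
    """Percentages straight from printed-style counts (two decimals)."""
    return {
        "correct": round_half_up(100.0 * correct / total),
        "over": round_half_up(100.0 * over / total),
        "under": round_half_up(100.0 * under / total),
    }


def categorize_objects(
    truth: np.ndarray,
    pred: np.ndarray,
    iou_min: float = 0.5,
    claim_floor: float = 0.2,
) -> SegCategoryCounts:
    """Sort each truth nucleus into correct / over / under-segmented.

    A truth nucleus is over-segmented when two or more predicted regions
    each claim >= ``claim_floor`` of its area; under-segmented when its
    best-overlapping region also claims >= ``claim_floor`` of another
    truth nucleus; correct when exactly one region claims it with IoU >=
    ``iou_min``; otherwise unmatched.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("label map shape mismatch")
    t_ids = [int(v) for v in np.unique(truth) if v != 0]
    p_ids = [int(v) for v in np.unique(pred) if v != 0]
    # overlap contingency
    t_index = {v: i for i, v in enumerate(t_ids)}
    p_index = {v: i for i, v in enumerate(p_ids)}
    overlap = np.zeros((len(t_ids), len(p_ids)), dtype=np.int64)
    both = (truth > 0) & (pred > 0)
    for tv, pv in zip(truth[both].ravel(), pred[both].ravel()):
        overlap[t_index[int(tv)], p_index[int(pv)]] += 1
    t_area = np.array([(truth == v).sum() for v in t_ids], dtype=np.int64)
    p_area = np.array([(pred == v).sum() for v in p_ids], dtype=np.int64)

    correct = over = under = unmatched = 0
    for i, tv in enumerate(t_ids):
        claims = np.flatnonzero(overlap[i] >= claim_floor * t_area[i])
        if len(claims) >= 2:
            over += 1
            continue
        if len(p_ids) == 0 or overlap[i].max() == 0:
            unmatched += 1
            continue
        iou = overlap[i] / (t_area[i] + p_area - overlap[i])
        j = int(np.argmax(iou))
        # does the best region also claim a big chunk of another nucleus?
        other = [
            k
            for k in range(len(t_ids))
            if k != i and overlap[k, j] >= claim_floor * t_area[k]
        ]
        if other and iou[j] > 0:
            under += 1
        elif iou[j] >= iou_min:
            correct += 1
        else:
            unmatched += 1
    return SegCategoryCounts(correct, over, under, unmatched)


def object_iou(truth: np.ndarray, pred: np.ndarray) -> dict[int, float]:
    """Best-match IoU per truth nucleus."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    out: dict[int, float] = {}
    for tv in (int(v) for v in np.unique(truth) if v != 0):
        t_mask = truth == tv
        candidates = [int(v) for v in np.unique(pred[t_mask]) if v != 0]
        best = 0.0
        for pv in candidates:
            p_mask = pred == pv
            inter = (t_mask & p_mask).sum()
            union = (t_mask | p_mask).sum()
            best = max(best, inter / union)
        out[tv] = best
    return out


def segmentation_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-day precision/sensitivity table with an unweighted Sum row.

    ``scores`` needs columns: day, and per-group precision / sensitivity
    values (already in percent or fractions — passed through unchanged).
    Extra grouping columns (tissue, channel_mode) are preserved.
    """
    group_cols = [c for c in scores.columns if c not in ("precision", "sensitivity", "day")]
    rows = []
    for key, grp in scores.groupby(group_cols) if group_cols else [((), scores)]:
        per_day = grp.groupby("day")[["precision", "sensitivity"]].mean().reset_index()
        for _, r in per_day.iterrows():
            rows.append(
                dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
                | {"day": r["day"], "precision": r["precision"], "sensitivity": r["sensitivity"]}
            )
        rows.append(
            dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
            | {
                "day": "Sum",
                "precision": per_day["precision"].mean(),
                "sensitivity": per_day["sensitivity"].mean(),
            }
        )
    return pd.DataFrame(rows)


def sum_row(per_day_values) -> float:
    """The table's Sum row: unweighted mean over the day rows."""
    vals = np.asarray(list(per_day_values), dtype=float)
    if vals.size == 0:
        raise ValueError("no per-day values")
    return float(vals.mean())


def classification_table(per_class_accuracy: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Per-classifier class accuracies plus the MCA column."""
    rows = []
    for method, acc in per_class_accuracy.items():
        rows.append({"method": method, **acc, "MCA": mca_from_class_accuracies(acc)})
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    segmentation: pd.DataFrame | None = None
    categories: SegCategoryCounts | None = None
    classification: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out: dict = dict(self.extras)
        if self.segmentation is not None:
            out["segmentation"] = self.segmentation.to_dict(orient="records")
        if self.categories is not None:
            out["categories"] = {
                "correct": self.categories.correct,
                "over": self.categories.over,
                "under": self.categories.under,
                "unmatched": self.categories.unmatched,
                "percentages": self.categories.percentages,
            }
        if self.classification is not None:
            out["classification"] = self.classification.to_dict(orient="records")
        return out
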
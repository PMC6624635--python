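"""Object-level scoring of a segmentation against ground truth.

Predicted objects are sorted into the four categories an expert
reviewer would use: correctly segmented glands, correctly segmented
non-glandular objects, over-segmentation (more than the gland
identified as one object) and under-segmentation (only part of a gland
segmented).  The expert judgment is replaced by explicit overlap
thresholds — an IoU floor for a correct match and coverage bounds for
the over/under calls — which are numeric surrogates and deliberately
configurable.  The summary arithmetic reports per-category counts and
percentages plus the headline accuracy (share of objects neither over-
nor under-segmented) and the gland / non-gland split among the
accurate objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import InvalidInputError
from .types import GroundTruthLabels, LabelMap

__all__ = [
    "CATEGORY_GLAND_CORRECT",
    "CATEGORY_NON_GLAND_CORRECT",
    "CATEGORY_OVER",
    "CATEGORY_UNDER",
    "ObjectCategorization",
    "SummaryTable",
    "categorize_objects",
    "summarize",
    "GLAND_TAGS",
]

CATEGORY_GLAND_CORRECT = "gland_correct"
CATEGORY_NON_GLAND_CORRECT = "non_gland_correct"
CATEGORY_OVER = "over_segmented"
CATEGORY_UNDER = "under_segmented"

# architecture tags that count as glands; anything else in the truth is
# a non-glandular object (traps, bare nuclei)
GLAND_TAGS = frozenset(
    {"benign", "well_formed", "poorly_formed", "cribriform", "fused", "single_cells"}
)


@dataclass
class ObjectCategorization:
    """Per-object categories plus the prediction/truth overlap records."""

    category_per_object: dict  # predicted id -> category
    status_per_truth: dict  # truth id -> "found" | "missed"
    matching: list  # (predicted id, truth id, intersection px, iou)
    matched_truth: dict = field(default_factory=dict)  # predicted id -> best truth id (or None)

    def counts(self) -> dict:
        out = {
            CATEGORY_GLAND_CORRECT: 0,
            CATEGORY_NON_GLAND_CORRECT: 0,
            CATEGORY_OVER: 0,
            CATEGORY_UNDER: 0,
        }
        for cat in self.category_per_object.values():
            out[cat] += 1
        return out


def _overlap_table(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Pixel-intersection counts for every (pred id, truth id) pair."""
    sel = (pred > 0) & (truth > 0)
    if not np.any(sel):
        return {}
    pair = pred[sel].astype(np.int64) * (int(truth.max()) + 1) + truth[sel].astype(np.int64)
    vals, counts = np.unique(pair, return_counts=True)
    base = int(truth.max()) + 1
    return {(int(v // base), int(v % base)): int(c) for v, c in zip(vals, counts)}


def categorize_objects(
    predicted: LabelMap,
    truth: GroundTruthLabels,
    iou_match: float = 0.5,
    coverage_low: float = 0.2,
    coverage_high: float = 0.7,
) -> ObjectCategorization:
    """Assign every predicted object exactly one category.

    Decision order per predicted object: (1) over-segmentation when it
    spans two or more truth objects (each covering at least
    ``coverage_low`` of the prediction) or exceeds ``1/coverage_high``
    times its best-matching truth object's area; (2) under-segmentation
    when it covers less than ``coverage_high`` of its best truth
    object; (3) a correct gland or non-gland object when the best IoU
    reaches ``iou_match``; (4) otherwise, when the residual overlap is
    still substantial, under-segmentation, and with no meaningful truth
    overlap at all, a correctly segmented non-glandular object (the
    truth labels only gland-like structures, so stray stromal objects
    fall here).  Every truth object is marked found when a prediction
    categorized as correct matches it at ``iou_match`` IoU, else missed
    (a gland whose only match is an under-segmentation was not found).
    """
    if not (0 < coverage_low < coverage_high <= 1):
        raise InvalidInputError("need 0 < coverage_low < coverage_high <= 1")
    pred = predicted.labels
    tru = truth.instance_labels
    if pred.shape != tru.shape:
        raise InvalidInputError(f"shape mismatch: {pred.shape} vs {tru.shape}")

    pred_areas = dict(zip(*[a.tolist() for a in np.unique(pred[pred > 0], return_counts=True)]))
    truth_areas = dict(zip(*[a.tolist() for a in np.unique(tru[tru > 0], return_counts=True)]))
    inter = _overlap_table(pred, tru)

    by_pred: dict[int, list] = {pid: [] for pid in pred_areas}
    for (pid, tid), c in inter.items():
        by_pred[pid].append((tid, c))

    category: dict[int, str] = {}
    matching: list[tuple[int, int, int, float]] = []
    matched_truth: dict[int, int | None] = {}
    found: set[int] = set()

    for pid, p_area in pred_areas.items():
        overlaps = by_pred.get(pid, [])
        if not overlaps:
            category[pid] = CATEGORY_NON_GLAND_CORRECT
            matched_truth[pid] = None
            continue
        ious = {tid: c / (p_area + truth_areas[tid] - c) for tid, c in overlaps}
        best_tid, best_c = max(overlaps, key=lambda tc: ious[tc[0]])
        best_iou = ious[best_tid]
        for tid, c in overlaps:
            matching.append((pid, tid, c, ious[tid]))
        matched_truth[pid] = best_tid

        qualifying = [tid for tid, c in overlaps if c / p_area >= coverage_low]
        truth_coverage = best_c / truth_areas[best_tid]
        if len(qualifying) >= 2 or p_area > truth_areas[best_tid] / coverage_high:
            category[pid] = CATEGORY_OVER
        elif truth_coverage < coverage_high:
            category[pid] = CATEGORY_UNDER
        elif best_iou >= iou_match:
            tag = truth.architecture_per_instance.get(best_tid, "")
            category[pid] = (
                CATEGORY_GLAND_CORRECT if tag in GLAND_TAGS else CATEGORY_NON_GLAND_CORRECT
            )
        elif best_c / p_area >= coverage_low:
            category[pid] = CATEGORY_UNDER
        else:
            category[pid] = CATEGORY_NON_GLAND_CORRECT
        if category[pid] in (CATEGORY_GLAND_CORRECT, CATEGORY_NON_GLAND_CORRECT) and best_iou >= iou_match:
            found.add(best_tid)

    status = {
        int(tid): ("found" if tid in found else "missed") for tid in truth_areas
    }
    return ObjectCategorization(
        category_per_object=category,
        status_per_truth=status,
        matching=matching,
        matched_truth=matched_truth,
    )


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _round0(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class SummaryTable:
    """Per-category counts with percentages and the headline accuracy split."""

    rows: list  # (category label, count, percent)
    total: int
    accuracy: int  # percent of objects neither over- nor under-segmented
    gland_share: int  # percent of accurate objects that are glands
    non_gland_share: int

    def to_dict(self) -> dict:
        return {
            "rows": [
                {"category": c, "count": int(n), "percent": float(p)} for c, n, p in self.rows
            ],
            "total": int(self.total),
            "accuracy_percent": self.accuracy,
            "gland_share_percent": self.gland_share,
            "non_gland_share_percent": self.non_gland_share,
        }


def summarize(
    counts: dict,
    over_key: str = CATEGORY_OVER,
    under_key: str = CATEGORY_UNDER,
    non_gland_keys: tuple = (CATEGORY_NON_GLAND_CORRECT,),
) -> SummaryTable:
    """Summary-table arithmetic over raw category counts.

    ``counts`` maps category labels (either the four canonical labels
    or finer gland sub-categories such as Gleason-grade rows) to object
    counts.  Percentages are 100 * count / total to two decimals; the
    headline accuracy is the integer-rounded percent of objects neither
    over- nor under-segmented, and the gland / non-gland shares are
    computed among those accurate objects.
    """
    if not counts:
        raise InvalidInputError("no counts given")
    total = sum(int(v) for v in counts.values())
    if total <= 0:
        raise InvalidInputError("total object count must be positive")
    rows = [(k, int(v), _round2(100.0 * v / total)) for k, v in counts.items()]
    over = int(counts.get(over_key, 0))
    under = int(counts.get(under_key, 0))
    accurate = total - over - under
    non_gland = sum(int(counts.get(k, 0)) for k in non_gland_keys)
    gland = accurate - non_gland
    return SummaryTable(
        rows=rows,
        total=total,
        accuracy=_round0(100.0 * accurate / total),
        gland_share=_round0(100.0 * gland / accurate) if accurate > 0 else 0,
        non_gland_share=_round0(100.0 * non_gland / accurate) if accurate > 0 else 0,
    )


def evaluate(
    predicted: LabelMap,
    truth: GroundTruthLabels,
    iou_match: float = 0.5,
    coverage_low: float = 0.2,
    coverage_high: float = 0.7,
) -> tuple[ObjectCategorization, SummaryTable]:
    """Categorize predicted objects and summarize in one call."""
    cat = categorize_objects(predicted, truth, iou_match, coverage_low, coverage_high)
    return cat, summarize(cat.counts())
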
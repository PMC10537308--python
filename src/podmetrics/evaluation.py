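"""COCO-style instance-segmentation metrics.

Ground truth and predictions are per-image lists of binary masks
(predictions additionally carry confidence scores).  Matching follows
the COCO convention: predictions are visited in order of descending
score and each is greedily assigned to the not-yet-matched ground truth
with the highest IoU, provided that IoU reaches the threshold; ties go
to the lower ground-truth index.  Average precision uses the 101-point
interpolated precision-recall curve (recall grid 0, 0.01, ..., 1).

Size-stratified AP (APs/APm/APl, strata <32^2, 32^2-96^2, >96^2 px of
ground-truth mask area) uses COCO ignore semantics: out-of-stratum
ground truths are ignored, predictions matched to an ignored ground
truth are dropped from the ranking, and unmatched predictions whose own
area falls outside the stratum are dropped as well.  A stratum with no
ground truth reports a missing value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "EvalReport",
    "mask_iou",
    "bbox_mask",
    "match_instances",
    "precision_recall",
    "average_precision",
    "evaluate",
    "IOU_THRESHOLDS",
    "AREA_STRATA",
]

IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
AREA_STRATA = {
    "small": (0.0, 32.0**2),
    "medium": (32.0**2, 96.0**2),
    "large": (96.0**2, float("inf")),
}
_RECALL_GRID = np.linspace(0.0, 1.0, 101)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two same-shaped boolean masks (0 when
    both are empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def bbox_mask(mask: np.ndarray) -> np.ndarray:
    """Filled tight axis-aligned bounding box of a mask (for box-level
    metrics computed with the mask machinery)."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    rows, cols = np.nonzero(mask)
    if rows.size:
        out[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1] = True
    return out


def match_instances(
    preds: Sequence[tuple[np.ndarray, float]],
    gts: Sequence[np.ndarray],
    iou_threshold: float,
) -> list[int | None]:
    """Greedy one-to-one matching for a single image.

    Returns, for each prediction in the order given, the index of the
    ground truth it matched or ``None``.  Predictions are processed by
    descending score (stable for equal scores).
    """
    if not 0 < iou_threshold <= 1:
        raise ValueError("iou_threshold must lie in (0, 1]")
    order = sorted(range(len(preds)), key=lambda i: -preds[i][1])
    matched_gt: set[int] = set()
    result: list[int | None] = [None] * len(preds)
    for i in order:
        mask = preds[i][0]
        best_j, best_iou = None, 0.0
        for j, gt in enumerate(gts):
            if j in matched_gt:
                continue
            iou = mask_iou(mask, gt)
            if iou < iou_threshold:
                continue
            if best_j is None or iou > best_iou:
                best_j, best_iou = j, iou
        if best_j is not None:
            matched_gt.add(best_j)
            result[i] = best_j
    return result


def precision_recall(
    matching: Sequence[int | None], n_gt: int
) -> tuple[float, float]:
    """Set-level precision and recall from a matching (0/0 defined as 0)."""
    tp = sum(m is not None for m in matching)
    fp = len(matching) - tp
    fn = n_gt - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


def _ranked_matches(
    preds: Mapping[object, Sequence[tuple[np.ndarray, float]]],
    gts: Mapping[object, Sequence[np.ndarray]],
    iou_threshold: float,
    stratum: tuple[float, float] | None = None,
):
    """Global score-ranked TP/FP flags and the number of ground truths.

    With a stratum, ignored detections are omitted from the ranking per
    the COCO area-range rules.
    """
    entries = []  # (score, order, is_tp)
    n_gt = 0
    order = 0
    for key in gts:
        gt_masks = list(gts[key])
        pred_list = list(preds.get(key, []))
        if stratum is None:
            gt_keep = [True] * len(gt_masks)
        else:
            lo, hi = stratum
            gt_keep = [
                lo <= float(np.count_nonzero(g)) < hi for g in gt_masks
            ]
        n_gt += sum(gt_keep)
        matching = match_instances(pred_list, gt_masks, iou_threshold)
        for i, (mask, score) in enumerate(pred_list):
            j = matching[i]
            if j is not None:
                if gt_keep[j]:
                    entries.append((score, order, True))
                # matched an ignored gt: dropped from the ranking
            else:
                if stratum is not None:
                    lo, hi = stratum
                    if not lo <= float(np.count_nonzero(mask)) < hi:
                        order += 1
                        continue  # unmatched out-of-stratum: ignored
                entries.append((score, order, False))
            order += 1
    entries.sort(key=lambda e: (-e[0], e[1]))
    flags = np.array([e[2] for e in entries], dtype=bool)
    return flags, n_gt


def _ap_from_flags(flags: np.ndarray, n_gt: int) -> float | None:
    if n_gt == 0:
        return None
    if flags.size == 0:
        return 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # precision envelope: max precision at any recall >= r
    ap = 0.0
    for r in _RECALL_GRID:
        mask = recall >= r - 1e-12
        ap += float(precision[mask].max()) if mask.any() else 0.0
    return ap / len(_RECALL_GRID)


def average_precision(
    preds: Mapping[object, Sequence[tuple[np.ndarray, float]]],
    gts: Mapping[object, Sequence[np.ndarray]],
    iou_threshold: float,
    stratum: tuple[float, float] | None = None,
) -> float | None:
    """101-point interpolated AP over a dataset at one IoU threshold.

    Returns ``None`` when no ground truth exists (in the stratum).
    """
    flags, n_gt = _ranked_matches(preds, gts, iou_threshold, stratum)
    return _ap_from_flags(flags, n_gt)


@dataclass(frozen=True)
class EvalReport:
    """Instance-detection quality summary (all fields in [0, 1]; strata
    without ground truth are None)."""

    precision: float
    recall: float
    ap_by_threshold: dict[float, float | None]
    map_50_95: float | None
    ap_small: float | None
    ap_medium: float | None
    ap_large: float | None
    n_images: int = 0
    n_gt: int = 0
    n_pred: int = 0

    @property
    def ap50(self) -> float | None:
        return self.ap_by_threshold.get(0.5)

    @property
    def ap75(self) -> float | None:
        return self.ap_by_threshold.get(0.75)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "ap_by_threshold": {f"{t:.2f}": v for t, v in self.ap_by_threshold.items()},
            "map_50_95": self.map_50_95,
            "ap_small": self.ap_small,
            "ap_medium": self.ap_medium,
            "ap_large": self.ap_large,
            "n_images": self.n_images,
            "n_gt": self.n_gt,
            "n_pred": self.n_pred,
        }

    def table(self) -> str:
        """Console table in the usual AP / AP50 / AP75 / APs / APm / APl
        column layout."""
        def fmt(v):
            return "Nan" if v is None else f"{100 * v:.3f}"

        headers = ["AP", "AP50", "AP75", "APs", "APm", "APl", "P", "R"]
        values = [
            fmt(self.map_50_95),
            fmt(self.ap50),
            fmt(self.ap75),
            fmt(self.ap_small),
            fmt(self.ap_medium),
            fmt(self.ap_large),
            fmt(self.precision),
            fmt(self.recall),
        ]
        w = max(len(s) for s in headers + values) + 2
        return (
            "".join(h.rjust(w) for h in headers)
            + "\n"
            + "".join(v.rjust(w) for v in values)
        )


def evaluate(
    preds: Mapping[object, Sequence[tuple[np.ndarray, float]]],
    gts: Mapping[object, Sequence[np.ndarray]],
    iou_thresholds: Sequence[float] = IOU_THRESHOLDS,
    mode: str = "mask",
) -> EvalReport:
    """Full metric suite between aligned per-image prediction and ground
    truth sets.

    ``preds`` may omit images with no detections but must not contain
    images absent from ``gts``.  ``mode='bbox'`` replaces every mask
    with its filled bounding box before evaluation.
    """
    extra = set(preds) - set(gts)
    if extra:
        raise ValueError(f"predictions reference unknown images: {sorted(map(str, extra))}")
    if mode == "bbox":
        preds = {
            k: [(bbox_mask(m), s) for m, s in v] for k, v in preds.items()
        }
        gts = {k: [bbox_mask(m) for m in v] for k, v in gts.items()}
    elif mode != "mask":
        raise ValueError(f"unknown mode {mode!r}")

    tp = fp = fn = 0
    for key in gts:
        matching = match_instances(list(preds.get(key, [])), list(gts[key]), 0.5)
        t = sum(m is not None for m in matching)
        tp += t
        fp += len(matching) - t
        fn += len(gts[key]) - t
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0

    ap_by_threshold = {
        float(t): average_precision(preds, gts, float(t)) for t in iou_thresholds
    }
    aps = [v for v in ap_by_threshold.values()]
    map_50_95 = None if any(v is None for v in aps) or not aps else float(np.mean(aps))

    strata_ap = {
        name: average_precision(preds, gts, 0.5, stratum=rng)
        for name, rng in AREA_STRATA.items()
    }
    return EvalReport(
        precision=precision,
        recall=recall,
        ap_by_threshold=ap_by_threshold,
        map_50_95=map_50_95,
        ap_small=strata_ap["small"],
        ap_medium=strata_ap["medium"],
        ap_large=strata_ap["large"],
        n_images=len(gts),
        n_gt=sum(len(v) for v in gts.values()),
        n_pred=sum(len(v) for v in preds.values()),
    )
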
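"""Panoptic-quality evaluation of typed instance segmentations.

Predicted and ground-truth instances are matched by pixel IoU with the
strict threshold IoU > 0.5, which guarantees a unique one-to-one matching
(two objects cannot both overlap a third by more than half of the union),
so no assignment algorithm is needed.  From the matches:

    DQ = TP / (TP + FP/2 + FN/2)        (detection quality, an F1 score)
    SQ = mean IoU over matched pairs    (segmentation quality)
    PQ = DQ * SQ                        (panoptic quality)

Matching may be class-aware (per cell type) or class-agnostic ("all"
instances pooled without distinguishing types).  Confidence intervals are
obtained by bootstrap: the set of evaluated regions (ROIs) is resampled
with replacement n_rounds times (default 200), pooled TP/FP/FN and IoUs
are recomputed per round, and the 2.5/97.5 percentiles of the bootstrap
distribution give the bounds.

When a class has no prediction and no ground truth at all (TP=FP=FN=0)
its metrics are undefined and reported as None, never as 0; bootstrap
rounds where a class vanishes are dropped for that class with a logged
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic import CLASS_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "MatchResult",
    "PanopticResult",
    "BootstrapCI",
    "match_instances",
    "panoptic_quality",
    "bootstrap_metrics",
]


@dataclass
class ClassMatch:
    """Matching outcome for one class (or the pooled "all" pseudo-class)."""

    tp_pairs: list[tuple[int, int, float]] = field(default_factory=list)  # (pred, gt, IoU)
    fp_ids: list[int] = field(default_factory=list)
    fn_ids: list[int] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_ids)

    @property
    def fn(self) -> int:
        return len(self.fn_ids)

    @property
    def ious(self) -> list[float]:
        return [iou for _, _, iou in self.tp_pairs]


@dataclass
class MatchResult:
    """Per-class instance matching at a fixed IoU threshold."""

    per_class: dict[str, ClassMatch]
    iou_threshold: float = 0.5
    class_aware: bool = True


@dataclass
class PanopticResult:
    """DQ/SQ/PQ and counts for one class; metrics are None when undefined."""

    class_name: str
    tp: int
    fp: int
    fn: int
    dq: float | None
    sq: float | None
    pq: float | None

    @property
    def defined(self) -> bool:
        return self.dq is not None


@dataclass
class BootstrapCI:
    point: float | None
    lower: float
    upper: float
    n_rounds: int
    levels: tuple[float, float] = (2.5, 97.5)
    n_dropped: int = 0


def _pair_ious(pred: np.ndarray, gt: np.ndarray) -> dict[tuple[int, int], float]:
    """IoU of every overlapping (pred, gt) instance pair via the
    contingency table of the two label maps."""
    pred = np.asarray(pred).ravel()
    gt = np.asarray(gt).ravel()
    n_gt = int(gt.max()) + 1
    keys = pred.astype(np.int64) * n_gt + gt
    counts = np.bincount(keys)
    pred_areas = np.bincount(pred)
    gt_areas = np.bincount(gt)
    nz = np.flatnonzero(counts)
    out: dict[tuple[int, int], float] = {}
    for k in nz:
        p, g = divmod(int(k), n_gt)
        if p == 0 or g == 0:
            continue
        inter = counts[k]
        union = pred_areas[p] + gt_areas[g] - inter
        out[(p, g)] = float(inter / union)
    return out


def match_instances(
    pred: np.ndarray,
    pred_classes: dict[int, int],
    gt: np.ndarray,
    gt_classes: dict[int, int],
    iou_threshold: float = 0.5,
    class_aware: bool = True,
    class_subset: tuple[str, ...] | None = None,
) -> MatchResult:
    """Match predicted to ground-truth instances at IoU > threshold.

    A pair is a true positive iff IoU strictly exceeds ``iou_threshold``
    and, when ``class_aware``, the classes agree.  With threshold >= 0.5 the
    matching is provably unique.  ``class_subset`` restricts scoring to the
    named classes: instances of other classes are removed from both sides
    before matching (so e.g. dead and epithelial cells can be excluded from
    an analysis where they are too rare to score).

    Raises on canvas shape mismatch.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"canvas mismatch: pred {pred.shape} vs gt {gt.shape}")
    if iou_threshold < 0.5:
        raise ValueError("iou_threshold below 0.5 loses the unique-matching guarantee")

    if class_subset is not None:
        allowed = {CLASS_NAMES.index(c) + 1 for c in class_subset}
        pred = _drop_classes(pred, pred_classes, allowed)
        gt = _drop_classes(gt, gt_classes, allowed)
        pred_classes = {k: v for k, v in pred_classes.items() if v in allowed}
        gt_classes = {k: v for k, v in gt_classes.items() if v in allowed}

    ious = _pair_ious(pred, gt)
    pred_ids = sorted(pred_classes.keys() & set(np.unique(pred[pred > 0]).tolist()))
    gt_ids = sorted(gt_classes.keys() & set(np.unique(gt[gt > 0]).tolist()))

    keys: tuple[str, ...]
    if class_aware:
        keys = class_subset if class_subset is not None else CLASS_NAMES
    else:
        keys = ("all",)
    result = {k: ClassMatch() for k in keys}

    matched_pred: set[int] = set()
    matched_gt: set[int] = set()
    for (p, g), iou in sorted(ious.items()):
        if iou <= iou_threshold:
            continue
        if class_aware and pred_classes[p] != gt_classes[g]:
            continue
        # uniqueness guarantee: no instance can appear in two >0.5 pairs
        assert p not in matched_pred and g not in matched_gt
        key = CLASS_NAMES[gt_classes[g] - 1] if class_aware else "all"
        result[key].tp_pairs.append((p, g, iou))
        matched_pred.add(p)
        matched_gt.add(g)
    for p in pred_ids:
        if p not in matched_pred:
            key = CLASS_NAMES[pred_classes[p] - 1] if class_aware else "all"
            if key in result:
                result[key].fp_ids.append(p)
    for g in gt_ids:
        if g not in matched_gt:
            key = CLASS_NAMES[gt_classes[g] - 1] if class_aware else "all"
            if key in result:
                result[key].fn_ids.append(g)
    return MatchResult(per_class=result, iou_threshold=iou_threshold, class_aware=class_aware)


def _drop_classes(labels: np.ndarray, classes: dict[int, int], allowed: set[int]) -> np.ndarray:
    lut = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    for lab, ci in classes.items():
        if ci in allowed and lab < lut.size:
            lut[lab] = lab
    return lut[labels]


def _metrics(tp: int, fp: int, fn: int, ious) -> tuple[float | None, float | None, float | None]:
    if tp == 0 and fp == 0 and fn == 0:
        return None, None, None
    dq = tp / (tp + 0.5 * fp + 0.5 * fn)
    sq = float(np.mean(ious)) if tp > 0 else 0.0
    return dq, sq, dq * sq


def panoptic_quality(match: MatchResult) -> dict[str, PanopticResult]:
    """DQ/SQ/PQ per class of a MatchResult (see module docstring)."""
    out: dict[str, PanopticResult] = {}
    for cname, cm in match.per_class.items():
        dq, sq, pq = _metrics(cm.tp, cm.fp, cm.fn, cm.ious)
        out[cname] = PanopticResult(
            class_name=cname, tp=cm.tp, fp=cm.fp, fn=cm.fn, dq=dq, sq=sq, pq=pq
        )
    return out


def bootstrap_metrics(
    rois: list[MatchResult],
    n_rounds: int = 200,
    seed: int = 0,
    levels: tuple[float, float] = (2.5, 97.5),
) -> dict[str, dict[str, BootstrapCI]]:
    """Percentile bootstrap CIs of pooled DQ/SQ/PQ over a set of ROIs.

    ROIs are resampled with replacement; each round pools TP/FP/FN counts
    and TP IoUs over the resampled ROIs and recomputes the metrics.  Rounds
    where a class has no instances at all are dropped for that class.
    Deterministic under a fixed seed.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if len(rois) < 2:
        raise ValueError("need at least 2 ROIs to bootstrap")
    keys = list(rois[0].per_class.keys())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(rois), size=(n_rounds, len(rois)))

    def pooled(selection) -> dict[str, tuple[float | None, float | None, float | None]]:
        res = {}
        for k in keys:
            tp = fp = fn = 0
            ious: list[float] = []
            for m in selection:
                cm = m.per_class[k]
                tp += cm.tp
                fp += cm.fp
                fn += cm.fn
                ious.extend(cm.ious)
            res[k] = _metrics(tp, fp, fn, ious)
        return res

    point = pooled(rois)
    samples: dict[str, dict[str, list[float]]] = {
        k: {"dq": [], "sq": [], "pq": []} for k in keys
    }
    dropped = {k: 0 for k in keys}
    for row in idx:
        res = pooled([rois[i] for i in row])
        for k in keys:
            dq, sq, pq = res[k]
            if dq is None:
                dropped[k] += 1
                continue
            samples[k]["dq"].append(dq)
            samples[k]["sq"].append(sq)
            samples[k]["pq"].append(pq)

    out: dict[str, dict[str, BootstrapCI]] = {}
    for ki, k in enumerate(keys):
        if dropped[k]:
            logger.info("bootstrap: class %s undefined in %d/%d rounds", k, dropped[k], n_rounds)
        out[k] = {}
        for mi, metric in enumerate(("dq", "sq", "pq")):
            vals = samples[k][metric]
            pt = point[k][mi]
            if not vals:
                out[k][metric] = BootstrapCI(pt, np.nan, np.nan, n_rounds, levels, dropped[k])
                continue
            lo, hi = np.percentile(vals, levels)
            out[k][metric] = BootstrapCI(pt, float(lo), float(hi), n_rounds, levels, dropped[k])
    return out
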
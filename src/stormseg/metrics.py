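"""Instance-segmentation evaluation: IoU matching, F1, FN%/FP%, Hausdorff.

Matching follows the one-to-one convention standard in nucleus
segmentation benchmarking: each ground-truth instance is paired with its
maximum-IoU prediction when that IoU reaches the threshold (default
0.7).  For thresholds above 0.5 the pairing is automatically one-to-one,
since two predictions cannot each share more than half their union with
the same ground-truth mask.

The false-negative and false-positive percentages are both expressed as
fractions of the *ground-truth* instance count.  The Hausdorff distance
is reported as the mean over matched pairs, in pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .instances import InstanceSet

log = logging.getLogger(__name__)

__all__ = [
    "MetricsConfig",
    "MatchResult",
    "MetricsReport",
    "iou",
    "iou_matrix",
    "match_instances",
    "f1_fn_fp",
    "hausdorff",
    "evaluate",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class MetricsConfig:
    iou_threshold: float = 0.7
    aggregate: str = "per_image_mean"  # or "pooled"
    hausdorff_mode: str = "full"  # or "boundary"

    def __post_init__(self) -> None:
        if not (0 < self.iou_threshold <= 1):
            raise ValueError("iou_threshold must be in (0, 1]")
        if self.aggregate not in ("per_image_mean", "pooled"):
            raise ValueError(f"unknown aggregate {self.aggregate!r}")
        if self.hausdorff_mode not in ("full", "boundary"):
            raise ValueError(f"unknown hausdorff_mode {self.hausdorff_mode!r}")


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]  # (gt_id, pred_id, iou)
    unmatched_gt: list[int]
    unmatched_pred: list[int]


@dataclass
class MetricsReport:
    f1: float
    fn_percent: float
    fp_percent: float
    mean_hausdorff: float  # nan when no pair matched
    n_tp: int
    n_fn: int
    n_fp: int
    match: MatchResult | None = field(default=None, repr=False)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two boolean masks of equal shape."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    if union == 0:
        log.warning("iou of two empty masks, defined as 0")
        return 0.0
    return float(inter) / float(union)


def iou_matrix(gt: InstanceSet, pred: InstanceSet) -> np.ndarray:
    """Full |gt| x |pred| IoU matrix, computed via label-map contingency.

    Requires disjoint masks within each set.
    """
    for name, s in (("gt", gt), ("pred", pred)):
        if not s.is_disjoint():
            raise ValueError(f"{name} masks overlap; run resolve_overlaps first")
    if gt.shape != pred.shape:
        raise ValueError("gt and pred shapes differ")
    n_g, n_p = len(gt), len(pred)
    mat = np.zeros((n_g, n_p), dtype=np.float64)
    if n_g == 0 or n_p == 0:
        return mat
    glab = np.zeros(gt.shape, dtype=np.int64)
    plab = np.zeros(pred.shape, dtype=np.int64)
    g_areas = np.empty(n_g)
    p_areas = np.empty(n_p)
    for k, inst in enumerate(gt):
        glab[inst.mask] = k + 1
        g_areas[k] = inst.area
    for k, inst in enumerate(pred):
        plab[inst.mask] = k + 1
        p_areas[k] = inst.area
    both = (glab > 0) & (plab > 0)
    pair_codes = glab[both] * (n_p + 1) + plab[both]
    codes, counts = np.unique(pair_codes, return_counts=True)
    gi = codes // (n_p + 1) - 1
    pj = codes % (n_p + 1) - 1
    inter = counts.astype(np.float64)
    mat[gi, pj] = inter / (g_areas[gi] + p_areas[pj] - inter)
    return mat


def match_instances(
    gt: InstanceSet, pred: InstanceSet, cfg: MetricsConfig | None = None
) -> MatchResult:
    """One-to-one IoU matching at the configured threshold.

    Each ground-truth mask is paired with its maximum-IoU prediction if
    that IoU reaches the threshold.  For thresholds at or below 0.5
    (outside the usual regime) candidate pairs are taken greedily in
    descending IoU to keep the matching one-to-one.
    """
    cfg = cfg or MetricsConfig()
    mat = iou_matrix(gt, pred)
    gt_ids = gt.ids()
    pred_ids = pred.ids()
    pairs: list[tuple[int, int, float]] = []
    used_g: set[int] = set()
    used_p: set[int] = set()
    if mat.size:
        cand = np.argwhere(mat >= cfg.iou_threshold)
        order = np.argsort(-mat[cand[:, 0], cand[:, 1]], kind="stable")
        for gi, pj in cand[order]:
            if gi in used_g or pj in used_p:
                continue
            used_g.add(int(gi))
            used_p.add(int(pj))
            pairs.append((gt_ids[gi], pred_ids[pj], float(mat[gi, pj])))
    pairs.sort(key=lambda t: t[0])
    return MatchResult(
        pairs=pairs,
        unmatched_gt=[g for k, g in enumerate(gt_ids) if k not in used_g],
        unmatched_pred=[p for k, p in enumerate(pred_ids) if k not in used_p],
    )


def f1_fn_fp(match: MatchResult, n_gt: int, n_pred: int) -> tuple[float, float, float]:
    """F1 and the FN/FP fractions (both with the GT count as denominator)."""
    tp = len(match.pairs)
    fn = n_gt - tp
    fp = n_pred - tp
    if n_gt == 0 and n_pred == 0:
        return 1.0, 0.0, 0.0
    if n_gt == 0:
        log.warning("no ground-truth instances: fp_percent undefined, reported inf")
        return 0.0, 0.0, float("inf")
    f1 = 2.0 * tp / (2.0 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return f1, fn / n_gt, fp / n_gt


def _boundary(mask: np.ndarray) -> np.ndarray:
    import scipy.ndimage as ndi

    eroded = ndi.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    return mask & ~eroded


def hausdorff(a: np.ndarray, b: np.ndarray, mode: str = "full") -> float:
    """Symmetric Hausdorff distance between two non-empty masks, in pixels.

    ``mode='full'`` uses every foreground pixel coordinate;
    ``mode='boundary'`` uses only boundary pixels (8-connected erosion
    residue).  For solid masks the two coincide on the outer contour.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if not a.any() or not b.any():
        raise ValueError("hausdorff requires non-empty masks")
    if mode == "boundary":
        a, b = _boundary(a), _boundary(b)
    pa = np.argwhere(a).astype(np.float64)
    pb = np.argwhere(b).astype(np.float64)
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


def evaluate(
    gt: InstanceSet, pred: InstanceSet, cfg: MetricsConfig | None = None
) -> MetricsReport:
    """Match, score and report one image.

    ``mean_hausdorff`` averages the Hausdorff distance over matched pairs
    only and is NaN when nothing matched.
    """
    cfg = cfg or MetricsConfig()
    match = match_instances(gt, pred, cfg)
    f1, fn_pct, fp_pct = f1_fn_fp(match, len(gt), len(pred))
    if match.pairs:
        dists = [
            hausdorff(gt.get(g).mask, pred.get(p).mask, cfg.hausdorff_mode)
            for g, p, _ in match.pairs
        ]
        mean_h = float(np.mean(dists))
    else:
        mean_h = float("nan")
    tp = len(match.pairs)
    return MetricsReport(
        f1=f1,
        fn_percent=fn_pct,
        fp_percent=fp_pct,
        mean_hausdorff=mean_h,
        n_tp=tp,
        n_fn=len(gt) - tp,
        n_fp=len(pred) - tp,
        match=match,
    )


def evaluate_dataset(
    reports: list[MetricsReport], cfg: MetricsConfig | None = None
) -> MetricsReport:
    """Aggregate per-image reports over a test set.

    ``per_image_mean`` (default) averages each score across images;
    ``pooled`` recomputes scores from the summed TP/FN/FP counts.
    Mean Hausdorff averages over images that had at least one match.
    """
    cfg = cfg or MetricsConfig()
    if not reports:
        raise ValueError("no reports to aggregate")
    tp = sum(r.n_tp for r in reports)
    fn = sum(r.n_fn for r in reports)
    fp = sum(r.n_fp for r in reports)
    h_vals = [r.mean_hausdorff for r in reports if np.isfinite(r.mean_hausdorff)]
    mean_h = float(np.mean(h_vals)) if h_vals else float("nan")
    if cfg.aggregate == "pooled":
        n_gt = tp + fn
        f1 = 2.0 * tp / (2.0 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 1.0
        fn_pct = fn / n_gt if n_gt else 0.0
        fp_pct = fp / n_gt if n_gt else (float("inf") if fp else 0.0)
    else:
        f1 = float(np.mean([r.f1 for r in reports]))
        fn_pct = float(np.mean([r.fn_percent for r in reports]))
        fp_pct = float(np.mean([r.fp_percent for r in reports]))
    return MetricsReport(
        f1=f1, fn_percent=fn_pct, fp_percent=fp_pct, mean_hausdorff=mean_h,
        n_tp=tp, n_fn=fn, n_fp=fp,
    )
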
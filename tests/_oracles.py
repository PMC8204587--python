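"""Independent reference implementations used only to check stormseg.

Everything here is deliberately written as direct, brute-force code —
python loops, exhaustive search, cdist — with no reuse of the package's
own computation paths.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def overlap_rule(a: np.ndarray, b: np.ndarray,
                 merge_frac: float = 0.5, assign_frac: float = 0.1) -> str:
    """Direct transcription of the four-way overlap rule."""
    area_a = int(a.sum())
    area_b = int(b.sum())
    o = int((a & b).sum())
    assert o > 0
    union = area_a + area_b - o
    f_a = o / area_a
    f_b = o / area_b
    f_u = o / union
    if f_u > merge_frac:
        return "merge"
    if f_a > merge_frac or f_b > merge_frac:
        return "merge"
    if f_a <= assign_frac and f_b <= assign_frac:
        return "random_assign"
    if f_a <= assign_frac:  # A barely participates, B loses more -> B keeps it
        return "assign_to_B"
    if f_b <= assign_frac:
        return "assign_to_A"
    return "split"


def otsu_brute_force(hist) -> int:
    """Exhaustive search of the between-class variance over all 256 splits."""
    hist = [float(h) for h in hist]
    total = sum(hist)
    best_t, best_v = None, -1.0
    for t in range(256):
        w0 = sum(hist[: t + 1]) / total
        w1 = 1.0 - w0
        if w0 == 0.0 or w1 == 0.0:
            v = 0.0
        else:
            mu0 = sum(i * hist[i] for i in range(t + 1)) / (w0 * total)
            mu1 = sum(i * hist[i] for i in range(t + 1, 256)) / (w1 * total)
            v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t, best_v


def hausdorff_brute_force(pts_a: np.ndarray, pts_b: np.ndarray) -> float:
    """O(nm) double loop via the full distance matrix."""
    d = cdist(pts_a, pts_b)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def iou_pair(a: np.ndarray, b: np.ndarray) -> float:
    inter = int((a & b).sum())
    union = int((a | b).sum())
    return inter / union if union else 0.0


def match_brute_force(gt_masks: dict, pred_masks: dict, threshold: float):
    """Max-IoU-per-GT matching computed from a dense per-pair IoU table.

    Returns (pairs, unmatched_gt, unmatched_pred); asserts the pairing is
    one-to-one, which holds automatically for thresholds above 0.5.
    """
    pairs = []
    used_pred = []
    for g_id, g_mask in gt_masks.items():
        best_p, best_iou = None, 0.0
        for p_id, p_mask in pred_masks.items():
            v = iou_pair(g_mask, p_mask)
            if v > best_iou:
                best_p, best_iou = p_id, v
        if best_p is not None and best_iou >= threshold:
            assert best_p not in used_pred, "matching not one-to-one"
            used_pred.append(best_p)
            pairs.append((g_id, best_p, best_iou))
    unmatched_gt = [g for g in gt_masks if g not in [p[0] for p in pairs]]
    unmatched_pred = [p for p in pred_masks if p not in used_pred]
    return pairs, unmatched_gt, unmatched_pred


def block_mean(img: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Area-average downsizing by explicit python loops."""
    h, w = img.shape
    out = np.zeros((h // kh, w // kw))
    for i in range(h // kh):
        for j in range(w // kw):
            out[i, j] = img[i * kh : (i + 1) * kh, j * kw : (j + 1) * kw].mean()
    return out


def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1, dtype=float)
    k = np.exp(-(x**2) / (2 * sigma**2))
    return k / k.sum()


def random_masks_on_grid(rng: np.random.Generator, size: int = 6,
                         max_area: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """A random pair of small overlapping masks on a size x size grid."""
    while True:
        a = np.zeros((size, size), dtype=bool)
        b = np.zeros((size, size), dtype=bool)
        na = rng.integers(1, max_area + 1)
        nb = rng.integers(1, max_area + 1)
        idx_a = rng.choice(size * size, size=na, replace=False)
        idx_b = rng.choice(size * size, size=nb, replace=False)
        a.flat[idx_a] = True
        b.flat[idx_b] = True
        if (a & b).any():
            return a, b


def random_instance_scene(rng: np.random.Generator, shape=(64, 64),
                          n_max: int = 6, r_max: int = 9, overlap: bool = True):
    """Random disks as (id, mask) pairs; disjoint unless overlap=True."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    masks = {}
    taken = np.zeros(shape, dtype=bool)
    n = rng.integers(1, n_max + 1)
    next_id = 1
    for _ in range(n):
        for _ in range(50):
            cy, cx = rng.uniform(r_max, h - r_max), rng.uniform(r_max, w - r_max)
            r = rng.uniform(3, r_max)
            m = np.hypot(yy - cy, xx - cx) <= r
            if overlap:
                masks[next_id] = m
                next_id += 1
                break
            if not (m & taken).any():
                masks[next_id] = m
                taken |= m
                next_id += 1
                break
    return masks
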
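"""Instance post-processing: small-instance removal and overlap resolution.

Region-proposal segmenters emit per-object masks that may overlap.  This
module implements the four-way overlap rule used on super-resolution
nuclei segmentations:

* two masks sharing more than half of their combined area (or where more
  than half of either mask lies in the overlap) are **merged**;
* when both masks contribute at most 10 % of their pixels to the overlap,
  the contested region is **randomly assigned** to one of them;
* when exactly one mask contributes at most 10 %, the region is
  **assigned** to the mask with the greater overlap fraction;
* otherwise the region is **split** along the perpendicular bisector of
  the segment joining the two mask centroids.

Small instances (area below a fraction of the image-average instance
area) are removed before resolution and again afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Instance",
    "InstanceSet",
    "PostprocessConfig",
    "OverlapDecision",
    "remove_small",
    "classify_overlap",
    "split_overlap",
    "resolve_overlaps",
    "postprocess",
    "to_label_map",
    "from_label_map",
]


@dataclass
class Instance:
    """One object: positive integer id, boolean mask, optional confidence."""

    id: int
    mask: np.ndarray
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValueError(f"instance id must be positive, got {self.id}")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class InstanceSet:
    """Ordered collection of possibly-overlapping instances on one image frame."""

    shape: tuple[int, int]
    instances: list[Instance] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        ids = [inst.id for inst in self.instances]
        if len(ids) != len(set(ids)):
            raise ValueError("instance ids must be unique")
        for inst in self.instances:
            if inst.mask.shape != self.shape:
                raise ValueError(
                    f"mask shape {inst.mask.shape} != set shape {self.shape}"
                )
            if inst.area == 0:
                raise ValueError(f"instance {inst.id} has an empty mask")

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)

    def ids(self) -> list[int]:
        return [inst.id for inst in self.instances]

    def get(self, id_: int) -> Instance:
        for inst in self.instances:
            if inst.id == id_:
                return inst
        raise KeyError(id_)

    def is_disjoint(self) -> bool:
        cover = np.zeros(self.shape, dtype=np.int32)
        for inst in self.instances:
            cover += inst.mask
        return bool((cover <= 1).all())

    def coverage(self) -> np.ndarray:
        """Boolean union of all masks."""
        cover = np.zeros(self.shape, dtype=bool)
        for inst in self.instances:
            cover |= inst.mask
        return cover

    def copy(self) -> "InstanceSet":
        return InstanceSet(
            self.shape,
            [Instance(i.id, i.mask.copy(), i.confidence) for i in self.instances],
        )


@dataclass(frozen=True)
class PostprocessConfig:
    small_area_fraction: float = 0.25
    merge_fraction: float = 0.5
    assign_fraction: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.assign_fraction < self.merge_fraction <= 1):
            raise ValueError("need 0 < assign_fraction < merge_fraction <= 1")
        if not (0 < self.small_area_fraction < 1):
            raise ValueError("need 0 < small_area_fraction < 1")


class OverlapDecision(Enum):
    MERGE = "merge"
    ASSIGN_TO_A = "assign_to_A"
    ASSIGN_TO_B = "assign_to_B"
    RANDOM_ASSIGN = "random_assign"
    SPLIT = "split"


def remove_small(iset: InstanceSet, fraction: float = 0.25) -> InstanceSet:
    """Drop instances with area below ``fraction`` of the image-average area.

    The mean area is computed once over the whole set before any removal,
    so the threshold does not drift as instances drop out.  Survivor ids
    are unchanged.
    """
    if len(iset) == 0:
        return iset.copy()
    mean_area = float(np.mean([inst.area for inst in iset]))
    threshold = fraction * mean_area
    kept = [
        Instance(i.id, i.mask.copy(), i.confidence)
        for i in iset
        if i.area >= threshold
    ]
    if len(kept) < len(iset):
        log.info(
            "remove_small: dropped %d of %d instances (area < %.1f px)",
            len(iset) - len(kept), len(iset), threshold,
        )
    return InstanceSet(iset.shape, kept)


def _overlap_fractions(a: np.ndarray, b: np.ndarray) -> tuple[int, float, float, float]:
    inter = int(np.logical_and(a, b).sum())
    area_a = int(a.sum())
    area_b = int(b.sum())
    union = area_a + area_b - inter
    return inter, inter / area_a, inter / area_b, inter / union


def classify_overlap(
    a: np.ndarray, b: np.ndarray, cfg: PostprocessConfig | None = None
) -> OverlapDecision:
    """Apply the four-way overlap rule to two intersecting masks.

    With overlap O and fractions fA = O/|A|, fB = O/|B|, fU = O/|A u B|,
    evaluated in order:

    1. fU > merge_fraction or fA > merge_fraction or fB > merge_fraction
       -> merge;
    2. fA <= assign_fraction and fB <= assign_fraction -> random assign;
    3. exactly one of fA, fB <= assign_fraction -> assign the overlap to
       the mask with the greater overlap fraction;
    4. otherwise -> split along the centroid perpendicular bisector.
    """
    cfg = cfg or PostprocessConfig()
    inter, fa, fb, fu = _overlap_fractions(a, b)
    if inter == 0:
        raise ValueError("classify_overlap requires intersecting masks")
    if fu > cfg.merge_fraction or fa > cfg.merge_fraction or fb > cfg.merge_fraction:
        return OverlapDecision.MERGE
    if fa <= cfg.assign_fraction and fb <= cfg.assign_fraction:
        return OverlapDecision.RANDOM_ASSIGN
    if fa <= cfg.assign_fraction or fb <= cfg.assign_fraction:
        # the overlap goes to the instance losing the larger fraction of
        # its pixels to the overlap
        return OverlapDecision.ASSIGN_TO_A if fa > fb else OverlapDecision.ASSIGN_TO_B
    return OverlapDecision.SPLIT


def _centroid(mask: np.ndarray) -> np.ndarray:
    coords = np.argwhere(mask)
    return coords.mean(axis=0)


def split_overlap(
    a: np.ndarray, b: np.ndarray, a_id: int = 1, b_id: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Split the overlap of two masks along the centroid perpendicular bisector.

    Centroids cA, cB are computed on the *full* masks (overlap pixels
    counted in both).  Each overlap pixel p goes to A when
    ``(p - M) . (cA - cB) > 0`` with M the midpoint of cA and cB, to B
    when negative; exact ties go to the instance with the smaller id.
    Non-overlap pixels keep their owner, so A' u B' = A u B and
    A' n B' is empty.

    Coincident centroids define no bisector; the caller should escalate
    to a merge (a ``ValueError`` is raised here).
    """
    overlap = np.logical_and(a, b)
    if not overlap.any():
        raise ValueError("split_overlap requires intersecting masks")
    ca = _centroid(a)
    cb = _centroid(b)
    axis = ca - cb
    if np.allclose(axis, 0):
        raise ValueError("coincident centroids: no bisector definable")
    mid = (ca + cb) / 2.0

    pts = np.argwhere(overlap)
    side = (pts - mid) @ axis
    to_a = side > 0
    to_b = side < 0
    tie = ~(to_a | to_b)
    if tie.any():
        if a_id < b_id:
            to_a |= tie
        else:
            to_b |= tie

    a_new = a.copy()
    b_new = b.copy()
    a_new[tuple(pts[to_b].T)] = False
    b_new[tuple(pts[to_a].T)] = False
    return a_new, b_new


def _largest_overlap_pair(iset: InstanceSet) -> tuple[int, int, int] | None:
    """Return (area, index_i, index_j) of the pair with the largest overlap.

    Ties break toward the pair with the smaller ids.  Bounding boxes
    prefilter the quadratic scan.  ``None`` when the set is disjoint.
    """
    insts = iset.instances
    boxes = []
    for inst in insts:
        rows = np.flatnonzero(inst.mask.any(axis=1))
        cols = np.flatnonzero(inst.mask.any(axis=0))
        boxes.append((rows[0], rows[-1], cols[0], cols[-1]))
    best: tuple[int, int, int] | None = None
    order = sorted(range(len(insts)), key=lambda k: insts[k].id)
    for oi in range(len(order)):
        for oj in range(oi + 1, len(order)):
            i, j = order[oi], order[oj]
            bi, bj = boxes[i], boxes[j]
            if bi[1] < bj[0] or bj[1] < bi[0] or bi[3] < bj[2] or bj[3] < bi[2]:
                continue
            inter = int(np.logical_and(insts[i].mask, insts[j].mask).sum())
            if inter > 0 and (best is None or inter > best[0]):
                best = (inter, i, j)
    return best


def resolve_overlaps(iset: InstanceSet, cfg: PostprocessConfig | None = None) -> InstanceSet:
    """Iteratively resolve all pairwise overlaps, then re-remove small instances.

    Pairs are processed largest-overlap-first (ties toward the smaller id
    pair); after each action overlaps are recomputed.  Merging unions the
    two masks under the smaller id; assignment moves the whole contested
    region to one owner; splitting applies :func:`split_overlap`.  Random
    assignment draws one Bernoulli(0.5) per contested region from a
    generator seeded with ``cfg.rng_seed``, so output is a deterministic
    function of input and config.  Each action strictly reduces the total
    count of multiply-owned pixels, so the loop terminates.  Afterwards
    :func:`remove_small` runs once more with the recomputed mean area.
    """
    cfg = cfg or PostprocessConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    out = iset.copy()

    while True:
        hit = _largest_overlap_pair(out)
        if hit is None:
            break
        _, i, j = hit
        inst_a, inst_b = out.instances[i], out.instances[j]
        # orient so A carries the smaller id (merge target, tie owner)
        if inst_b.id < inst_a.id:
            inst_a, inst_b = inst_b, inst_a
        decision = classify_overlap(inst_a.mask, inst_b.mask, cfg)
        if decision is OverlapDecision.SPLIT:
            try:
                na, nb = split_overlap(inst_a.mask, inst_b.mask, inst_a.id, inst_b.id)
            except ValueError:
                log.warning(
                    "split of instances %d/%d degenerate (coincident centroids); merging",
                    inst_a.id, inst_b.id,
                )
                decision = OverlapDecision.MERGE
        if decision is OverlapDecision.MERGE:
            inst_a.mask = np.logical_or(inst_a.mask, inst_b.mask)
            out.instances.remove(inst_b)
            continue
        if decision is OverlapDecision.RANDOM_ASSIGN:
            decision = (
                OverlapDecision.ASSIGN_TO_A
                if rng.random() < 0.5
                else OverlapDecision.ASSIGN_TO_B
            )
        if decision is OverlapDecision.ASSIGN_TO_A:
            overlap = np.logical_and(inst_a.mask, inst_b.mask)
            inst_b.mask = np.logical_and(inst_b.mask, ~overlap)
        elif decision is OverlapDecision.ASSIGN_TO_B:
            overlap = np.logical_and(inst_a.mask, inst_b.mask)
            inst_a.mask = np.logical_and(inst_a.mask, ~overlap)
        else:  # SPLIT
            inst_a.mask = na
            inst_b.mask = nb
        # assignment or split may have emptied one side entirely
        for inst in (inst_a, inst_b):
            if inst.area == 0:
                out.instances.remove(inst)

    return remove_small(out, cfg.small_area_fraction)


def postprocess(iset: InstanceSet, cfg: PostprocessConfig | None = None) -> InstanceSet:
    """Full post-processing: remove small instances, then resolve overlaps.

    Small-instance removal runs first on the raw set and again inside
    :func:`resolve_overlaps` after splitting, each time with the mean
    area recomputed on the current set.
    """
    cfg = cfg or PostprocessConfig()
    return resolve_overlaps(remove_small(iset, cfg.small_area_fraction), cfg)


def to_label_map(iset: InstanceSet, dtype=np.uint16) -> np.ndarray:
    """Export a disjoint InstanceSet as a label map (0 = background)."""
    if not iset.is_disjoint():
        raise ValueError(
            "masks overlap; run resolve_overlaps before exporting a label map"
        )
    out = np.zeros(iset.shape, dtype=dtype)
    for inst in iset:
        if inst.id > np.iinfo(dtype).max:
            raise ValueError(f"id {inst.id} exceeds {np.dtype(dtype).name} range")
        out[inst.mask] = inst.id
    return out


def from_label_map(labels: np.ndarray) -> InstanceSet:
    """Build an InstanceSet from a label map, preserving label values as ids."""
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    insts = [Instance(int(v), labels == v) for v in ids]
    return InstanceSet(labels.shape, insts)
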
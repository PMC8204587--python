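"""Overlapping tiling of large images and stitching of per-tile segmentations.

Memory-limited segmenters cannot process a full-resolution
super-resolution frame (e.g. 5120 x 5120), so the image is divided into
square tiles (default 512) that overlap their neighbours by a margin
(default 128).  After per-tile segmentation, instances from different
tiles whose masks touch inside a shared region are matched and unioned,
eliminating the false instance divisions a tile border would otherwise
introduce; any residual overlaps go through the standard overlap
resolver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .instances import Instance, InstanceSet, PostprocessConfig, resolve_overlaps

log = logging.getLogger(__name__)

__all__ = ["TileLayout", "make_tiles", "stitch"]


@dataclass(frozen=True)
class TileLayout:
    """Grid of overlapping tiles covering an image.

    Origins are row-major top-left corners; the interior stride is
    ``tile_size - margin`` and the last tile per axis is clamped so it
    ends exactly at the image edge.
    """

    image_size: tuple[int, int]
    tile_size: int
    margin: int
    origins: tuple[tuple[int, int], ...]

    @property
    def n_tiles(self) -> int:
        return len(self.origins)

    def tile_shape(self, index: int) -> tuple[int, int]:
        h, w = self.image_size
        r, c = self.origins[index]
        return (min(self.tile_size, h) , min(self.tile_size, w))

    def tile_slices(self, index: int) -> tuple[slice, slice]:
        r, c = self.origins[index]
        th, tw = self.tile_shape(index)
        return slice(r, r + th), slice(c, c + tw)


def _axis_origins(length: int, tile: int, stride: int) -> list[int]:
    if tile >= length:
        return [0]
    n = int(np.ceil((length - tile) / stride)) + 1
    origins = [min(i * stride, length - tile) for i in range(n)]
    # clamping can duplicate the final origin when stride divides exactly
    out: list[int] = []
    for o in origins:
        if not out or o != out[-1]:
            out.append(o)
    return out


def make_tiles(
    img: np.ndarray, tile_size: int = 512, margin: int = 128
) -> tuple[TileLayout, list[np.ndarray]]:
    """Cut an image into overlapping tiles.

    Requires ``0 <= margin < tile_size``.  A tile larger than the image
    degrades to a single full-image tile with a warning.  Reassembling
    the returned tiles at their origins reconstructs the image exactly.
    """
    if margin < 0 or margin >= tile_size:
        raise ValueError("need 0 <= margin < tile_size")
    h, w = img.shape
    if tile_size > min(h, w):
        log.warning(
            "tile_size %d exceeds image %s; using a single full-image tile",
            tile_size, img.shape,
        )
        layout = TileLayout((h, w), max(h, w), margin, ((0, 0),))
        return layout, [img.copy()]
    stride = tile_size - margin
    rows = _axis_origins(h, tile_size, stride)
    cols = _axis_origins(w, tile_size, stride)
    origins = tuple((r, c) for r in rows for c in cols)
    layout = TileLayout((h, w), tile_size, margin, origins)
    tiles = [img[layout.tile_slices(i)].copy() for i in range(layout.n_tiles)]
    return layout, tiles


def assemble(layout: TileLayout, tiles: list[np.ndarray]) -> np.ndarray:
    """Paste tiles back at their origins (overlaps overwritten identically)."""
    if len(tiles) != layout.n_tiles:
        raise ValueError("tile count does not match layout")
    out = np.zeros(layout.image_size, dtype=tiles[0].dtype)
    for i, tile in enumerate(tiles):
        out[layout.tile_slices(i)] = tile
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # attach the later-seen root under the earlier one so global
            # ids follow first-seen order
            if ra < rb:
                self.parent[rb] = ra
            else:
                self.parent[ra] = rb


def stitch(
    layout: TileLayout,
    tile_sets: list[InstanceSet],
    min_match_fraction: float = 0.0,
    postprocess_cfg: PostprocessConfig | None = None,
) -> InstanceSet:
    """Recombine per-tile segmentations into one whole-image segmentation.

    Every tile-local instance is placed at its tile's origin in global
    coordinates.  Instances from *different* tiles are matched when their
    global masks intersect and the intersection exceeds
    ``min_match_fraction`` of the smaller fragment (default 0: any shared
    pixel matches).  Matched groups (connected components of the match
    graph) are unioned into single global instances, with ids assigned in
    first-seen order (tile row-major, then local id).  Residual overlaps
    between distinct global instances are passed through
    :func:`stormseg.instances.resolve_overlaps` before return.
    """
    if len(tile_sets) != layout.n_tiles:
        raise ValueError(
            f"layout has {layout.n_tiles} tiles but {len(tile_sets)} sets given"
        )
    h, w = layout.image_size

    # place all fragments in global coordinates, in first-seen order
    frags: list[np.ndarray] = []
    frag_tile: list[int] = []
    for t, iset in enumerate(tile_sets):
        rs, cs = layout.tile_slices(t)
        expected = (rs.stop - rs.start, cs.stop - cs.start)
        if iset.shape != expected:
            raise ValueError(
                f"tile {t}: instance set shape {iset.shape} != tile shape {expected}"
            )
        for inst in sorted(iset.instances, key=lambda i: i.id):
            g = np.zeros((h, w), dtype=bool)
            g[rs, cs] = inst.mask
            frags.append(g)
            frag_tile.append(t)

    uf = _UnionFind(len(frags))
    # only tiles whose rectangles overlap can share pixels
    rects = [layout.tile_slices(t) for t in range(layout.n_tiles)]
    by_tile: dict[int, list[int]] = {}
    for fi, t in enumerate(frag_tile):
        by_tile.setdefault(t, []).append(fi)
    for ta in range(layout.n_tiles):
        for tb in range(ta + 1, layout.n_tiles):
            ra, rb = rects[ta], rects[tb]
            if (ra[0].stop <= rb[0].start or rb[0].stop <= ra[0].start
                    or ra[1].stop <= rb[1].start or rb[1].stop <= ra[1].start):
                continue
            for fa in by_tile.get(ta, []):
                for fb in by_tile.get(tb, []):
                    inter = int(np.logical_and(frags[fa], frags[fb]).sum())
                    if inter == 0:
                        continue
                    smaller = min(frags[fa].sum(), frags[fb].sum())
                    if inter > min_match_fraction * smaller:
                        uf.union(fa, fb)

    groups: dict[int, np.ndarray] = {}
    for fi, g in enumerate(frags):
        root = uf.find(fi)
        if root in groups:
            groups[root] |= g
        else:
            groups[root] = g.copy()

    insts = [
        Instance(next_id + 1, groups[root])
        for next_id, root in enumerate(sorted(groups))
    ]
    merged = InstanceSet((h, w), insts)
    log.info("stitch: %d fragments -> %d instances", len(frags), len(merged))
    if not merged.is_disjoint():
        merged = resolve_overlaps(merged, postprocess_cfg or PostprocessConfig())
    return merged
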
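"""File I/O: intensity images, label maps, mask stacks, layouts and configs.

TIFF is the native format (via :mod:`tifffile`); PNG is supported for
8/16-bit intensity images via :mod:`imageio`.  Label maps are written as
16-bit TIFF.  An overlapping instance set that cannot be flattened to a
label map is stored as a multi-page TIFF mask stack with a CSV sidecar
carrying id, area and confidence.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .instances import Instance, InstanceSet, from_label_map, to_label_map
from .tiling import TileLayout

__all__ = [
    "read_image", "write_image",
    "read_label_map", "write_label_map",
    "read_instance_set", "write_instance_set",
    "write_layout", "read_layout",
    "load_yaml", "dump_yaml",
]


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image, got shape {arr.shape}")
    return arr


def write_image(path, img: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, img)


def read_label_map(path) -> np.ndarray:
    arr = read_image(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: label map must be integer-typed, got {arr.dtype}")
    return arr


def write_label_map(path, labels: np.ndarray) -> None:
    write_image(path, labels.astype(np.uint16))


def write_instance_set(path, iset: InstanceSet) -> None:
    """Write a label-map TIFF when disjoint, else a mask stack + CSV sidecar."""
    path = Path(path)
    if iset.is_disjoint():
        write_label_map(path, to_label_map(iset))
        return
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([inst.mask.astype(np.uint8) for inst in iset])
    tifffile.imwrite(path, stack)
    sidecar = pd.DataFrame(
        {
            "id": [i.id for i in iset],
            "area": [i.area for i in iset],
            "confidence": [i.confidence for i in iset],
        }
    )
    sidecar.to_csv(path.with_suffix(".csv"), index=False)


def read_instance_set(path) -> InstanceSet:
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        return from_label_map(arr)
    sidecar_path = path.with_suffix(".csv")
    if sidecar_path.exists():
        sidecar = pd.read_csv(sidecar_path)
        ids = sidecar["id"].tolist()
        confs = sidecar["confidence"].tolist()
    else:
        ids = list(range(1, arr.shape[0] + 1))
        confs = [None] * arr.shape[0]
    insts = [
        Instance(int(ids[k]), arr[k] > 0, None if pd.isna(confs[k]) else float(confs[k]))
        for k in range(arr.shape[0])
    ]
    return InstanceSet(arr.shape[1:], insts)


def write_layout(path, layout: TileLayout) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "image_size": list(layout.image_size),
        "tile_size": layout.tile_size,
        "margin": layout.margin,
        "origins": [list(o) for o in layout.origins],
    }
    path.write_text(json.dumps(doc, indent=2))


def read_layout(path) -> TileLayout:
    doc = json.loads(Path(path).read_text())
    return TileLayout(
        image_size=tuple(doc["image_size"]),
        tile_size=int(doc["tile_size"]),
        margin=int(doc["margin"]),
        origins=tuple(tuple(o) for o in doc["origins"]),
    )


def load_yaml(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return doc


def dump_yaml(path, doc: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
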
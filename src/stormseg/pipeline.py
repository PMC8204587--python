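"""Pipeline orchestration: preprocess -> denoise -> tile -> segment ->
stitch -> postprocess -> evaluate.

Each enabled stage reads the previous stage's output, writes its own
artifact with a stage suffix into the run directory, and is timed into a
machine-readable manifest (config hash, seed, library versions, per-stage
timings).  Re-running the same config on the same inputs reproduces the
data artifacts byte-identically; the manifest's timings are the only
run-to-run variation.

Segmenters are plugins resolved by name.  Shipped:

* ``threshold-cc`` — the reference threshold / fill-holes / connected
  components segmenter (see :func:`stormseg.simgen.oracle_segmenter`);
* ``external-labelmap`` — reads an instance segmentation produced
  elsewhere (e.g. a trained network's exported label map).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio
from .denoise import binarize, subtract_noise, validate_noise_map
from .imageops import PreprocessConfig, preprocess, resize_labels
from .instances import InstanceSet, PostprocessConfig, postprocess as _postprocess, to_label_map
from .metrics import MetricsConfig, MetricsReport, evaluate
from .simgen import oracle_segmenter
from .tiling import make_tiles, stitch

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "DataError", "run_pipeline", "SEGMENTERS"]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(RuntimeError):
    """Missing or malformed data encountered mid-run (CLI exit code 3)."""


def _threshold_cc_segmenter(params: dict):
    threshold = params.get("threshold", 1)

    def segment(img: np.ndarray) -> InstanceSet:
        return oracle_segmenter(img, threshold)

    return segment


def _external_labelmap_segmenter(params: dict):
    path = params.get("path")
    if path is None:
        raise ConfigError("external-labelmap segmenter requires a 'path' parameter")

    def segment(img: np.ndarray) -> InstanceSet:
        iset = sio.read_instance_set(path)
        if iset.shape != img.shape:
            raise DataError(
                f"external labelmap {path} shape {iset.shape} != image {img.shape}"
            )
        return iset

    return segment


SEGMENTERS = {
    "threshold-cc": _threshold_cc_segmenter,
    "external-labelmap": _external_labelmap_segmenter,
}


@dataclass
class RunConfig:
    image: str
    out_dir: str
    gt: str | None = None
    noise_map: str | None = None
    segmenter: str = "threshold-cc"
    segmenter_params: dict = field(default_factory=dict)
    do_preprocess: bool = False
    do_denoise: bool = False
    do_tile: bool = False
    do_postprocess: bool = True
    do_evaluate: bool = False
    preprocess_cfg: PreprocessConfig = field(default_factory=PreprocessConfig)
    tile_size: int = 512
    tile_margin: int = 128
    postprocess_cfg: PostprocessConfig = field(default_factory=PostprocessConfig)
    metrics_cfg: MetricsConfig = field(default_factory=MetricsConfig)
    rng_seed: int = 0

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        try:
            if "preprocess_cfg" in doc:
                sub = dict(doc["preprocess_cfg"])
                if sub.get("target_size") is not None:
                    sub["target_size"] = tuple(sub["target_size"])
                doc["preprocess_cfg"] = PreprocessConfig(**sub)
            if "postprocess_cfg" in doc:
                doc["postprocess_cfg"] = PostprocessConfig(**doc["postprocess_cfg"])
            if "metrics_cfg" in doc:
                doc["metrics_cfg"] = MetricsConfig(**doc["metrics_cfg"])
            return cls(**doc)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        from dataclasses import asdict

        doc = asdict(self)
        ts = doc["preprocess_cfg"]["target_size"]
        if ts is not None:
            doc["preprocess_cfg"]["target_size"] = list(ts)
        return doc


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> MetricsReport | None:
    """Execute the enabled stages in fixed order and write all artifacts.

    Returns the evaluation report when evaluation is enabled, else None.
    A stage failure aborts with the stage name; artifacts written so far
    are kept next to a ``.partial`` marker.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / ".partial"
    marker.write_text("run in progress\n")
    timings: dict[str, float] = {}
    stage = "load"
    try:
        img_path = Path(cfg.image)
        if not img_path.exists():
            raise DataError(f"input image not found: {img_path}")
        img = sio.read_image(img_path)
        original_shape = img.shape
        stem = img_path.stem

        if cfg.do_preprocess:
            stage = "preprocess"
            t0 = time.perf_counter()
            img = preprocess(img, cfg.preprocess_cfg)
            timings[stage] = time.perf_counter() - t0
            sio.write_image(out_dir / f"{stem}_preprocessed.tif", img)

        if cfg.do_denoise:
            stage = "denoise"
            t0 = time.perf_counter()
            if cfg.noise_map is None:
                raise ConfigError("denoise stage enabled but no noise_map given")
            nm_path = Path(cfg.noise_map)
            if not nm_path.exists():
                raise DataError(f"noise map not found: {nm_path}")
            probs = validate_noise_map(sio.read_image(nm_path))
            if probs.shape != img.shape:
                raise DataError(
                    f"noise map shape {probs.shape} != image shape {img.shape}"
                )
            mask = binarize(probs)
            img = subtract_noise(img, mask)
            timings[stage] = time.perf_counter() - t0
            sio.write_image(out_dir / f"{stem}_noise_mask.tif", mask.astype(np.uint8))
            sio.write_image(out_dir / f"{stem}_denoised.tif", img)

        stage = "segment"
        if cfg.segmenter not in SEGMENTERS:
            raise ConfigError(
                f"unknown segmenter {cfg.segmenter!r}; available: {sorted(SEGMENTERS)}"
            )
        segment = SEGMENTERS[cfg.segmenter](cfg.segmenter_params)
        t0 = time.perf_counter()
        if cfg.do_tile:
            layout, tiles = make_tiles(img, cfg.tile_size, cfg.tile_margin)
            tile_sets = [segment(tile) for tile in tiles]
            timings["segment"] = time.perf_counter() - t0
            sio.write_layout(out_dir / f"{stem}_layout.json", layout)
            stage = "stitch"
            t0 = time.perf_counter()
            pred = stitch(layout, tile_sets, postprocess_cfg=cfg.postprocess_cfg)
            timings["stitch"] = time.perf_counter() - t0
        else:
            pred = segment(img)
            timings["segment"] = time.perf_counter() - t0
        sio.write_instance_set(out_dir / f"{stem}_segmented.tif", pred)

        if cfg.do_postprocess:
            stage = "postprocess"
            t0 = time.perf_counter()
            pred = _postprocess(pred, cfg.postprocess_cfg)
            timings[stage] = time.perf_counter() - t0
            sio.write_image(out_dir / f"{stem}_postprocessed.tif", to_label_map(pred))

        report = None
        if cfg.do_evaluate:
            stage = "evaluate"
            if cfg.gt is None:
                raise ConfigError("evaluate stage enabled but no gt given")
            gt_path = Path(cfg.gt)
            if not gt_path.exists():
                raise DataError(f"ground truth not found: {gt_path}")
            gt = sio.read_instance_set(gt_path)
            if pred.shape != gt.shape:
                # segmentation ran at preprocessed scale: upsize the label
                # map back to the ground-truth frame before scoring
                labels = resize_labels(to_label_map(pred), gt.shape)
                from .instances import from_label_map

                pred = from_label_map(labels)
                sio.write_image(out_dir / f"{stem}_upsized.tif", labels)
            t0 = time.perf_counter()
            report = evaluate(gt, pred, cfg.metrics_cfg)
            timings[stage] = time.perf_counter() - t0
            (out_dir / f"{stem}_report.json").write_text(
                json.dumps(
                    {
                        "f1": report.f1,
                        "fn_percent": report.fn_percent,
                        "fp_percent": report.fp_percent,
                        "mean_hausdorff": report.mean_hausdorff,
                        "n_tp": report.n_tp,
                        "n_fn": report.n_fn,
                        "n_fp": report.n_fp,
                    },
                    indent=2,
                )
            )

        manifest = {
            "config": cfg.to_dict(),
            "config_hash": _config_hash(cfg),
            "rng_seed": cfg.rng_seed,
            "original_shape": list(original_shape),
            "versions": {"numpy": np.__version__, "stormseg": _version()},
            "timings_s": timings,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        marker.unlink()
        return report
    except Exception as exc:
        log.error("pipeline aborted in stage %r: %s", stage, exc)
        marker.write_text(f"failed in stage {stage}: {exc}\n")
        raise


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("stormseg")
    except PackageNotFoundError:
        return "unknown"
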
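"""Intensity-image preprocessing: resizing, Gaussian blur, histogram equalization.

Images are plain 2-D numpy arrays; the dtype carries the bit depth
(``uint8``, ``uint16`` or a float dtype).  Label maps are non-negative
integer arrays with 0 as background and are resized with nearest-neighbour
interpolation only, so no label value is ever invented.

The pixel grid convention throughout the package is row-major, 0-based,
with pixel centers at integer coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.transform import resize as _sk_resize

log = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "resize_image",
    "resize_labels",
    "gaussian_blur",
    "equalize_hist",
    "preprocess",
]


def _dtype_range(dtype: np.dtype) -> tuple[float, float]:
    dtype = np.dtype(dtype)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return float(info.min), float(info.max)
    return 0.0, 1.0


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing recipe: resize, then blur, then equalize.

    ``target_size`` of ``None`` skips resizing; ``blur_sigma`` of 0 skips
    blurring.  Defaults mirror the acquisition pipeline this package
    targets (sigma-2 Gaussian blur, full-range histogram equalization).
    """

    target_size: tuple[int, int] | None = None
    blur_sigma: float = 2.0
    equalize: bool = True

    def __post_init__(self) -> None:
        if self.target_size is not None:
            h, w = self.target_size
            if h <= 0 or w <= 0:
                raise ValueError(f"target_size must be positive, got {self.target_size}")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")


def resize_image(img: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """Resize an intensity image, averaging when downsizing.

    Downsizing by an integer factor uses exact block (area) averaging —
    each output pixel is the mean of its k x k source block.  Non-integer
    downsizing uses bilinear interpolation with an anti-alias prefilter;
    upsizing uses plain bilinear interpolation.  The output keeps the
    input dtype; integer outputs are rounded half-to-even.
    """
    th, tw = int(target_size[0]), int(target_size[1])
    if th <= 0 or tw <= 0:
        raise ValueError(f"target size must be positive, got {target_size}")
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    h, w = img.shape
    if (th, tw) == (h, w):
        return img.copy()

    if h % th == 0 and w % tw == 0 and th <= h and tw <= w:
        kh, kw = h // th, w // tw
        out = img.astype(np.float64).reshape(th, kh, tw, kw).mean(axis=(1, 3))
    else:
        downsizing = th < h or tw < w
        out = _sk_resize(
            img.astype(np.float64),
            (th, tw),
            order=1,
            anti_aliasing=downsizing,
            preserve_range=True,
            mode="reflect",
        )
    return _cast_back(out, img.dtype)


def _cast_back(out: np.ndarray, dtype: np.dtype) -> np.ndarray:
    if np.issubdtype(np.dtype(dtype), np.integer):
        lo, hi = _dtype_range(dtype)
        return np.clip(np.rint(out), lo, hi).astype(dtype)
    return out.astype(dtype)


def resize_labels(labels: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """Resize a label map with nearest-neighbour interpolation.

    The set of output label values is always a subset of the input's;
    background (0) stays background.
    """
    th, tw = int(target_size[0]), int(target_size[1])
    if th <= 0 or tw <= 0:
        raise ValueError(f"target size must be positive, got {target_size}")
    if labels.shape == (th, tw):
        return labels.copy()
    out = _sk_resize(
        labels, (th, tw), order=0, anti_aliasing=False, preserve_range=True
    )
    return out.astype(labels.dtype)


def gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Isotropic Gaussian blur (kernel truncated at 4*sigma, reflect boundary).

    ``sigma=0`` is the identity.  Output keeps the input dtype.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return img.copy()
    out = ndi.gaussian_filter(img.astype(np.float64), sigma=sigma, truncate=4.0, mode="reflect")
    return _cast_back(out, img.dtype)


def equalize_hist(img: np.ndarray) -> np.ndarray:
    """Histogram equalization with full-range normalization.

    The image is first min-max normalized to the full bit-depth range and
    then mapped through its normalized cumulative histogram (256 bins for
    8-bit input, 65 536 for 16-bit), a monotone non-decreasing mapping
    whose output spans the full range.  A constant image has no contrast
    to equalize and is returned unchanged with a warning.
    """
    if img.size == 0:
        raise ValueError("empty image")
    lo, hi = float(img.min()), float(img.max())
    if lo == hi:
        log.warning("equalize_hist: constant image, returned unchanged")
        return img.copy()

    dtype = np.dtype(img.dtype)
    if dtype == np.uint8:
        n_bins = 256
    else:
        n_bins = 65536
    # min-max normalize onto the bin range
    norm = np.rint((img.astype(np.float64) - lo) / (hi - lo) * (n_bins - 1)).astype(np.int64)
    hist = np.bincount(norm.ravel(), minlength=n_bins)
    cdf = np.cumsum(hist).astype(np.float64)
    cdf /= cdf[-1]
    cdf_min = cdf[norm.min()]
    mapped = (cdf - cdf_min) / (1.0 - cdf_min) if cdf_min < 1.0 else cdf
    out = mapped[norm] * (n_bins - 1)
    if np.issubdtype(dtype, np.integer):
        out = np.rint(out)
        if dtype == np.uint8:
            return out.astype(np.uint8)
        return np.clip(out, 0, 65535).astype(dtype)
    return (out / (n_bins - 1)).astype(dtype)


def preprocess(img: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Apply the full recipe in fixed order: resize -> blur -> equalize."""
    out = img
    if cfg.target_size is not None:
        out = resize_image(out, cfg.target_size)
        log.info("preprocess: resized to %s", cfg.target_size)
    if cfg.blur_sigma > 0:
        out = gaussian_blur(out, cfg.blur_sigma)
        log.info("preprocess: blurred with sigma=%g", cfg.blur_sigma)
    if cfg.equalize:
        out = equalize_hist(out)
        log.info("preprocess: histogram equalized")
    return out
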
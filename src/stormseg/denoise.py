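"""Semantic noise removal: Otsu binarization of a noise-probability map
and subtraction of the resulting mask from the test image.

Localization-based super-resolution images frequently contain diffuse
"noisy regions" — non-specific binding, unbound fluorophores,
out-of-focus fluorescence and autofluorescence — that downstream
instance segmenters mistake for nuclei.  Given a per-pixel noise
probability map (from any provider: a trained semantic network, a file
on disk, or the classical density baseline shipped here), the map is
binarized with Otsu's method and the flagged pixels are zeroed in the
image.
"""

from __future__ import annotations

import logging
from typing import Callable, Protocol

import numpy as np
import scipy.ndimage as ndi

log = logging.getLogger(__name__)

__all__ = [
    "otsu_threshold",
    "binarize",
    "subtract_noise",
    "denoise_image",
    "NoiseMapProvider",
    "file_noise_provider",
    "density_noise_provider",
]

N_BINS = 256


def validate_noise_map(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2:
        raise ValueError("noise map must be 2-D")
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("noise probabilities must lie in [0, 1]")
    return probs


def otsu_threshold(hist: np.ndarray) -> int:
    """Otsu's threshold on a 256-bin histogram, as a bin index.

    Returns the bin t maximizing the between-class variance
    w0*w1*(mu0 - mu1)^2 of the split {bins <= t} / {bins > t}; ties break
    toward the lower bin.  A histogram with a single populated bin
    returns that bin (degenerate: everything in one class).
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.ndim != 1 or hist.size != N_BINS:
        raise ValueError(f"expected a {N_BINS}-bin histogram, got shape {hist.shape}")
    total = hist.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    populated = np.flatnonzero(hist)
    if populated.size == 1:
        return int(populated[0])

    p = hist / total
    bins = np.arange(N_BINS, dtype=np.float64)
    w0 = np.cumsum(p)                      # weight of class {<= t}
    mu_cum = np.cumsum(p * bins)
    mu_total = mu_cum[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.nan_to_num(var_between, nan=0.0)
    return int(np.argmax(var_between))  # argmax takes the first (lowest) maximizer


def binarize(probs: np.ndarray) -> np.ndarray:
    """Binarize a noise-probability map with Otsu's method.

    Probabilities are quantized to 256 bins; pixels strictly above the
    Otsu threshold are flagged as noise.  The strict inequality makes an
    all-zero map yield an empty mask, and re-binarizing a 0/1 mask is the
    identity.
    """
    probs = validate_noise_map(probs)
    quant = np.clip(np.rint(probs * (N_BINS - 1)), 0, N_BINS - 1).astype(np.int64)
    hist = np.bincount(quant.ravel(), minlength=N_BINS)
    t = otsu_threshold(hist)
    return quant > t


def subtract_noise(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero image pixels under the noise mask; everything else untouched."""
    if img.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs mask {mask.shape}")
    out = img.copy()
    out[np.asarray(mask, dtype=bool)] = 0
    return out


class NoiseMapProvider(Protocol):
    """Anything that maps an image to a noise-probability map in [0, 1]."""

    def __call__(self, img: np.ndarray) -> np.ndarray: ...


def file_noise_provider(path) -> Callable[[np.ndarray], np.ndarray]:
    """Provider returning a precomputed probability map read from ``path``.

    This is the hook for maps produced elsewhere, e.g. by a trained
    semantic segmentation network.
    """
    from .io import read_image

    def provider(img: np.ndarray) -> np.ndarray:
        probs = validate_noise_map(read_image(path))
        if probs.shape != img.shape:
            raise ValueError(
                f"noise map shape {probs.shape} does not match image {img.shape}"
            )
        return probs

    return provider


def density_noise_provider(
    sigma: float = 8.0, exclude: np.ndarray | None = None
) -> Callable[[np.ndarray], np.ndarray]:
    """Classical baseline provider: smoothed local density of lit pixels.

    Computes the fraction of above-zero pixels in a Gaussian
    neighbourhood of scale ``sigma`` and rescales it to [0, 1].  Diffuse
    noise regions are locally dense in lit pixels, which is exactly what
    this statistic ranks; it knows nothing about nuclei, so regions in
    ``exclude`` (e.g. detected instances) can be masked out of the score.
    """

    def provider(img: np.ndarray) -> np.ndarray:
        lit = (np.asarray(img) > 0).astype(np.float64)
        dens = ndi.gaussian_filter(lit, sigma=sigma, mode="constant")
        if exclude is not None:
            dens[np.asarray(exclude, dtype=bool)] = 0.0
        top = dens.max()
        if top > 0:
            dens /= top
        return dens

    return provider


def denoise_image(img: np.ndarray, provider: NoiseMapProvider) -> tuple[np.ndarray, np.ndarray]:
    """Run a provider, binarize its map, subtract; returns (denoised, mask)."""
    probs = validate_noise_map(provider(img))
    if probs.shape != img.shape:
        raise ValueError("provider returned a map with mismatched shape")
    mask = binarize(probs)
    log.info("denoise: %d px (%.2f%%) flagged as noise",
             int(mask.sum()), 100.0 * mask.mean() if mask.size else 0.0)
    return subtract_noise(img, mask), mask
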
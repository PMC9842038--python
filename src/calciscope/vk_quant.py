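"""Von Kossa staining quantification.

Von Kossa silver staining marks phosphate-rich mineral deposits as black
puncta on a light counterstain. Quantification follows the classical
histology recipe: convert the RGB micrograph to 8-bit grayscale, apply one
threshold uniformly across all conditions being compared, and summarize
the resulting binary image by its integrated density (255 per foreground
pixel) and area fraction.

The study-wide threshold can be fixed by the caller or derived with
:func:`auto_threshold`, which runs Otsu's method on the histogram pooled
over *all* images so a single value is shared across conditions. The
value actually used is always carried in the result and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .image_io import BinaryMask, CalibratedImage, RGBImage

__all__ = [
    "VKResult",
    "rgb_to_gray8",
    "binarize_dark",
    "auto_threshold",
    "otsu_from_histogram",
    "integrated_density",
]

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luminance weights, selectable instead of the plain mean.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class VKResult:
    """Summary of a thresholded Von Kossa image.

    ``integrated_density`` is the sum of binary-image intensities, i.e.
    255 per foreground pixel; ``normalized_density`` divides it by the ROI
    pixel count so fields of view of different sizes are comparable.
    """

    integrated_density: float
    area_fraction: float
    normalized_density: float
    threshold_used: int
    n_foreground_px: int
    roi_px_count: int
    source_id: str = ""


def rgb_to_gray8(
    rgb, pixels_per_micron: float | None = None, *, weights: str = "mean", source_id: str = ""
) -> CalibratedImage:
    """Convert an RGB raster to 8-bit grayscale.

    The default is the unweighted channel mean (R+G+B)/3 rounded half-up
    and clipped to 0-255, matching the historical behavior of common
    measurement software; ``weights="luminance"`` selects ITU-R BT.601
    weights instead. Accepts an :class:`RGBImage` (calibration carried
    over) or a bare (H, W, 3) array plus an explicit calibration.
    """
    if isinstance(rgb, RGBImage):
        arr = rgb.pixels
        ppm = rgb.pixels_per_micron
        sid = source_id or rgb.source_id
    else:
        arr = np.asarray(rgb, dtype=np.float64)
        if pixels_per_micron is None:
            raise ValidationError("pixels_per_micron is required for bare arrays")
        ppm = pixels_per_micron
        sid = source_id
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected an (H, W, 3) raster, got shape {arr.shape}")
    if weights == "mean":
        gray = arr.mean(axis=2)
    elif weights == "luminance":
        gray = arr @ np.asarray(LUMINANCE_WEIGHTS)
    else:
        raise ValidationError(f"unknown weights mode {weights!r}")
    # half-up rounding: counts near the threshold depend on this choice
    gray = np.clip(np.floor(gray + 0.5), 0, 255)
    return CalibratedImage(gray, ppm, source_id=sid)


def binarize_dark(
    gray: CalibratedImage, threshold: int, *, dark_foreground: bool = True
) -> BinaryMask:
    """Binarize with foreground = pixels at or below the threshold.

    Von Kossa deposits are dark on a light counterstain, so foreground is
    intensity <= threshold; pass ``dark_foreground=False`` for bright
    objects (e.g. fluorescence-derived masks).
    """
    t = int(threshold)
    if not 0 <= t <= 255:
        raise ValidationError(f"threshold must be in 0-255, got {threshold}")
    if dark_foreground:
        fg = gray.pixels <= t
    else:
        fg = gray.pixels >= t
    return BinaryMask(fg.astype(np.uint8), gray.pixels_per_micron)


def otsu_from_histogram(hist) -> int:
    """Otsu's threshold on a 256-bin histogram, with midpoint tie-breaking.

    Maximizes between-class variance over all candidate thresholds t
    (classes <= t and > t). When a plateau of thresholds is equally
    optimal — e.g. well-separated modes — the plateau midpoint is
    returned (half-up), so a histogram with mass only at 0 and 255 yields
    127 rather than an arbitrary plateau edge.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValidationError(f"expected a 256-bin histogram, got shape {hist.shape}")
    if np.count_nonzero(hist) < 2:
        raise ValidationError("undefined threshold: histogram has fewer than two occupied bins")
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)[:-1]  # P(class <= t), t = 0..254
    m0 = np.cumsum(p * levels)[:-1]
    mt = float((p * levels).sum())
    valid = (w0 > 0) & (w0 < 1)
    sigma_b = np.full(255, -1.0)
    sigma_b[valid] = (mt * w0[valid] - m0[valid]) ** 2 / (w0[valid] * (1.0 - w0[valid]))
    best = sigma_b.max()
    ties = np.flatnonzero(sigma_b >= best - 1e-12 * max(best, 1.0))
    return int(np.floor(ties.mean() + 0.5))


def auto_threshold(images) -> int:
    """Otsu threshold on the histogram pooled over all given images.

    Pooling enforces the "one threshold uniformly applied across
    conditions" contract: all images being compared contribute to a single
    256-bin histogram and receive the same cut.
    """
    images = list(images)
    if not images:
        raise ValidationError("need at least one image")
    hist = np.zeros(256, dtype=np.int64)
    for img in images:
        px = img.pixels if isinstance(img, CalibratedImage) else np.asarray(img)
        vals = np.clip(np.floor(np.asarray(px, dtype=np.float64) + 0.5), 0, 255).astype(np.intp)
        hist += np.bincount(vals.ravel(), minlength=256)
    t = otsu_from_histogram(hist)
    logger.info("auto_threshold: pooled Otsu over %d image(s) -> %d", len(images), t)
    return t


def integrated_density(
    mask: BinaryMask,
    roi_px_count: int | None = None,
    *,
    threshold_used: int = -1,
    source_id: str = "",
) -> VKResult:
    """Integrated density and area fraction of a thresholded image.

    ``roi_px_count`` defaults to the full image pixel count; supply the
    tissue-region pixel count instead to normalize to tissue area.
    """
    n_fg = mask.n_foreground
    if roi_px_count is None:
        roi_px_count = mask.mask.size
    roi_px_count = int(roi_px_count)
    if roi_px_count < n_fg or roi_px_count <= 0:
        raise ValidationError(
            f"roi_px_count ({roi_px_count}) must be positive and >= foreground count ({n_fg})"
        )
    intden = 255.0 * n_fg
    return VKResult(
        integrated_density=intden,
        area_fraction=n_fg / roi_px_count,
        normalized_density=intden / roi_px_count,
        threshold_used=int(threshold_used),
        n_foreground_px=n_fg,
        roi_px_count=roi_px_count,
        source_id=source_id,
    )
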
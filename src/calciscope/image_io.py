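"""Image and stack I/O with explicit spatial calibration.

Every measurement downstream is reported in micrometers through a single
pixels-per-micrometer constant supplied by the caller (for the acquisition
setup this package was written around, 2.73 px/um at 20x). The calibration
is a required, explicit input: it is never inferred from TIFF metadata
unless the caller passes ``pixels_per_micron=None`` together with
``allow_metadata_calibration=True``, because a study-wide measured constant
is less error-prone than per-file tags of mixed provenance.

Conventions: arrays are row-major with the origin at the top-left corner
and 0-based indices; multichannel z-stacks are ordered ``(z, channel, y,
x)``; multi-page TIFFs are assumed z-major (all channels of slice 0, then
slice 1, ...) unless ``page_order="c-major"`` is given.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import ImageFormatError, ValidationError

__all__ = [
    "CalibratedImage",
    "RGBImage",
    "MultichannelStack",
    "BinaryMask",
    "read_image",
    "write_image",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "px_to_um",
    "um_to_px",
]

CHANNEL_ROLES = ("nuclei", "signal", "other")


def _check_calibration(pixels_per_micron: float) -> float:
    ppm = float(pixels_per_micron)
    if not np.isfinite(ppm) or ppm <= 0:
        raise ValidationError(f"pixels_per_micron must be positive, got {pixels_per_micron!r}")
    return ppm


@dataclass
class CalibratedImage:
    """A single-channel 2D intensity field plus spatial calibration.

    Intensities are stored at full float precision but are nominally on the
    8-bit 0-255 scale after RGB conversion; thresholds throughout the
    package are expressed on that scale.
    """

    pixels: np.ndarray
    pixels_per_micron: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValidationError(f"expected a 2D image, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
            raise ValidationError("intensities must be finite and non-negative")
        self.pixels_per_micron = _check_calibration(self.pixels_per_micron)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class RGBImage:
    """A 3-channel raster read from disk, awaiting grayscale conversion.

    Returned by :func:`read_image` for color files; pass it to
    :func:`calciscope.vk_quant.rgb_to_gray8` before any quantification.
    """

    pixels: np.ndarray
    pixels_per_micron: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ImageFormatError(f"expected an (H, W, 3) raster, got shape {self.pixels.shape}")
        self.pixels_per_micron = _check_calibration(self.pixels_per_micron)


@dataclass
class BinaryMask:
    """Foreground/background field marking stain-positive (or cellular) pixels."""

    mask: np.ndarray
    pixels_per_micron: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError(f"mask values must be in {{0, 1}}, found {vals[:8]}")
        if arr.ndim != 2:
            raise ValidationError(f"expected a 2D mask, got shape {arr.shape}")
        self.mask = arr.astype(np.uint8)
        self.pixels_per_micron = _check_calibration(self.pixels_per_micron)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


@dataclass
class MultichannelStack:
    """A ``(z, channel, y, x)`` fluorescence stack with channel roles.

    ``channel_roles`` maps channel index to one of ``"nuclei"``,
    ``"signal"`` or ``"other"``; exactly one nuclei and one signal channel
    must be present.
    """

    voxels: np.ndarray
    channel_roles: dict[int, str]
    pixels_per_micron: float
    z_step_um: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 4:
            raise ValidationError(f"expected (z, c, y, x) voxels, got shape {self.voxels.shape}")
        nz, nc = self.voxels.shape[:2]
        if nz < 1:
            raise ValidationError("need at least one z slice")
        roles = dict(self.channel_roles)
        if set(roles) != set(range(nc)):
            raise ValidationError(
                f"channel_roles keys {sorted(roles)} do not match {nc} channels"
            )
        for r in roles.values():
            if r not in CHANNEL_ROLES:
                raise ValidationError(f"unknown channel role {r!r}")
        counts = {r: sum(1 for v in roles.values() if v == r) for r in ("nuclei", "signal")}
        if counts["nuclei"] != 1 or counts["signal"] != 1:
            raise ValidationError(
                "exactly one 'nuclei' and one 'signal' channel are required, "
                f"got {counts}"
            )
        self.channel_roles = roles
        self.pixels_per_micron = _check_calibration(self.pixels_per_micron)
        self.z_step_um = float(self.z_step_um)
        if self.z_step_um <= 0:
            raise ValidationError("z_step_um must be positive")

    def channel_index(self, role: str) -> int:
        for idx, r in self.channel_roles.items():
            if r == role:
                return idx
        raise ValidationError(f"no channel with role {role!r}")

    def channel(self, role: str) -> np.ndarray:
        """Return the (z, y, x) sub-stack for a role."""
        return self.voxels[:, self.channel_index(role)]

    @property
    def n_z(self) -> int:
        return self.voxels.shape[0]


# ---------------------------------------------------------------------------
# unit conversion

def px_to_um(length_px, pixels_per_micron: float):
    """Convert a length in pixels to micrometers (length / calibration)."""
    ppm = _check_calibration(pixels_per_micron)
    length_px = np.asarray(length_px, dtype=np.float64)
    if np.any(length_px < 0):
        raise ValidationError("lengths must be non-negative")
    out = length_px / ppm
    return float(out) if out.ndim == 0 else out


def um_to_px(length_um, pixels_per_micron: float):
    ppm = _check_calibration(pixels_per_micron)
    length_um = np.asarray(length_um, dtype=np.float64)
    if np.any(length_um < 0):
        raise ValidationError("lengths must be non-negative")
    out = length_um * ppm
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# readers / writers

def _load_raster(path: Path) -> np.ndarray:
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            return tifffile.imread(path)
        import imageio.v3 as iio

        return np.asarray(iio.imread(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder-specific failure
        raise OSError(f"could not read image file {path}: {exc}") from exc


def read_image(path, pixels_per_micron: float, source_id: str | None = None):
    """Read a 2D grayscale or RGB raster (TIFF/PNG) with calibration attached.

    Grayscale files return a :class:`CalibratedImage` directly; color files
    return an :class:`RGBImage` that must go through ``rgb_to_gray8``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = _load_raster(path)
    sid = source_id if source_id is not None else path.name
    if arr.ndim == 2:
        return CalibratedImage(arr, pixels_per_micron, source_id=sid)
    if arr.ndim == 3 and arr.shape[2] == 3:
        return RGBImage(arr, pixels_per_micron, source_id=sid)
    raise ImageFormatError(
        f"{path}: expected 2D grayscale or (H, W, 3) RGB, got shape {arr.shape}"
    )


def _sidecar(path: Path, pixels_per_micron: float, source_id: str, extra: dict | None = None):
    meta = {"pixels_per_micron": pixels_per_micron, "source_id": source_id}
    if extra:
        meta.update(extra)
    Path(str(path) + ".calibration.json").write_text(json.dumps(meta, indent=1) + "\n")


def write_image(image: CalibratedImage, path, sidecar: bool = True) -> None:
    """Write a calibrated image as TIFF (or PNG), with a calibration sidecar.

    Integer-valued pixels are written as uint8 when they fit 0-255 and
    uint16 otherwise, so 8-/16-bit rasters round-trip bit-identically;
    genuinely fractional data are written as float64 TIFF.
    """
    path = Path(path)
    px = image.pixels
    if np.all(px == np.round(px)):
        if px.max() <= 255:
            arr = px.astype(np.uint8)
        elif px.max() <= 65535:
            arr = px.astype(np.uint16)
        else:
            arr = px
    else:
        arr = px
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        if arr.dtype == np.float64:
            raise ImageFormatError("non-integer images can only be written as TIFF")
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    if sidecar:
        _sidecar(path, image.pixels_per_micron, image.source_id)


def read_stack(
    path,
    channel_roles: dict[int, str],
    pixels_per_micron: float,
    z_step_um: float,
    page_order: str = "z-major",
    source_id: str | None = None,
) -> MultichannelStack:
    """Read a multi-page TIFF as a (z, channel, y, x) stack.

    The file's page count must be divisible by ``len(channel_roles)``;
    ``page_order`` declares whether pages cycle channels within each slice
    (``"z-major"``, the default) or slices within each channel
    (``"c-major"``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ImageFormatError(f"{path}: expected a stack of 2D pages, got shape {pages.shape}")
    nc = len(channel_roles)
    if nc < 1 or pages.shape[0] % nc != 0:
        raise ImageFormatError(
            f"{path}: page count {pages.shape[0]} is not divisible by {nc} channels"
        )
    nz = pages.shape[0] // nc
    if page_order == "z-major":
        voxels = pages.reshape(nz, nc, *pages.shape[1:])
    elif page_order == "c-major":
        voxels = pages.reshape(nc, nz, *pages.shape[1:]).transpose(1, 0, 2, 3)
    else:
        raise ValidationError(f"unknown page_order {page_order!r}")
    sid = source_id if source_id is not None else path.name
    return MultichannelStack(voxels, channel_roles, pixels_per_micron, z_step_um, source_id=sid)


def write_stack(stack: MultichannelStack, path, sidecar: bool = True) -> None:
    """Write a stack as a z-major multi-page TIFF."""
    path = Path(path)
    nz, nc, h, w = stack.voxels.shape
    pages = stack.voxels.reshape(nz * nc, h, w)
    if np.all(pages == np.round(pages)) and pages.max() <= 65535 and pages.min() >= 0:
        pages = pages.astype(np.uint16 if pages.max() > 255 else np.uint8)
    tifffile.imwrite(path, pages)
    if sidecar:
        _sidecar(
            path,
            stack.pixels_per_micron,
            stack.source_id,
            extra={
                "z_step_um": stack.z_step_um,
                "channel_roles": {str(k): v for k, v in stack.channel_roles.items()},
                "page_order": "z-major",
            },
        )


def write_mask(mask: BinaryMask, path, sidecar: bool = True) -> None:
    """Write a binary mask as an 8-bit TIFF with foreground = 255."""
    path = Path(path)
    tifffile.imwrite(path, (mask.mask * np.uint8(255)))
    if sidecar:
        _sidecar(path, mask.pixels_per_micron, "", extra={"encoding": "0/255"})


def read_mask(path, pixels_per_micron: float) -> BinaryMask:
    """Read a mask stored as 0/255 (or already 0/1) 8-bit TIFF/PNG."""
    arr = _load_raster(Path(path))
    vals = np.unique(arr)
    if np.all(np.isin(vals, (0, 255))):
        arr = (arr > 0).astype(np.uint8)
    return BinaryMask(arr, pixels_per_micron)
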
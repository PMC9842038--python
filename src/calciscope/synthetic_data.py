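"""Seeded synthetic micrographs with ground truth.

Two image classes are generated, mirroring the two kinds of data the
analysis pipeline consumes:

* **Puncta fields** — a Boolean (germ-grain) model of mineral deposits:
  disk centers form a Poisson process of intensity ``lambda`` per square
  micrometer, disk radii are lognormal, and disks are rendered dark on a
  light background with optional Gaussian noise. The model is sampled on
  a torus (disks wrap), which makes it exactly stationary, so the
  closed-form coverage fraction ``1 - exp(-lambda * pi * E[R^2])`` holds
  without edge correction and serves as an analytic oracle.

* **IF scenes** — fluorescence fields with elliptical nuclei in a DAPI
  channel (Gaussian-blurred, sigma = 1 px) and a signal channel composed
  of a diffuse ECM level plus an additive perinuclear halo on the annulus
  within ``halo_width_um`` of each nucleus boundary. The ground truth
  carries the exact cell and ECM means of the noiseless signal under the
  nominal dilation, so ratio recovery can be checked to float precision.

Every generator takes an explicit seed and is bit-for-bit reproducible;
there is no hidden global RNG state. Named presets encode the study
conditions compared in the tests: small-puncta vs. large-nodule
calcification at equal nominal area fraction, a near-blank osteogenic
control, and perinuclear vs. diffuse protein localization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .image_io import BinaryMask, CalibratedImage, MultichannelStack
from .localization import dilate_nuclei, LabelMask

__all__ = [
    "PunctaFieldSpec",
    "IFSceneSpec",
    "GroundTruth",
    "gen_puncta_field",
    "gen_if_scene",
    "preset",
    "PRESET_NAMES",
    "boolean_model_coverage",
]


@dataclass(frozen=True)
class PunctaFieldSpec:
    """Parameters of a Boolean-disk Von Kossa phantom.

    ``intensity_density_per_um2`` is the germ intensity lambda (expected
    disk centers per um^2); radii are lognormal, parameterized by the mean
    and standard deviation of the radius itself (not of log-radius).
    """

    height_px: int = 512
    width_px: int = 512
    intensity_density_per_um2: float = 2e-3
    radius_mean_um: float = 4.0
    radius_sd_um: float = 1.2
    background_gray: int = 220
    foreground_gray: int = 30
    noise_sd: float = 8.0
    pixels_per_micron: float = 2.73
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ValidationError("image dimensions must be positive")
        if not 0 <= self.foreground_gray < self.background_gray <= 255:
            raise ValidationError("need 0 <= foreground_gray < background_gray <= 255 (dark stain)")
        if self.intensity_density_per_um2 < 0 or self.noise_sd < 0 or self.radius_sd_um < 0:
            raise ValidationError("densities, radii and noise must be non-negative")
        if self.radius_mean_um <= 0:
            raise ValidationError("radius_mean_um must be positive")
        if self.pixels_per_micron <= 0:
            raise ValidationError("pixels_per_micron must be positive")

    @property
    def midpoint_threshold(self) -> int:
        """Gray level halfway between puncta and background; recovers the
        true mask exactly on noiseless renders."""
        return (self.background_gray + self.foreground_gray) // 2


@dataclass(frozen=True)
class IFSceneSpec:
    """Parameters of a synthetic immunofluorescence scene.

    Signal-channel composition: ``ecm_level`` everywhere, plus
    ``halo_level`` added on the perinuclear annulus (within
    ``halo_width_um`` of a nucleus boundary); pixels inside nuclei are
    set to ``nucleus_signal_level`` when given, else stay at the ECM
    level. ``dilation_px`` is the nominal dilation at which the ground
    truth evaluates the analytic cell:ECM means.
    """

    height_px: int = 256
    width_px: int = 256
    n_z: int = 4
    n_nuclei: int = 10
    nucleus_axes_um: tuple[float, float] = (3.5, 2.5)
    halo_width_um: float = 1.83
    ecm_level: float = 60.0
    halo_level: float = 120.0
    nucleus_signal_level: Optional[float] = None
    nucleus_dapi_level: float = 200.0
    noise_sd: float = 6.0
    pixels_per_micron: float = 2.73
    z_step_um: float = 1.5
    dilation_px: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.height_px, self.width_px, self.n_z) < 1:
            raise ValidationError("scene dimensions and z count must be positive")
        if self.n_nuclei < 0:
            raise ValidationError("n_nuclei must be >= 0")
        if min(self.nucleus_axes_um) <= 0 or self.halo_width_um <= 0:
            raise ValidationError("nucleus axes and halo width must be positive")
        if min(self.ecm_level, self.halo_level, self.nucleus_dapi_level, self.noise_sd) < 0:
            raise ValidationError("levels and noise must be non-negative")
        if self.pixels_per_micron <= 0 or self.z_step_um <= 0:
            raise ValidationError("calibration and z step must be positive")
        if self.dilation_px < 0:
            raise ValidationError("dilation_px must be >= 0")


@dataclass
class GroundTruth:
    """The generator's exact truth, used as the recovery oracle downstream."""

    true_mask: BinaryMask
    true_radii_um: Optional[list[float]] = None
    true_label_mask: Optional[LabelMask] = None
    true_cell_mean: Optional[float] = None
    true_ecm_mean: Optional[float] = None
    true_ratio: Optional[float] = None


def boolean_model_coverage(spec: PunctaFieldSpec) -> float:
    """Closed-form expected area fraction 1 - exp(-lambda * pi * E[R^2])."""
    er2 = spec.radius_mean_um**2 + spec.radius_sd_um**2
    return 1.0 - np.exp(-spec.intensity_density_per_um2 * np.pi * er2)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # moment matching: mean/sd of R, not of log R
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _render_disks_torus(h: int, w: int, centers: np.ndarray, radii_px: np.ndarray) -> np.ndarray:
    mask = np.zeros((h, w), dtype=bool)
    for (cy, cx), r in zip(centers, radii_px):
        rr = int(np.ceil(r))
        if 2 * rr + 1 >= h or 2 * rr + 1 >= w:
            # disk comparable to the field: evaluate wrapped distance everywhere
            dy = np.abs(np.arange(h) - cy)
            dy = np.minimum(dy, h - dy)
            dx = np.abs(np.arange(w) - cx)
            dx = np.minimum(dx, w - dx)
            mask |= dy[:, None] ** 2 + dx[None, :] ** 2 <= r * r
            continue
        ys = np.arange(int(np.floor(cy)) - rr, int(np.floor(cy)) + rr + 2)
        xs = np.arange(int(np.floor(cx)) - rr, int(np.floor(cx)) + rr + 2)
        sub = (ys - cy)[:, None] ** 2 + ((xs - cx)[None, :]) ** 2 <= r * r
        iy, ix = np.ix_(ys % h, xs % w)
        np.logical_or.at(mask, (np.broadcast_to(iy, sub.shape), np.broadcast_to(ix, sub.shape)), sub)
    return mask


def gen_puncta_field(spec: PunctaFieldSpec) -> tuple[CalibratedImage, GroundTruth]:
    """Sample one Boolean-disk phantom and its exact foreground mask."""
    rng = np.random.default_rng(spec.seed)
    h, w, ppm = spec.height_px, spec.width_px, spec.pixels_per_micron
    area_um2 = (h / ppm) * (w / ppm)
    n = int(rng.poisson(spec.intensity_density_per_um2 * area_um2))
    centers = rng.uniform((0.0, 0.0), (h, w), size=(n, 2)) if n else np.empty((0, 2))
    if n == 0:
        radii_um = np.empty(0)
    elif spec.radius_sd_um == 0:
        radii_um = np.full(n, spec.radius_mean_um)
    else:
        mu, sigma = _lognormal_params(spec.radius_mean_um, spec.radius_sd_um)
        radii_um = rng.lognormal(mu, sigma, size=n)
    mask = _render_disks_torus(h, w, centers, radii_um * ppm)
    img = np.where(mask, float(spec.foreground_gray), float(spec.background_gray))
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    gt = GroundTruth(
        true_mask=BinaryMask(mask.astype(np.uint8), ppm),
        true_radii_um=[float(r) for r in radii_um],
    )
    return CalibratedImage(img, ppm, source_id=f"puncta-seed{spec.seed}"), gt


def _place_ellipses(spec: IFSceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping nucleus placements (cy, cx, theta) via rejection."""
    ppm = spec.pixels_per_micron
    a_px = max(spec.nucleus_axes_um) * ppm  # major semi-axis
    margin = a_px + spec.halo_width_um * ppm + spec.dilation_px + 2
    if 2 * margin >= min(spec.height_px, spec.width_px) and spec.n_nuclei > 0:
        raise ValidationError("scene too small for the requested nucleus geometry")
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    min_sep = 2 * a_px + 2  # circumscribed circles disjoint -> ellipses disjoint
    while len(placed) < spec.n_nuclei:
        if attempts >= 1000 * max(1, spec.n_nuclei):
            raise ValidationError(
                "could not place nuclei without overlap; lower n_nuclei or enlarge the scene"
            )
        attempts += 1
        cy = rng.uniform(margin, spec.height_px - margin)
        cx = rng.uniform(margin, spec.width_px - margin)
        theta = rng.uniform(0.0, np.pi)
        if all(np.hypot(cy - py, cx - px) > min_sep for py, px, _ in placed):
            placed.append((cy, cx, theta))
    return np.asarray(placed).reshape(-1, 3)


def gen_if_scene(spec: IFSceneSpec) -> tuple[MultichannelStack, GroundTruth]:
    """Sample one IF scene: (z, 2, H, W) stack plus exact ground truth.

    Channel 0 is DAPI (role "nuclei"), channel 1 the protein signal. Both
    channels are replicated across z with independent per-slice noise;
    the ground-truth means are taken on the noiseless signal field over
    the true nuclei dilated by ``spec.dilation_px``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w, ppm = spec.height_px, spec.width_px, spec.pixels_per_micron
    placements = _place_ellipses(spec, rng)

    labels = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    a_px = spec.nucleus_axes_um[0] * ppm
    b_px = spec.nucleus_axes_um[1] * ppm
    # labels follow the same row-major centroid convention as segmentation
    placements = placements[np.lexsort((placements[:, 1], placements[:, 0]))]
    for k, (cy, cx, theta) in enumerate(placements, start=1):
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        labels[(u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0] = k
    nuclei = labels > 0

    halo_r = spec.halo_width_um * ppm
    if nuclei.any():
        dist = ndimage.distance_transform_edt(~nuclei)
        annulus = (dist > 0) & (dist <= halo_r)
    else:
        annulus = np.zeros((h, w), dtype=bool)

    signal = np.full((h, w), spec.ecm_level, dtype=np.float64)
    signal[annulus] += spec.halo_level
    if spec.nucleus_signal_level is not None:
        signal[nuclei] = spec.nucleus_signal_level
    dapi = ndimage.gaussian_filter(
        np.where(nuclei, spec.nucleus_dapi_level, 0.0), sigma=1.0
    )

    voxels = np.empty((spec.n_z, 2, h, w))
    for z in range(spec.n_z):
        for c, base in enumerate((dapi, signal)):
            page = base if spec.noise_sd == 0 else base + rng.normal(0, spec.noise_sd, (h, w))
            voxels[z, c] = np.clip(page, 0.0, None)

    stack = MultichannelStack(
        voxels,
        {0: "nuclei", 1: "signal"},
        ppm,
        spec.z_step_um,
        source_id=f"ifscene-seed{spec.seed}",
    )

    label_mask = LabelMask(labels, int(labels.max()), ppm)
    if nuclei.any() and not nuclei.all():
        cellular = dilate_nuclei(label_mask, spec.dilation_px).mask.astype(bool)
        cell_mean = float(signal[cellular].mean())
        ecm_mean = float(signal[~cellular].mean())
        ratio = np.inf if ecm_mean == 0 else cell_mean / ecm_mean
    else:
        cell_mean = ecm_mean = ratio = None
    gt = GroundTruth(
        true_mask=BinaryMask(nuclei.astype(np.uint8), ppm),
        true_label_mask=label_mask,
        true_cell_mean=cell_mean,
        true_ecm_mean=ecm_mean,
        true_ratio=ratio,
    )
    return stack, gt


def _puncta_lambda(target_area_fraction: float, radius_mean: float, radius_sd: float) -> float:
    er2 = radius_mean**2 + radius_sd**2
    return -np.log1p(-target_area_fraction) / (np.pi * er2)


#: Shared nominal coverage of the two calcified presets: the feature-size
#: statistic, not total staining, is what separates them.
_CM_AREA_FRACTION = 0.10

_PRESETS: dict[str, PunctaFieldSpec | IFSceneSpec] = {
    # small, dense micropuncta (female-like calcification)
    "female_CM": PunctaFieldSpec(
        intensity_density_per_um2=_puncta_lambda(_CM_AREA_FRACTION, 4.0, 1.2),
        radius_mean_um=4.0,
        radius_sd_um=1.2,
    ),
    # few large nodules at the same nominal coverage (male-like)
    "male_CM": PunctaFieldSpec(
        intensity_density_per_um2=_puncta_lambda(_CM_AREA_FRACTION, 12.0, 3.5),
        radius_mean_um=12.0,
        radius_sd_um=3.5,
    ),
    # osteogenic-medium control: essentially no positive staining
    "OM_control": PunctaFieldSpec(intensity_density_per_um2=0.0, radius_mean_um=4.0, radius_sd_um=1.2),
    # protein concentrated in a perinuclear halo -> cell:ECM ratio > 1
    "perinuclear_OPN": IFSceneSpec(ecm_level=60.0, halo_level=120.0),
    # diffuse matrix-localized protein -> ratio ~ 1
    "diffuse_OPN": IFSceneSpec(ecm_level=120.0, halo_level=0.0),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, **overrides):
    """Return a documented preset spec, optionally with field overrides
    (``seed`` in particular)."""
    try:
        base = _PRESETS[name]
    except KeyError:
        raise ValidationError(f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None
    return replace(base, **overrides) if overrides else base
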
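"""Radially averaged autocorrelation and the correlation-length statistic.

The correlation length summarizes the characteristic feature size of a
binary micrograph — here, mineral deposits against surrounding tissue. It
is the integral of the radially averaged autocorrelation g(r) of the
binary image from zero lag to the first non-positive crossing, converted
to micrometers: images whose features are large stay correlated out to
larger lags and therefore integrate to a longer correlation length.

Definition. The mask m in {0, 1} is mapped to s = 2m - 1 in {-1, +1}, so
a pair of pixels of the same value contributes +1 and a pair of opposite
values contributes -1. For a lag vector d,

    g(d) = ( <s(x) s(x+d)>_valid  -  s_bar^2 ) / var(s),

where the pair average runs over valid (non-wrapped) pixel pairs only,
s_bar and var(s) are the whole-image mean and variance of s, and the
normalization makes g(0) = 1 exactly. Mean subtraction matters: the raw
+-1 pair average has a large-lag baseline of (2p - 1)^2 at coverage p,
whereas g decays to ~0 so its integral is a well-defined length. The raw
(un-normalized) profile remains available via ``raw_values``.

Boundary handling is aperiodic (zero-padded) with exact per-lag valid-pair
counts, not wrap-around: tissue sections are not periodic. The spectral
path :func:`acf2d` and the direct shifted-overlap path
:func:`acf2d_bruteforce` implement the identical definition; because all
pair sums are integers, the FFT result is rounded to the exact integer
sums and the two agree to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ValidationError
from .image_io import BinaryMask, px_to_um

__all__ = [
    "LagField",
    "RadialACF",
    "CorrLengthResult",
    "acf2d",
    "acf2d_bruteforce",
    "radial_average",
    "correlation_length",
    "correlation_length_from_mask",
    "default_max_lag",
]

#: Masks with fewer foreground pixels than this are flagged low-support.
LOW_SUPPORT_FOREGROUND = 10


@dataclass
class LagField:
    """g on the centered square lag grid |dy|, |dx| <= max_lag.

    ``values[max_lag + dy, max_lag + dx]`` is g(dy, dx); ``counts`` holds
    the number of valid pixel pairs at each lag.
    """

    values: np.ndarray
    counts: np.ndarray
    max_lag: int
    pixels_per_micron: float


@dataclass
class RadialACF:
    """Radially averaged autocorrelation profile in 1-px annuli.

    Bin b collects lag vectors with Euclidean length in [b - 0.5, b + 0.5)
    (bin 0 is the zero lag alone); ``values`` are pair-count-weighted
    means of g, so g(0) = 1 by construction. ``raw_values`` is the same
    binning of the un-normalized +-1 pair average, whose large-lag
    baseline is (2p - 1)^2.
    """

    lags_px: np.ndarray
    lags_um: np.ndarray
    values: np.ndarray
    pair_counts: np.ndarray
    pixels_per_micron: float
    raw_values: np.ndarray | None = None
    low_support: bool = False


@dataclass
class CorrLengthResult:
    """Correlation length and the profile it was integrated from."""

    correlation_length_um: float
    correlation_length_px: float
    integration_upper_lag_px: float
    crossed_zero: bool
    profile: RadialACF
    low_support: bool = False
    source_id: str = ""


def _mask_stats(mask: BinaryMask) -> tuple[np.ndarray, float, float]:
    m = mask.mask
    p = float(m.mean())
    if p == 0.0 or p == 1.0:
        raise ValidationError("undefined autocorrelation: zero variance (constant mask)")
    s = 2.0 * m.astype(np.float64) - 1.0
    sbar = 2.0 * p - 1.0
    var = 1.0 - sbar * sbar  # since s^2 = 1 everywhere
    return s, sbar, var


def _check_max_lag(mask: BinaryMask, max_lag_px: int) -> int:
    max_lag_px = int(max_lag_px)
    h, w = mask.shape
    if max_lag_px < 1 or max_lag_px >= min(h, w):
        raise ValidationError(
            f"max_lag_px must be in [1, {min(h, w) - 1}] for a {h}x{w} mask, got {max_lag_px}"
        )
    return max_lag_px


def default_max_lag(mask: BinaryMask) -> int:
    """Default maximum lag: a quarter of the smaller image dimension."""
    return max(1, min(mask.shape) // 4)


def _valid_pair_counts(h: int, w: int, max_lag: int) -> np.ndarray:
    d = np.arange(-max_lag, max_lag + 1)
    return np.outer(h - np.abs(d), w - np.abs(d))


def acf2d(mask: BinaryMask, max_lag_px: int) -> LagField:
    """Variance-normalized 2D autocorrelation via zero-padded FFT.

    Cross sums are computed spectrally and rounded back to their exact
    integer values; valid-pair counts come from the closed form
    (H - |dy|)(W - |dx|), so the output matches the direct enumeration of
    :func:`acf2d_bruteforce` to machine precision.
    """
    max_lag_px = _check_max_lag(mask, max_lag_px)
    s, sbar, var = _mask_stats(mask)
    h, w = s.shape
    full = signal.correlate(s, s, mode="full", method="fft")
    # products of +-1 pixels sum to integers; remove FFT round-off entirely
    cross = np.rint(full[h - 1 - max_lag_px : h + max_lag_px, w - 1 - max_lag_px : w + max_lag_px])
    counts = _valid_pair_counts(h, w, max_lag_px)
    g = (cross / counts - sbar * sbar) / var
    return LagField(g, counts, max_lag_px, mask.pixels_per_micron)


def acf2d_bruteforce(mask: BinaryMask, max_lag_px: int) -> LagField:
    """Reference implementation: explicit per-lag overlap sums.

    Same definition as :func:`acf2d`, evaluated by looping over every lag
    vector and summing products over the valid overlap region directly.
    Quadratic in the lag range — intended for small masks and testing.
    """
    max_lag_px = _check_max_lag(mask, max_lag_px)
    s, sbar, var = _mask_stats(mask)
    h, w = s.shape
    n = 2 * max_lag_px + 1
    g = np.empty((n, n))
    counts = np.empty((n, n), dtype=np.int64)
    for i, dy in enumerate(range(-max_lag_px, max_lag_px + 1)):
        y0, y1 = max(0, -dy), min(h, h - dy)
        for j, dx in enumerate(range(-max_lag_px, max_lag_px + 1)):
            x0, x1 = max(0, -dx), min(w, w - dx)
            a = s[y0:y1, x0:x1]
            b = s[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
            npairs = a.size
            counts[i, j] = npairs
            g[i, j] = ((a * b).sum() / npairs - sbar * sbar) / var
    return LagField(g, counts, max_lag_px, mask.pixels_per_micron)


def radial_average(
    acf: LagField, pixels_per_micron: float | None = None, *, raw_baseline: float | None = None
) -> RadialACF:
    """Average a lag field over 1-px annuli of Euclidean lag distance.

    Annulus b spans radii [b - 0.5, b + 0.5); each annulus mean weights
    lags by their valid-pair counts. Only complete annuli are kept, i.e.
    bins 0..max_lag (corners of the square lag grid would populate larger
    radii anisotropically and are truncated).
    """
    ppm = pixels_per_micron if pixels_per_micron is not None else acf.pixels_per_micron
    m = acf.max_lag
    d = np.arange(-m, m + 1)
    r = np.hypot(d[:, None], d[None, :])
    bins = np.floor(r + 0.5).astype(np.intp)  # half-up: bin b <-> [b-0.5, b+0.5)
    keep = bins <= m
    wsum = np.bincount(bins[keep], weights=(acf.values * acf.counts)[keep], minlength=m + 1)
    csum = np.bincount(bins[keep], weights=acf.counts[keep].astype(np.float64), minlength=m + 1)
    values = wsum / csum
    lags = np.arange(m + 1, dtype=np.float64)
    return RadialACF(
        lags_px=lags,
        lags_um=lags / ppm,
        values=values,
        pair_counts=csum.astype(np.int64),
        pixels_per_micron=ppm,
        raw_values=None if raw_baseline is None else values * (1.0 - raw_baseline) + raw_baseline,
    )


def correlation_length(profile: RadialACF) -> CorrLengthResult:
    """Integrate g(r) from zero lag to its first non-positive crossing.

    The trapezoidal integral runs from r = 0 to the lag where g first
    reaches zero, locating the crossing by linear interpolation between
    the bracketing bins. A profile that never becomes non-positive is
    integrated to its maximum lag and flagged ``crossed_zero=False`` —
    such values depend on the chosen max lag and deserve scrutiny.
    """
    g = np.asarray(profile.values, dtype=np.float64)
    r = np.asarray(profile.lags_px, dtype=np.float64)
    if g.size < 2:
        raise ValidationError("profile needs at least 2 bins to integrate")
    if abs(g[0] - 1.0) > 1e-9:
        raise ValidationError(f"profile must start at g(0) = 1, got {g[0]!r}")

    nonpos = np.flatnonzero(g[1:] <= 0.0)
    if nonpos.size:
        i = int(nonpos[0]) + 1  # first bin with g <= 0
        if g[i] == 0.0:
            r_cross = r[i]
        else:
            r_cross = r[i - 1] + g[i - 1] * (r[i] - r[i - 1]) / (g[i - 1] - g[i])
        area = float(np.trapezoid(g[:i], r[:i]))
        area += 0.5 * g[i - 1] * (r_cross - r[i - 1])  # triangle to the crossing
        crossed = True
    else:
        r_cross = float(r[-1])
        area = float(np.trapezoid(g, r))
        crossed = False
    return CorrLengthResult(
        correlation_length_um=px_to_um(area, profile.pixels_per_micron),
        correlation_length_px=area,
        integration_upper_lag_px=float(r_cross),
        crossed_zero=crossed,
        profile=profile,
        low_support=profile.low_support,
    )


def correlation_length_from_mask(
    mask: BinaryMask, max_lag_px: int | None = None, *, source_id: str = ""
) -> CorrLengthResult:
    """Full pipeline: 2D autocorrelation -> radial average -> integral."""
    if max_lag_px is None:
        max_lag_px = default_max_lag(mask)
    lag_field = acf2d(mask, max_lag_px)
    p = float(mask.mask.mean())
    profile = radial_average(lag_field, raw_baseline=(2.0 * p - 1.0) ** 2)
    profile.low_support = mask.n_foreground < LOW_SUPPORT_FOREGROUND
    res = correlation_length(profile)
    res.source_id = source_id
    return res
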
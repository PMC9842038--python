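# Methods

## The measurement problem

Calcific aortic valve disease presents differently by sex: with comparable
total mineral content, male-derived tissue tends to form large discrete
nodules where female-derived tissue forms many small punctae. Comparing
conditions therefore needs (a) a total-staining measure, (b) a
feature-size measure that is independent of total staining, and (c) for
protein-localization questions, a measure of whether fluorescence signal
concentrates near cells or in the extracellular matrix. This package
implements all three, plus the synthetic data needed to validate them.

## Von Kossa quantification

Color histology images are converted to 8-bit grayscale as the unweighted
channel mean (R+G+B)/3, rounded half-up — the historical convention of
common measurement software; ITU-R BT.601 luminance weighting is available
behind a flag. Rounding direction is documented because it shifts pixel
counts near the threshold.

Stain-positive pixels are dark, so foreground is intensity ≤ threshold.
One threshold must be shared by every image entering a comparison. Because
the appropriate manual threshold is operator-dependent, the default policy
is Otsu's method computed on the histogram *pooled over all images in the
study* (`auto_threshold`), with a fixed-integer override; the value used
is recorded in every result row. Our Otsu returns the midpoint of a tied
plateau (half-up) rather than an arbitrary plateau edge, so a two-delta
histogram at {0, 255} thresholds at 127.

Integrated density is 255 per foreground pixel (the sum of binary-image
intensities). Because the study figures report a "normalized" density
without defining the normalizer, `normalized_density` is defined here
explicitly as integrated density / ROI pixel count, with the ROI
defaulting to the full image; a tissue-ROI pixel count can be supplied
instead. Area fraction is foreground / ROI count.

## Radial autocorrelation and correlation length

The binary mask `m` is mapped to `s = 2m − 1`, so same-valued pixel pairs
contribute +1 and opposite pairs −1. For lag vector **d**,

    g(d) = ( ⟨s(x) s(x+d)⟩_valid − s̄² ) / Var(s),

with the pair average over valid (non-wrapped) pairs only and s̄, Var(s)
the whole-image mean and variance. Two normalization decisions:

* **Mean subtraction and variance scaling.** The raw ±1 pair average
  levels off at (2p − 1)² for coverage p, so its integral would grow with
  the chosen maximum lag. Subtracting s̄² and dividing by Var(s) gives
  g(0) = 1 exactly and g → ~0 at large lags, making the integral a
  length. The raw profile is still exported (`raw_values`) for
  comparison with tools that skip mean subtraction.
* **Aperiodic boundaries.** Correlation uses zero padding with exact
  per-lag valid-pair counts (H − |dy|)(W − |dx|), not periodic
  wrap-around: tissue sections are not periodic. Valid-pair averaging
  also removes border bias to first order, so a feature's position in
  the field changes L by under 1% (tested).

The spectral path computes cross sums by FFT and rounds them to integers
(sums of ±1 products are integers), so it agrees with the direct
shifted-overlap enumeration bit-for-bit, not merely to FFT round-off. The
brute-force path is retained as the reference semantics and is anchored by
a hand-enumerated 5×5 case with exact rational values (g(0,1) = −29/96).

Radial averaging bins lag vectors by Euclidean length into 1-px annuli
[b − 0.5, b + 0.5) (bin 0 = zero lag alone), weighting by pair counts.
Bins are kept only up to the maximum lag, where annuli are complete;
corner lags of the square grid are truncated rather than averaged
anisotropically.

The correlation length is the trapezoidal integral of g(r) from 0 to the
first non-positive crossing, with the crossing located by linear
interpolation; this operationalizes "the maximum distance at which
features remain segregated from background" and decouples L from the
maximum lag. A profile that never crosses is integrated to the maximum lag
and flagged (`crossed_zero=False`). Defaults: maximum lag = min(image
dimension)/4; masks with < 10 foreground pixels are processed but flagged
low-support. A pure-noise mask (i.i.d. pixels) has g ≈ [1, 0, 0, …] and
hence L ≈ 0.5 px — the floor against which real feature sizes are read.

## Cell:ECM localization

Each two-channel z-stack is median-projected per channel (even slice
counts average the central order statistics), which suppresses
single-slice noise while representing signal through the imaged volume.
Nuclei are segmented from the projected DAPI channel by Otsu threshold,
hole filling, removal of components below `min_area_px` (default 50 px,
debris), and 8-connected labeling ordered by centroid (row-major). The
"cellular" set is the union of nuclei dilated by a disk of radius
`dilation_px` (default 5 px ≈ 1.8 µm at 2.73 px/µm — a small perinuclear
rim); "ECM" is the complement, so the two sets partition the image. The
statistic is mean(signal | cellular) / mean(signal | ECM). It is invariant
under global intensity scaling, which is what makes ratios comparable
across staining batches.

Design choices made where the procedure was genuinely open: no watershed
splitting of touching nuclei (the ratio needs only the union mask);
border-touching nuclei retained (excluding them would bias the cellular
fraction); constant DAPI images return zero nuclei with a warning so blank
controls flow through; a zero ECM mean yields an explicit +inf ratio with
a flag rather than a dropped image. An optional tissue ROI can restrict
the ECM set when slide background should be excluded.

## Synthetic data

**Puncta fields** are a Boolean (germ-grain) model: disk centers are a
Poisson process with intensity λ per µm², radii are lognormal
(parameterized by the mean and SD of the radius itself), disks render at
`foreground_gray` (default 30) on `background_gray` (default 220) with
additive Gaussian noise (σ = 8 gray levels) clipped to 0–255. Sampling is
on a torus (disks wrap), which makes the process exactly stationary so the
closed-form coverage 1 − exp(−λπE[R²]) holds without edge correction and
serves as an analytic oracle for area-fraction recovery.

Preset study conditions (chosen once as realistic for ×20 valve-section
imaging at 2.73 px/µm; 512×512 px ≈ 188 µm fields): `female_CM` — radius
4 ± 1.2 µm micropunctae; `male_CM` — radius 12 ± 3.5 µm nodules;
both at equal nominal coverage 0.10 so that feature size, not total
staining, is the only systematic difference; `OM_control` — λ = 0
(osteogenic medium shows essentially no discrete staining). The equal
coverage deliberately reproduces the dissociation the measurements are
for: integrated density statistically indistinguishable between groups
while correlation length separates them in every replicate.

**IF scenes**: non-overlapping rotated ellipse nuclei (semi-axes
3.5 × 2.5 µm) at `nucleus_dapi_level` 200, Gaussian-blurred (σ = 1 px) in
the DAPI channel; the signal channel is `ecm_level` (60) everywhere plus
an additive `halo_level` (120) on the annulus within `halo_width_um`
(1.83 µm ≈ 5 px) of each nucleus boundary, with an optional absolute level
inside nuclei for constructing scenes of exactly known ratio. Slices are
replicated across z (default 4) with independent per-slice noise (σ = 6;
recovery tests use σ = 20, i.e. DAPI SNR 10). Ground truth carries the
exact label mask and the analytic cell/ECM means of the noiseless signal
at the nominal dilation, so pipeline recovery can be asserted to 1e−10
with truth injected and to a 15% tolerance through full segmentation under
noise.

All generators take one explicit seed and are bit-for-bit reproducible;
there is no hidden global RNG.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: textured tissue background and counterstain,
uneven illumination, stain batch variation, anisotropic or clustered
(non-Poisson) deposit placement, out-of-focus haze and spectral
bleed-through, irregular nuclear morphology and touching nuclei. Results
on real micrographs still depend on acquisition quality and threshold
choice in ways the phantoms cannot probe.

## Statistics

Two-group comparisons default to Welch's unequal-variance t test (the
"when appropriate" criterion for Welch correction is undefined in common
practice, so Welch is used uniformly — it costs little power and never
assumes equal variances). Multi-group comparisons use one-way ANOVA with
Dunnett many-to-one or Tukey HSD post hoc; Dunnett adjusted p-values come
from the multivariate-t distribution of the simultaneous contrasts and are
cross-checked in the tests against an independent 10⁶-draw Monte-Carlo
simulation of the max-|t| null (`dunnett_montecarlo`), agreeing to
±0.005. Two-way ANOVA supports balanced full-factorial designs only;
unbalanced data are rejected loudly rather than silently re-weighted. The
interaction term is the headline statistic, with main effects reported
alongside.

`run_study` orchestrates whole studies from one config: it materializes
all group images first (the uniform threshold must see the pooled
histogram), runs the configured stages per image, aggregates per-image
rows, group summaries and comparisons, and writes CSV/JSON/log outputs.
Per-image analysis failures (e.g. a blank control mask with undefined
autocorrelation) are recorded as explicit NaN gaps, and comparisons drop
gap rows per group. Nothing time- or host-dependent enters the outputs, so
re-running a config reproduces them byte for byte; the echoed config plus
recorded seeds and threshold suffice to rerun. Each image is treated as
the experimental unit by default; per-replicate averaging, where wanted,
should be applied to the per-image table before testing.

## Numerical notes and problem sizes

Thresholds are integers on the 8-bit scale; 8- and 16-bit input rasters
are accepted, with thresholds expressed after conversion. The FFT/brute
force agreement is exact (integer rounding of cross sums); radial-bin
assignment uses half-up rounding so bin edges are deterministic. Test and
verification runs use 48×48 masks for oracle sweeps, 256–512 px fields for
end-to-end experiments, 7 images × 2 groups × 10 replicates for the
dimorphism experiment, 10⁶ draws for the Dunnett reference and 2000
simulations for type-I calibration — sizes at which every check completes
in seconds on one CPU while Monte-Carlo errors stay well inside the
asserted tolerances.

## Known limitations

* No color deconvolution: thresholding operates on grayscale, as in the
  underlying protocol; heavy counterstain could bleed into the dark
  threshold class on real slides.
* The correlation length of a *mixture* of feature sizes is a single
  summary; bimodal deposit populations are not resolved.
* Localization is 2D after projection; no per-cell statistics, 3D
  segmentation, or colocalization coefficients.
* Proprietary microscope formats (CZI/LIF/ND2), stitching and flat-field
  correction are out of scope; inputs are TIFF/PNG with an explicit
  calibration.
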
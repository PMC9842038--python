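# calciscope

Quantitative image analysis of sex-specific aortic valve calcification.

In calcific aortic valve disease, male and female valves can carry similar
total mineral loads while depositing it very differently: male tissue tends
toward large Von Kossa-positive nodules, female tissue toward small, dense
micropunctae. Total staining intensity alone cannot see this. `calciscope`
implements the three image measurements needed to quantify the dimorphism,
for researchers analyzing Von Kossa histology and immunofluorescence of
valvular interstitial cell (VIC) cultures or valve sections:

1. **Von Kossa quantification** — RGB → 8-bit grayscale conversion, one
   threshold applied uniformly across all conditions (fixed, or pooled-Otsu
   via `auto_threshold`), and integrated density / area fraction of the
   binary stain image.
2. **Correlation length** — the feature-size statistic. For a binary mask
   `m`, map `s = 2m − 1 ∈ {−1, +1}` and compute the radially averaged,
   variance-normalized autocorrelation

   ```
   g(r) = ( ⟨ s(x) s(x + r) ⟩ − s̄² ) / Var(s),        g(0) = 1,
   ```

   averaged over all valid (non-wrapped) pixel pairs at Euclidean lag r.
   The correlation length is the trapezoidal integral of g(r) from 0 to its
   first non-positive crossing, converted to micrometers via the
   pixels-per-µm calibration (2.73 px/µm by default). Images with larger
   features stay correlated to larger lags and yield longer L.
3. **Cell:ECM localization ratio** — for two-channel fluorescence z-stacks
   (DAPI + protein of interest, e.g. osteopontin): median z-projection,
   Otsu nuclear segmentation, dilation of nuclei by a small perinuclear
   rim ("cellular" pixels), then the ratio of mean signal over cellular
   pixels to mean signal over all remaining ("ECM") pixels.

A seeded synthetic generator (`calciscope.synthetic_data`) produces
Boolean-disk mineral phantoms and IF scenes with exact ground truth, so
every stage is testable without microscope data; Welch t / ANOVA
(Dunnett, Tukey) comparisons and a config-driven study runner
(`run_study`) sit on top.

## Worked example

```python
import calciscope as cs
from calciscope.synthetic_data import preset, gen_puncta_field

for name in ("female_CM", "male_CM"):
    spec = preset(name, seed=1)              # equal nominal area fraction
    img, truth = gen_puncta_field(spec)      # dark puncta on light tissue
    mask = cs.binarize_dark(img, spec.midpoint_threshold)
    vk = cs.integrated_density(mask)
    L = cs.correlation_length_from_mask(mask)
    print(f"{name}: area fraction {vk.area_fraction:.3f}, "
          f"correlation length {L.correlation_length_um:.1f} um "
          f"(zero crossing at {L.integration_upper_lag_px/2.73:.1f} um)")
```

```
female_CM: area fraction 0.103, correlation length 3.6 um (zero crossing at 10.6 um)
male_CM: area fraction 0.164, correlation length 10.4 um (zero crossing at 23.9 um)
```

The two presets share the same expected coverage, yet the large-nodule
(`male_CM`) field integrates to a ~3× longer correlation length than the
micropuncta (`female_CM`) field: the statistic separates deposition
*pattern* from deposition *amount*. Per-image area fractions fluctuate
around the nominal 0.10 (strongly for the nodule preset, which contains
only a handful of disks per field).

The same pipelines are scriptable from the shell:

```sh
calciscope synth puncta --preset male_CM --n 7 --seed 1 --outdir fixtures/
calciscope vk-quant --images 'fixtures/*[0-9].tif' --threshold auto --out vk.csv
calciscope corrlength --masks 'fixtures/*_mask.tif' --out cl.csv --profiles profiles/
calciscope run --config study.yaml          # full multi-group study
```

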
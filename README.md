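# spindlequant

Quantification of mitotic-spindle fluorescence microscopy for cell
biologists studying chromosome alignment and spindle mechanics (e.g.
kinesin-8/KIF18A perturbations in HeLa or RPE1 cells). The package turns
calibrated multi-channel TIFFs, pole coordinates, and event tables into the
standard per-cell metrics of the field:

- **Chromosome alignment (FWHM).** The kinetochore (CENP-C) intensity
  profile is sampled along the pole-to-pole axis, normalized internally to
  its highest value, and fit with a Gaussian
  `A·exp(−(x−µ)²/2σ²) + c`; the reported alignment metric is
  `FWHM = 2√(2 ln 2)·σ`, alongside the Euclidean spindle length. Smaller
  FWHM = tighter metaphase plate.
- **Spindle geometry.** Sub-pixel pole detection, inter-pole angle to the
  focal plane (dot product of the µm-scaled pole vector with its xy
  projection, from clicked `(x, y, slice)` triplets or automatic
  detection), and spindle rotation as pole-track path length in µm/min.
- **Intensity ratios.** Background-subtracted ROI means; the
  2.5 µm-band/inner ratio around a DNA ROI (EB1/GFP in monopolar cells);
  4.5 µm-band tubulin density; expression levels normalized to a control
  mean; and the 20-px line-scan quartile ratio (outer quarters of the
  normalized position axis over the middle half).
- **Kymograph velocity.** Position × time kymographs from time-lapse
  movies; the bounding-rectangle rule
  `v = width·pixel_size / (height·frame_interval)` plus an automated
  ridge detector that also reports a least-squares slope fit.
- **Mitotic timing.** NEB→anaphase durations, the ≥1 h "never divides"
  arrest rule with explicit censoring, and group comparisons via one-way
  ANOVA + Tukey or Kruskal–Wallis + Dunn (Holm).

Because real microscopy of this kind is rarely deposited, the package
ships a first-class synthetic-fixture generator
(`spindlequant.simulate`): bipolar/monopolar spindle images, rotating
time-lapses, and kymographs, each with a JSON-serializable ground-truth
manifest recording every realized random draw. All estimators are
validated by recovering those manifests (`spindlequant.benchmarks`).

## Worked example

```python
import spindlequant as sq

manifest = sq.BipolarManifest(seed=123, kinetochore_spread_sigma_um=1.5)
img, truth = sq.simulate_bipolar_cell(manifest)

poles = sq.detect_poles(img, "poles")
rec = sq.alignment_metric(img, poles)
print(f"FWHM {rec['fwhm_um']:.2f} um, "
      f"spindle {rec['spindle_length_um']:.2f} um, r2 {rec['r_squared']:.2f}")
```

prints

```
FWHM 3.94 um, spindle 12.00 um, r2 0.80
```

i.e. the kinetochore fluorescence spreads ≈3.9 µm at half maximum along a
12 µm spindle — close to the 2√(2 ln2)·1.5 ≈ 3.53 µm implied by the
simulated 1.5 µm kinetochore spread. The `examples/` directory has one
short script per assay (alignment, geometry/rotation, intensity ratios,
kymograph velocity, mitotic timing, fixture I/O); each builds a small
synthetic input, runs the measurement, and explains the numbers it
prints.

## Validation pipeline

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds every validation cohort from scratch with the given seed and
prints the recovery summaries: mean fitted FWHM per kinetochore-spread
level against `2√(2 ln2)·σ`, band and line-scan ratios against the
generative peripheral:inner densities, automated kymograph velocities
against the simulated run speeds, rotation-assay discrimination of
stationary vs rotating cohorts, and the timing/arrest tabulation. The
same properties are asserted with fixed seeds in
`tests/test_acceptance.py`.

## Conventions

- Pixel indices are 0-based and name pixel centers; physical positions
  are `index × calibration` (µm). Axes are normalized to
  `(channel, time, z, y, x)`.
- Calibration comes from a config (YAML/JSON or dict) and overrides TIFF
  metadata; operations needing a missing field (e.g. `z_step` for the
  pole angle) raise instead of assuming defaults.
- Intensities are treated as unitless non-negative reals; camera bit
  depth is not modelled.

See `docs/methods.md` for the measurement models, the synthetic-data
assumptions, and known limitations.
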
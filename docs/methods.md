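# Methods

This note documents the measurement models, the synthetic-data
assumptions they are validated against, and the numerical choices made
where the design was genuinely open. No empirical claim here goes beyond
what the test suite and `scripts/acceptance.py` themselves compute.

## Coordinate and calibration model

Pixel indices are 0-based and refer to pixel centers; every physical
quantity is `index × calibration` in µm. Arrays are normalized to
`(channel, time, z, y, x)` with absent axes dropped. A `Calibration`
carries `pixel_size_xy` (µm/px, required), `z_step` (µm/slice) and
`frame_interval` (s or min per frame); an operation that needs a missing
field raises rather than assuming a default, because fixed-cell and live
assays are routinely acquired on different optics. z is always converted
to µm with `z_step` before vector math — at a typical 0.25 µm z-step and
~0.11 µm pixels, raw-index angles would be meaningless. Intensities are
unitless non-negative reals; bit depth is not modelled.

## Chromosome-alignment FWHM

The kinetochore channel is sampled by bilinear interpolation along the
segment joining the two spindle poles, at ~1 px spacing, averaged over
`width_px` (default 20) unit-spaced perpendicular offsets. The profile
is normalized internally to its highest value and fit by nonlinear least
squares with `A·exp(−(x−µ)²/2σ²) + c`; the alignment metric is
`FWHM = 2√(2 ln 2)·σ`.

Numerical choices:

- Initialization: `A = max−min`, `µ` = intensity-weighted centroid,
  `σ` = line length/6, `c = min`; bounds keep `µ` on the line and
  `σ ∈ (0, line length]`.
- The offset `c` is bounded **below by 0**: it models a background
  pedestal and intensities are non-negative. Without this bound the fit
  has a broad-σ/negative-floor degeneracy whenever the kinetochore
  distribution fills most of the line (badly misaligned cells), which
  inflates FWHM by tens of percent. A no-offset variant
  (`with_offset=False`) is available.
- Non-convergence or a constant profile returns `converged=False` with a
  diagnostic, never a silent NaN; records with `converged=False` or
  `r² < 0.5` are flagged, not dropped.
- Normalization provably does not change the fitted FWHM (asserted in
  tests); it is kept because it mirrors the field's workflow and tames
  the optimizer's scaling.

The line width default of 20 px matches the width used in the
localization line-scan assay; it is configurable. The FWHM estimator has
a small negative bias (a few percent) on discrete-kinetochore images:
the profile is in effect a kernel-density estimate built from ~50–90
spot contributions, and least squares on a lumpy KDE slightly favors the
densest region. The validation cohorts quantify this: recovery is within
10% of `2√(2 ln2)·σ` at all tested spreads.

## Spindle geometry

- **Pole detection**: brightest well-separated local maxima after light
  smoothing, refined to sub-pixel by the intensity centroid of a 5×5
  window; for z-stacks the xy search runs on the max projection and each
  pole's z is the slice of maximal in-focus intensity at its position.
  Manual `(x, y, slice)` coordinates follow the same downstream math, so
  the clicked-points contract of the original workflow is reproduced
  exactly.
- **Inter-pole angle**: angle between the µm-scaled pole vector and its
  xy projection via the dot product, in [0°, 90°]; invariant to xy
  rotation and to pole relabeling.
- **Rotation displacement**: the **full polyline path length** of one
  pole's track divided by elapsed minutes — *not* net start-to-end
  displacement. The two differ for wobbling spindles; path length
  matches what track-measurement tools report. Tracking links
  frame-to-frame to the nearest local maximum within a 2 µm radius, ties
  broken by brightness, with 5×5 centroid refinement.

## Intensity ratios

Bands of stated physical width are built with a Euclidean distance
transform sampled in µm (isotropic regardless of pixel size), not square
structuring elements; `band = 0 < d ≤ width`. Construction fails loudly
if the band would clip the image border.

- `background_subtracted_mean` may legitimately go negative and is
  reported as-is; it is exactly invariant to adding a constant to the
  image.
- `band_ratio` (EB1/GFP assay) defaults to the pure ratio form with no
  background subtraction (the original protocol does not state any); a
  background ROI can be passed to subtract first.
- `tubulin_density` returns background-subtracted spindle and 4.5 µm-band
  means separately, since each is compared across conditions on its own.
- `linescan_quartile_ratio` rescales positions to [0, 1] and uses exact
  quarters with half-open intervals `[0, 0.25) ∪ (0.75, 1]` vs
  `[0.25, 0.75]`; boundary samples belong to the middle half. The
  protocol's printed "0.74–1"/"0.26–0.75" is read as rounding of exact
  quarters.
- ROIs may be supplied as masks or derived by Otsu thresholding plus
  largest-component selection; the automatic background ROI is the
  darkest 32×32 tile containing no segmented foreground.

All ratios are exactly invariant to multiplying the image by a positive
constant (asserted in tests).

## Kymograph velocity

`build_kymograph` resamples each frame along a segment (bilinear,
averaged over the line width); a segment of length L px yields
`ceil(L)+1` unit-spaced columns. Two estimators:

- **Rectangle rule** (manual emulation): exactly
  `width_px × pixel_size / (height_frames × frame_interval)`.
- **Automated** (`detect_runs`): threshold → connected traces →
  per-frame intensity-weighted ridge column → split where the smoothed
  ridge slope changes sign persistently → per-segment bounding rectangle
  *of the rounded ridge columns* (width = max−min+1 px, height =
  max−min+1 frames) plus the least-squares ridge slope `velocity_fit`.

The ±1 rectangle quantization biases short/slow runs upward by roughly
one pixel per run duration, so `velocity_fit` is the recommended
estimator for automated analysis; on noiseless runs the two agree within
one quantization unit (`pixel_size/duration`), as asserted. Segments
need ≥5 frames; ridge spans under 2 px are flagged stationary rather
than dropped. An empty kymograph yields an empty list, not an error.

## Mitotic timing and statistics

Duration = `(anaphase − NEB) × frame interval` (default cadence 3
min/frame in the live assay). A cell with NEB but no anaphase is
**arrested** ("never divides") if at least 60 min of movie remained
after NEB, and **censored** (excluded from both the duration set and the
arrest denominator) otherwise; arrested + divided + censored always
partitions the cells that entered mitosis. Anaphase without NEB is an
error.

Group comparison is a thin reporting layer over standard routines:
one-way ANOVA with Tukey's HSD (parametric family) or Kruskal–Wallis
with Dunn's all-pairs rank test (nonparametric family, for the skewed
timing and density metrics). Dunn's z uses the standard mean-rank
statistic with tie correction; the multiplicity adjustment is **Holm**
(the protocol is silent on the flavor; Holm dominates Bonferroni at no
cost). Per-replicate means are emitted alongside per-cell values for
superplot-style reporting, but the tests run on per-cell values,
matching the reported analyses. A calibration test holds the parametric
path's null rejection rate ≤7% at nominal 5% over 1000 simulations.

## Synthetic fixtures: what they emulate, and what they don't

All generators are deterministic given `(manifest, generator version)`;
random streams are split per channel from the manifest seed with a fixed
rule so adding a channel never perturbs another channel's draws. Noise
is Poisson shot noise on (signal + background) followed by Gaussian read
noise, both switchable off for exact tests. The PSF is an isotropic 2-D
Gaussian of σ = 1.3 px (~diffraction-limited at 60×-like sampling of
0.1083 µm/px on the default 256×256 field); z-stacks attenuate
structures with an axial Gaussian (σ 0.6 µm) instead of a true 3-D PSF.

- **Bipolar cells**: two pole spots; 92 kinetochore puncta
  (46 chromosomes × 2 sisters, each CENP-C-labeled) whose axial
  positions are Normal(midpoint, spread σ) and whose lateral positions
  follow the projected-disk (semicircle) marginal of a uniform
  metaphase-plate disk of 2 µm radius — the rendered 2-D image is a
  projection, so the plate's in-image lateral density is center-weighted;
  a tubulin ellipse with an optional peripheral shell scaled by
  `peripheral_to_inner_intensity`; a DNA plate.
- **Monopolar cells**: DNA disk of 5 µm radius around the pole (a
  monastrol rosette is ~10 µm across); EB1-like puncta at exact local
  densities — `round(density × area)` puncta uniformly in each region,
  no Poisson count noise — with a 0.15 µm (≈1 PSF σ) placement gap at
  the inner/outer boundary so PSF spill cannot mix the densities, and
  the peripheral annulus extended to cover the line-scan's outer reach.
  With this construction the generative density ratio is the exact
  ground truth for both ratio estimators; the geometry is a modelling
  choice (no quantitative peripheral-microtubule geometry exists to
  copy).
- **Rotation movies**: rigid xy rotation of the pole pair about its
  centroid, one frame/min for 30 min by default; true per-frame
  positions are recorded.
- **Kymographs**: Gaussian ridges (σ 1 px) advancing at constant
  velocity on a noisy background, 10 frames/s and 0.1 µm/px by default;
  `snr` is peak amplitude over noise σ.

Not emulated: 3-D PSFs, photobleaching, chromosome morphology, motor
pausing/diffusion, cell-to-cell size variation. A green recovery test
therefore establishes that the estimator is calibrated for images whose
statistical structure matches these assumptions — discrete puncta,
Gaussian optics, Poisson+read noise — not that it is robust to every
real-world artifact (clumped kinetochores, uneven illumination,
overlapping cells).

### Validation cohort design

- FWHM cohorts use `spindle length = max(12 µm, 6σ)` per spread level so
  the poles always flank the kinetochore distribution — the defining
  geometry of a measurable metaphase cell (and severely misaligned cells
  in kinesin-8 perturbations are indeed longer). On a fixed 12 µm
  spindle the σ = 3 µm level would put kinetochores beyond the poles and
  the pole-to-pole line could not see the full distribution.
- Ratio-recovery accuracy is judged on noise-off **cohort means**
  (12 cells/level): a single fixture's line-scan carries 6–14%
  puncta-sampling noise from the ~90 discrete comets in its outer
  quarters, which is physics, not estimator error. Monotonicity across
  enrichment levels is asserted with noise on (20 cells/level).
- Rotation discrimination applies Gaussian localization jitter
  (σ = 0.2 px) to the recorded true pole tracks — the statistical
  contract of manual point-tracking — rather than re-detecting poles in
  rendered frames; image-based tracking is validated separately. The
  stationary cohort's expected displacement under pure jitter is
  `σ√2·√(π/2)·pixel_size ≈ 0.038 µm/min`, well under the 0.05 µm/min
  acceptance line.

## Known limitations

- The alignment fit is a single Gaussian; strongly bilobed (fully
  congression-failed) distributions are flagged by low `r²` rather than
  modelled with mixtures.
- `detect_runs` segments at persistent slope sign changes and does not
  model pauses or diffusive dwells; runs shorter than 5 frames or 2 px
  are not scored as movement.
- The monopolar fixture's peripheral geometry is a stated model, not a
  measured one; conclusions about absolute peripheral enrichment in real
  cells depend on hand-drawn ROI placement that the package only
  approximates (Otsu + largest component).
- Timing analysis treats event frames as inputs; no automated NEB or
  anaphase detection is attempted.
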
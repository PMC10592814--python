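# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `fociquant`. Percentages are reported on the 0–100 scale
throughout.

## Image model and conventions

A field of view is a stack of 2-D planes indexed `(channel, row, column)`,
row-major and 0-based. Intensities are arbitrary detector counts, converted
to float64 once at read time and never rescaled or clipped by container
construction. Multi-plane TIFF/OME-TIFF is the on-disk format; plane order
defines channel order. Time-lapse series are one field per timepoint with
`timepoint_min` set; each timepoint aggregates independently. Z-stacks are
out of scope — project before analysis.

## Single-cell segmentation

1. **Background subtraction.** The background is estimated as a Gaussian
   blur of the image at a large scale (default 4× the configured cell
   radius) and subtracted, clipping at zero. A constant image maps to zero;
   structures much smaller than the scale are preserved.
2. **Cell mask.** Pixels at or above an intensity threshold (configured, or
   Otsu's threshold on the background-subtracted channel) form the mask;
   connected components outside the cell size bounds (default 80–20000 px)
   are removed.
3. **Watershed splitting.** The channel is blurred at `blur_sigma` (default
   half the cell radius); seeds are the blurred image's regional maxima
   inside the mask with minimum separation equal to the blur sigma (plateau
   maxima merge into one seed; ordering is scan-order deterministic). The
   watershed floods downhill from the seeds within the mask; its separating
   lines are removed from the mask and the remaining connected components
   are relabelled as cells, dropping any outside the size bounds. Border
   cells are kept by default (`exclude_border_cells` inverts this).

Identical inputs and configuration always give identical label maps.

## Foci detection

The foci channel is background-subtracted as above, then **equalized**:
divided pixel-wise by its own Gaussian blur plus a small epsilon
(10⁻⁶ × the image mean, guarding dark regions). Flat regions map to ~1;
spots much smaller than the equalization sigma map to values above 1.

The equalization sigma defaults to **one third of the cell radius** — a
scale between the focus and the cell size. At a full cell-radius sigma,
whole cells (not just spots) exceed the equalized threshold after
background subtraction, because the blur averages the near-zero surround
into the denominator; spots then merge into cell-sized components and are
lost to the size filter. One third of the radius flattens the cell interior
to ~1 while spots several times smaller still stand out.

A pixel is a focus candidate when it passes **both** gates: raw intensity ≥
`foci_raw_threshold` and equalized value ≥ `eq_threshold` (default 1.5).
The default raw threshold is automatic: Otsu's threshold computed over the
foreground (pixels above the global Otsu threshold), floored at the
foreground's robust upper fence (median + 4 × 1.4826 × MAD). The two-stage
Otsu separates bright compact structures from diffuse cytoplasm; the floor
prevents the second Otsu pass from bisecting the cytoplasm distribution in
images that contain no foci at all, which would otherwise flood the
detector with false spots.

Candidate connected components are filtered by size (default 3–50 px) and,
for channels listed in `circularity_channels`, by circularity
4πA/P² ≥ `circularity_threshold` (default 0.5; values are clipped to 1 for
tiny components whose discrete perimeter underestimates). Each focus is
assigned to the cell owning the majority of its pixels (ties break toward
the smaller label; wholly-background foci get no parent).

## Donut positivity

For each focus, the focus mask is dilated with a disk (default radius
2 px); subtracting the focus and **every other focus pixel in the field**
leaves a ring ("donut") guaranteed never to overlap any focus. The donut
ratio is the mean stain intensity over the focus divided by the mean over
the ring — mean rather than integrated intensity, so the statistic asks
"is the focus brighter than its immediate surround?" independently of ring
geometry, and is invariant to global rescaling of the stain channel. A
focus is **positive** when its ratio is *strictly greater than* 1.75. Foci
whose ring is empty after clipping (enclosed or at the border) or has zero
mean are *unscorable*: excluded from both numerator and denominator of
positivity percentages and counted separately.

## Readouts and aggregation

* **Per-cell Pearson correlation** between the configured channel pair over
  each cell's pixels. Cells where either channel has zero variance have an
  undefined correlation; they are excluded from aggregation (never coerced
  to 0) and their count is reported.
* **Percent cells with foci**: a cell is positive when its total foci pixel
  count exceeds `foci_pixel_count_threshold` (default 5 px, rejecting
  single-pixel noise without excluding small genuine foci).
* **Percent foci positive** for a stain channel, over scorable foci.

The hierarchy is: median over cells → one value per image; median over a
well's images → one value per well; mean and sample (ddof = 1) standard
deviation over a condition's wells. Percentages are recounted over the
pooled group at each level (an image's cells, a well's cells/foci). With
fewer than two wells the condition s.d. is undefined and reported as
missing.

## Molecular quantification

* **ΔΔCt.** Per sample, ΔCt = Ct(target) − Ct(reference gene); per gene,
  ΔΔCt = ΔCt − mean(ΔCt over baseline-condition samples); fold = 2^−ΔΔCt,
  with amplification efficiency fixed at 2. Subtracting the *arithmetic*
  mean baseline ΔCt divides by the *geometric* mean of baseline folds, so
  with noise the baseline's arithmetic-mean fold slightly exceeds 1; this
  is the convention, not an error, and is asserted as such in the tests.
  Technical-replicate pre-averaging is available behind a flag, off by
  default.
* **Blot intensities.** normalized = band/loading-control volume;
  relative = normalized / mean(normalized over the reference condition), so
  the reference mean is exactly 1 and all values are invariant to global
  volume rescaling.
* **Peptide ratios.** mean(treated) / mean(untreated) abundances.
* **Group comparison.** One- or two-factor analysis of variance (OLS,
  type-II sums of squares, with interaction for two factors) on the
  fold-change scale, followed by Tukey HSD over all factor-level
  combinations. Degenerate all-constant data short-circuits to adjusted
  p = 1 for every pair.

## Synthetic data generator

Scenes emulate spinning-disk fields: non-overlapping disk cells (radius
~N(12, 1.5²) px, rejection-sampled with bounded retries; infeasible packing
raises), diffuse intracellular signal, perinuclear foci, a linear
background ramp, and Poisson shot noise followed by Gaussian read noise
(both optional). Default intensities: cell base 300 counts over a
background of 20 (+30 gradient), intracellular texture s.d. 60 (smoothed at
sigma 2), spot amplitude 900 — about 3× the diffuse base, so stained foci
sit well above the strict 1.75 donut threshold while unstained foci sit at
~1.

* **Correlation control.** Channel A's texture is a unit-variance smoothed
  field S; channel B's is ρS + √(1−ρ²)·I with I independent, so the
  noiseless diffuse correlation is ρ. Shot noise attenuates the *measured*
  per-cell Pearson by σ²ₜ/(σ²ₜ + Ī) ≈ 0.92 at the default intensities —
  a property of the estimator on photon-limited data, not a pipeline
  defect; correlation-recovery tests therefore run noise-free, and the
  attenuation is the reason measured plate correlations sit slightly below
  their generative targets.
* **Foci.** Each foci-bearing cell draws a zero-truncated Poisson count
  (default mean 3; a mean of 0 degenerates to exactly one focus per cell,
  used by tests that need 1:1 focus/detection correspondence). Spots are
  isotropic Gaussians (s.d. = radius/2) placed near a random pole of the
  cell (perinuclear clustering, default on) or uniformly.
* **Quota realization.** The foci-bearing fraction f and colocalized
  fraction p are realized as *exact per-scene quotas* (round(f·n) cells,
  round(p·N) foci, chosen by seeded permutation) rather than independent
  Bernoulli draws. The stated fraction then *is* the scene's ground truth,
  so recovery tests measure pipeline error rather than generator sampling
  noise.
* **Touching pairs.** For watershed benchmarking, `touching_pairs` places
  cells in overlapping pairs (center separation 0.9×(r₁+r₂), a thin neck)
  and `dome_profile` gives cells a Gaussian intensity profile (s.d. 0.45r,
  bright center) — flat-intensity overlapping disks blur into a unimodal
  dumbbell that no peak-seeded watershed can split, whereas real cells are
  brightest near the nucleus. Pair benchmark scenes use radius-16 cells.
* **Plates.** Per-(well, field) generators derive deterministically from
  the master seed, so a plate regenerates byte-identically. Images are
  written as 16-bit TIFF named `<well>_f<field>.tif` alongside ground-truth
  CSV tables, in exactly the formats the pipeline reads.
* **Ct tables.** Reference-gene Ct draws around 20; target Ct = the
  sample's reference Ct + baseline ΔCt (default 7) − log₂(fold) + Gaussian
  noise, so zero-noise tables invert exactly through the ΔΔCt chain.

What the generator does *not* emulate: optics (PSF, Airyscan), 3-D
structure, cell-shape variability beyond disks, spatially varying noise,
cross-channel bleed-through, or motion between timepoints. Passing recovery
tests on these scenes demonstrates the correctness and calibration of the
analysis chain, not its performance on arbitrary real data.

## Numerical and design choices

* Thresholds chosen automatically are recomputed per image; every parameter
  is overridable in the YAML config and logged per run.
* Watershed seeding tie-breaks (plateaus) follow scan order; all stages are
  deterministic, and repeated plate runs produce byte-identical CSVs
  (full-precision float formatting).
* Pearson and aggregation use direct float64 arithmetic; equality with
  independent oracles is verified to 1e-10 (Pearson) and exactly
  (aggregation) in the test suite.
* With ≥3 channels the colocalization pair must be configured; the first
  two channels are used only as a logged fallback.
* Problem sizes in the recovery tests (20-cell 320×320 scenes, 200 cells or
  foci per condition, 100-seed Monte-Carlo for noisy ΔΔCt) were chosen so
  the whole suite runs in well under a minute of compute per criterion.

## Known limitations

* Merged detections: foci closer than the spot diameter form one connected
  component. In heavily clustered scenes this biases percent-foci-positive
  upward at low colocalized fractions (a merged pair is positive if either
  member is stained); classifier calibration is therefore benchmarked on
  one-focus-per-cell scenes.
* The donut ring uses the raw stain channel; a strong stain gradient within
  a ring radius of a focus can shift ratios.
* Cells touching the border are kept by default; their foci are scored only
  if the clipped ring is non-empty.
* The equalization-based detector assumes roughly isotropic spots well
  below the equalization scale; filamentous structures require the
  circularity filter.
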
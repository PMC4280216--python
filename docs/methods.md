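# Methods

## Shape descriptors

A case is represented by ≥100 segmented nuclei (binary or pre-labeled
raster; 8-connected components; objects under 15 px dropped as debris
and border-touching objects excluded by default, both configurable).
For each nucleus with pixel count *N* at calibration *c* (µm/pixel):

* **Area** A = N·c² (µm²).
* **Perimeter** P = length of the 0.5-level marching-squares contour of
  the Gaussian-smoothed (σ = 1 px) zero-padded mask, times *c* (µm).
  The raw binary iso-contour overestimates a digital circle's perimeter
  by ~5% and naive exposed-edge counting by up to ~27% (it measures the
  staircase, approaching 8r for a disc); the smoothed contour is within
  0.5% of 2πr for discs of radius 20–100 px. The edge-count estimator is
  kept behind `perimeter_method="edge_count"` for sensitivity analysis,
  since the original measurement software may well have used pixel-edge
  counts. Smoothing at σ = 1 px is negligible for nuclei at the working
  scale (hundreds of pixels) but will distort objects close to the
  minimum size; this estimator is not meant for objects under ~30 px.
* **Circular rate** 4πA/P², equal to 1 for a circle and < 1 otherwise.
  With the contour estimator it stays ≤ 1.005 (raster tolerance) for
  convex shapes; the published analysis's values (~0.70–0.89) are far
  from the bound.
* **Aspect ratio** major/minor axis of the moment-equivalent ellipse —
  rotation invariant, unlike a bounding box ("length to width" admits
  several operationalisations; this is the standard one). A mask with a
  zero minor axis raises a `DegenerateShapeError` rather than returning
  infinity.

Per case, area, perimeter, circular rate and aspect ratio are averaged
over nuclei (the per-case aggregation of the two shape ratios is not
specified in the source analysis; the mean is assumed), and
NACV = 100·SD(area)/mean(area) in percent. All SDs in the package use
the sample (n−1) denominator — the convention behind conventional
mean±SD reporting, though the source never states it. Consequence,
stated and tested: NACV is exactly invariant to reordering but not to
duplicating the whole nucleus set (the doubled set's NACV is
√(2(n−1)/(2n−1)) times the original's); the population-SD variant would
be exactly duplication-invariant. Fewer than 100 nuclei per case emits
a warning, not an error.

## Reference cohort fixture

The bundled 88-row cohort CSV transcribes the published per-patient
table verbatim (same row order; one boldfaced level label stored plain).
A SHA-256 checksum test guards the transcription. Recomputed group
moments and every published odds ratio agree with the printed values;
four internal inconsistencies of the published record are preserved
as printed rather than repaired, and documented here:

* the nodal-summary counts derived from the rows (pn-class 1/2b/2c =
  23/21/2; node-count histogram 26/8/7/4/1; level patterns with I = 6,
  II = 28, II+IV = 4 and no V) differ slightly from the published
  summary table (24/20/2; 27/8/7/3/1; I = 5, II = 29, II+IV = 3, V = 1);
* the rows contain one age of 34 whereas the published text reports a
  minimum of 35 (mean 64.4 reproduces either way);
* the published t-test p-values for area and perimeter (0.0226/0.0217)
  are not reproducible from the printed moments or the rows (a pooled or
  Welch t gives p ≈ 2×10⁻⁵); t-test p-values are therefore reported but
  not treated as reference values;
* the published per-group site counts in the text disagree with both
  per-patient rows and the univariate table; the rows are authoritative.

## Risk statistics

Outcome is binary pN status. All logistic models are maximum-likelihood
fits (statsmodels `Logit`); separation and non-convergence raise a
diagnostic `SeparationError`, never a silent estimate.

* **Wald intervals** use z = 1.96 throughout; OR = exp(β·s) for a
  per-increment scaling *s* (defaults: 1 unit; circular rate is reported
  per 0.1 because its observed range spans only ~0.2, making the per-1.0
  OR unreadable).
* **Overall test** per factor is the likelihood-ratio test against the
  intercept-only model (the source does not name its overall test; for a
  single continuous factor LR and Wald agree to the precision printed).
* **Dichotomized ORs** come from the logistic fit on the indicator and
  equal the 2×2 cross-product ratio ad/bc to numerical precision (tested
  to 10⁻⁶, with the Wald SE equal to √(1/a+1/b+1/c+1/d)); a zero cell
  switches to the Haldane–Anscombe (+0.5) closed form, flagged
  `corrected=True`.
* **Min-p cutpoint search** scans midpoints between consecutive distinct
  observed values, keeping ≥ 5 records per arm, scoring each 2×2 with
  the chi-square test without continuity correction (Fisher optional);
  ties break toward the smaller cutoff and the full p-profile is
  returned because the minimised p is optimism-biased (the result says
  so). The source's phrase tying cutoffs to "t-tests" is not executable
  for a binary outcome; the chi-square association test is the closest
  standard reading and reproduces the published partitions exactly:
  the area scan selects 81.4 µm² — the midpoint between the observed
  80.3 and 82.5, i.e. the published "> 80.3" dichotomy with its
  (33,15,9,31) table — and the perimeter scan 32.8 µm ("> 32.7",
  (26,8,16,38)).
* **Model selection** is two-stage: univariate screen at p < 0.1
  (Wald for continuous, LR for categorical factors), then an exhaustive
  best-subset AIC search — 2^k fits, path-independent, unlike stepwise —
  within one family per screened size anchor (area / perimeter), the
  anchor forced in and the other anchor excluded. On the reference
  cohort the screen keeps age, area, perimeter, circular rate and NACV
  (NACV's p = 0.095 clears the stated 0.1 threshold even though the
  source's own candidate list omits it). The perimeter family returns
  exactly the published Model 2 (age + perimeter, AIC 103.5). In the
  area family the AIC winner is age + circular rate + area (AIC 103.86),
  nosing out the published age + area (AIC 103.97) by ΔAIC 0.11 — an
  essentially tied pair; the selected model keeps the adjusted area OR
  at the published 1.05, and `fit_logistic_model(cohort, ["age",
  "mean_nuclear_area"])` reproduces the published Model 1
  parameterisation directly. No multiple-testing correction is applied
  anywhere, matching the source; reports carry a note to that effect.

## Synthetic data

`gen_case_image` draws nucleus areas from a truncated normal at a target
mean and CV (defaults 85 µm², 30% — between the two group means, with
the anisonucleosis level the cohort shows), axis ratios from a truncated
normal (1.44 ± 0.12), uniform orientations, and places each ellipse by
rejection sampling so bounding circles stay disjoint (a bounded retry
budget, then a capacity error). Boundary noise is a low-order (k = 2–4)
Fourier perturbation of the polar radius, peak-normalised to the
requested fraction of the radius (< 0.3). Ground truth is computed from
the continuous pre-raster shape: closed forms for noise-free ellipses
(πab; 4aE(m)), polygon shoelace/arc-length otherwise.

`gen_cohort` draws each group's area, circular rate, NACV, aspect ratio
and age from truncated normals at the published group moments (only
means and SDs are published, so normality is the minimal assumption);
the per-case perimeter is derived as √(4πA/c), so the circularity
identity holds by construction and simulated perimeter group means land
near the published 32.3/37.6 µm without being separately targeted.
Clinical covariates are drawn at the reference cohort's observed
frequencies with no built-in outcome association. What a green test on
simulated cohorts does **not** establish: real joint dependence among
the five parameters (only marginals are emulated), non-normal shapes,
measurement error, or any site/therapy effect on outcome.

## Numerical and design choices

* Candidate-cutoff arms require ≥ 5 records ("arm" = one side of the
  cutoff, not each of the four cells — the looser, more common reading).
* The selection-consistency simulation uses n = 88, one true predictor
  (log-OR 1 per SD) and two null covariates: the expected exact-support
  recovery of the screen+AIC pipeline is ≈ 0.9² ≈ 0.81, so the ≥ 0.80
  band tests the pipeline at its theoretical operating point.
* Seeds: every stochastic test and generator takes one integer seed via
  `numpy.random.default_rng`; fixed seed ⇒ byte-identical outputs.
* CLI manifests record resolved parameters, seed, package version and
  SHA-256 of every output; outputs are never overwritten without
  `--force`.

## Limitations

* No nuclear segmentation: input is masks (the original margins were
  drawn by hand); no stain handling or whole-slide formats.
* The perimeter estimator is tuned for objects ≥ ~30 px across; the
  15 px debris floor should not be lowered when perimeters matter.
* The min-p cutoffs and the screen are reported uncorrected, as in the
  source analysis; they are exploratory statistics, not calibrated
  inference.
* No predictive validation (ROC, cross-validation) and no survival
  modelling — the source analysis performs none.
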
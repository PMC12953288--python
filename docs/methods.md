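# Methods

This note documents the models implemented in `steatodia`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Grading rules

**Histology (S0–S3).** Input is the percentage of hepatocytes containing a
large, nucleus-displacing droplet. The published bands are printed on
integers (S0 < 5; S1 5–33; S2 34–66; S3 > 66), which leaves the intervals
(33, 34) and (66, 67) undefined on the real line. We round half-up to an
integer percent before banding — pathologists report integer estimates — so
33.4 → 33 → S1 and 33.5 → 34 → S2.

**MRI-PDFF.** Cutoffs 5.75 / 15.5 / 21.35 %, each inclusive for the higher
grade (the "≥" in their definition).

**Discordance** is a grade difference of ≥ 1; its direction is the sign of
(PDFF grade − histology grade), its magnitude the absolute difference.

**Distance to closest threshold** uses only the three grade cutoffs, not 0
or 100: both worked cases (3 % → 2.75, 18.25 % → 2.75) are consistent with
that choice, and 0/100 are range limits, not decision boundaries. The
function is piecewise linear with |slope| 1, zero exactly on the cutoffs.

## Droplet size classes and morphometry

Classes are half-open on the area axis: tiny [0, 1) μm², small [1, 100) μm²,
large [100, ∞) μm², forced by the printed "< 1", "1–100", "≥ 100".
Proportionate area of a class is 100 × (summed member area)/(tissue area);
the total is the sum of the three class percentages, so additivity holds to
float precision by construction and is asserted at 1e-9 in tests.

## Segmentation chain

The published description of the study-grade segmentation lives in
supplementary material that is not available, so this module defines its
own documented operator chain and preserves exactly the parts that are
printed: the class thresholds and the proportionate-area metric.

1. **Tissue**: three-class multi-Otsu threshold (background / tissue /
   lumina), keep everything above the lowest cut, fill holes, drop
   components under 64 px. Assumes some slide background is visible in the
   field of view. Idempotent on its own output.
2. **Droplets**: Otsu threshold *within* tissue separates bright lumina
   from tissue texture; a minimum-contrast guard (bright-minus-tissue mean
   difference ≥ 50 on the 8-bit scale) returns an empty result on
   droplet-free tissue instead of thresholding noise. Hole filling,
   8-connected labeling, optional distance-transform watershed (off by
   default; it can oversplit well-separated droplets and is only needed
   when lumina touch), minimum object size 2 px, then a circularity filter.
3. **Shape filter**: circularity 4πA/P² with the Crofton perimeter
   estimator of scikit-image's `regionprops`, clipped at 1. Default
   threshold 0.6 — "ovoid or circular" is qualitative; 0.6 admits ellipses
   down to axis ratio ≈ 0.25 while rejecting elongated stain artifacts
   (a 4×80 px bar scores ≈ 0.2). Configurable. Circularity is computed in
   pixel units and is therefore invariant to the μm calibration; areas
   scale with the square of the pixel size (tested).
4. Droplet ids are assigned in raster-scan order of the bounding box, so
   output is deterministic for a given raster.

At the default calibration of 0.25 μm/pixel (≈ a 40× scan) the 2-px minimum
object is 0.125 μm², below the tiny-class ceiling, so tiny droplets are
countable objects. Whether real DIA measured tiny-droplet signal as
discrete objects or as a diffuse stained fraction is not documented; this
package commits to discrete objects, which is the variant a ground-truth
audit can verify.

## Synthetic section images

Images emulate what the segmenter consumes: dark background (40), textured
tissue (120 ± 12), bright elliptical lumina (235) each with a 1-px darker
rim (80) standing in for the stained droplet membrane. Droplets are placed
by rejection sampling (bounded at 1000 attempts, then a placement error),
non-overlapping by default with a 2-px clearance. Per-class areas are
sampled log-uniformly within ranges margined away from the 1/100 μm² class
bounds (defaults 0.2–0.7, 2–80, 150–800 μm²) so rasterization can never
flip a droplet's class; a guard re-samples in the rare case it would.

Ground-truth area is the **rendered pixel count × pixel area**, not the
continuous sampled area: for a ~10-px tiny droplet the rasterization error
of an ideal ellipse area exceeds the 10 % tolerance the segmenter is held
to, and the pixel count is the actual quantity on the raster. With this
convention the chain recovers areas essentially exactly on clean synthetic
images; the 10 % tolerance in tests leaves room for parameter changes.

Not modelled: the diffuse, faint, sub-resolution appearance of real tiny
droplets (here they are resolvable objects by design, so segmentation can
be audited), stain variability, color, tissue architecture, overlapping
droplet optics, and whole-slide formats. Passing the imaging tests
therefore shows the operator chain is correct and calibrated, not that it
would segment real stained sections.

## Synthetic cohorts

Per patient:

1. **Total area T** ~ Gamma reparametrized to mean 8.7 %, sd 7.2 %,
   truncated by rejection to 0.5–35.8 %. Truncation pulls the realized sd
   to ≈ 6.6 while leaving the mean ≈ 8.7.
2. **Composition.** Expected large-droplet *share* of T follows the
   saturating curve L_max·T²/(T² + h²) with L_max = 0.65, h = 12 % — two
   interpretable parameters that reproduce the observed pattern of a
   concave-up large-LD curve and concave-down tiny+small curve against
   total fat (tested at sign level via quadratic fits). The share gets
   patient-level lognormal scatter (σ = 0.15, clipped at 0.95); the
   *deterministic* curve is exposed as `large_share_curve` and carries the
   monotonicity property, while binned simulated means are tested to be
   increasing. The non-large remainder splits tiny:small via a Beta draw
   with mean 0.90 and sd ≈ 0.07 rather than a fixed 90:10 ratio: a fixed
   split makes tiny and small areas exactly collinear, which would both
   defeat the multivariable model (singular design, and the package's own
   |r| > 0.9 screen would drop one of them) and contradict the independent
   dispersion observed for the small-LD class. The split is exact:
   tiny + small + large ≡ T per row.
3. **PDFF** = T + N(0, σ), truncated at 0. Default
   σ = 7.2·√(1/0.89² − 1) ≈ 3.69 %, the closed-form noise level for which
   corr(PDFF, T) = 0.89 when sd(T) = 7.2 (the realized correlation is
   ≈ 0.88 because truncation shrinks sd(T); within the ±0.05 band the
   calibration is held to).
4. **Histology grade** from a perceived large-droplet hepatocyte fraction
   min(100, k·large_pct·bias) with k = 5.5 %-hepatocytes per %-area and
   pathologist bias 1.5. Both are calibration knobs, not biological
   claims: the literature supports only that pathologists systematically
   overestimate (bias ≥ 1). k ≈ 5.5 puts simulated grade prevalences in a
   plausible range; they are deliberately only rough, and nothing
   quantitative in the package depends on them.
5. **Microvesicular flag**: Bernoulli with logit = −2.3 + 0.35·tiny_pct,
   giving ≈ 40 % prevalence at the default tiny mean and a positive link
   that the univariable screen can detect.
6. **Covariates** from documentation-level marginals: age N(55, 10)
   truncated 18–90; sex Bernoulli(0.59 female); significant fibrosis with
   logit = −1 + 0.05·T; inflammation Bernoulli(0.30); biopsy length
   N(20, 4) mm truncated at 15; portal tracts 6 + Poisson(6).

The cohort generator emulates marginal moments, one correlation structure
and the direction of the composition shift. It does not emulate real
etiology mixtures, biopsy sampling error, inter-pathologist variability, or
MRI segmentation failure modes — statistical conclusions drawn from it
validate the *machinery*, not clinical effect sizes.

## Logistic modelling conventions

Univariable fits are maximum-likelihood logistic regressions; odds ratios
are per unit (per % for areas, per year for age; sex is coded male = 1).
Confidence intervals are Wald, exp(β ± 1.96·SE) — the standard convention
for reported OR tables. Complete or quasi-complete separation raises a
dedicated error (detected via the optimizer plus a |β| > 15 guard) instead
of returning a degenerate table.

The multivariable model enters a candidate iff its univariable p < 0.05,
always adjusts for age and sex (a screen where nothing passes yields the
forced-only model), and then applies a two-part collinearity rule:
(a) a derived-sum variable (total area) is dropped whenever any of its
components is also entered; (b) of any remaining pair with |Pearson
r| > 0.9, the one with the larger univariable p is dropped, iterating from
the worst pair. The sum-rule mirrors the arithmetic identity
total = tiny + small + large; the 0.9 cutoff is this package's
operationalization, since only the removal itself is documented in the
source material. Product interaction terms are supported
(e.g. fibrosis × large-LD).

Planted-effect recovery (acceptance-level test) uses conditional log-odds
of +0.30 (tiny), +0.90 (small), −0.10 (large) per %: magnitudes chosen so
that, under the generator's covariance structure, each predictor's
*marginal* association is detectable at n = 355 (the entry rule screens
marginally) while the conditional signs match the target pattern. Under
this design the marginal large-LD association is positive even though its
conditional effect is negative — the same sign flip between univariable
and multivariable stages that motivates adjusted modelling in the first
place.

Group comparisons expose the test choice ('t', 'mannwhitney', 'chi2',
'fisher') plus an 'auto' default: Welch's t when both groups pass Shapiro
normality at 0.05, Mann–Whitney otherwise; Fisher's exact for binary
variables unless all expected counts are ≥ 5 (then chi-square). Paired
PDFF-vs-DIA comparisons use the Wilcoxon signed-rank test within each
histology-grade stratum: exact null below 25 pairs, normal approximation
with continuity correction above; strata with < 5 pairs are flagged
`too_small`; all-zero-difference strata are reported `degenerate` with
p = 1 by convention (the statistic is undefined there). No multiple-testing
correction is applied anywhere; p-values are reported raw.

The discordance rate carries a 95 % Wilson binomial CI. The sample-size
formula is the precision-based normal approximation
n = ⌈z²_{1−α/2}·p(1−p)/d²⌉; the printed worked value (p = 0.6, d = 0.05,
α = 0.05 → 369) is reproduced by precision and significance level alone,
without a power term entering the formula.

## Pipeline

`run_pipeline` derives every stage seed from the global seed via
`numpy.random.SeedSequence`, so identical configs give byte-identical
artifacts (asserted in tests). Two modes: `tabular` generates the cohort
directly (seconds; the statistics path) and `imaging` additionally renders
a configurable number of validation images (default 3) and audits the DIA
chain against their ground truth — per-patient imaging at cohort scale
would multiply runtime by orders of magnitude without adding statistical
information. Outputs are plain CSV/JSON/YAML plus a markdown report.

## Known limitations

- Tissue delineation needs visible slide background; a wall-to-wall tissue
  field defeats any global threshold.
- The watershed splitter is seed-distance based and will oversplit
  irregular single droplets if enabled on non-touching material.
- Simulated grade prevalences are approximate (see above).
- The generators produce one section per patient and no spatial
  heterogeneity within a section; biopsy sampling variability is a
  documented non-goal.
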
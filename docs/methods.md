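# Methods

This note documents the models, conventions and numerical choices behind
`centamine`, in the order the pipeline runs them.

## Canonical space and synthetic atlas

All quantification happens on a fixed MNI152-like grid: 91 × 109 × 91 voxels,
2 mm isotropic, right–anterior–superior axes, world origin at the grid
centre. Because the anatomical atlas used by clinical DAT pipelines is not
redistributable, the package ships a geometric stand-in with the same
*topology*: per hemisphere, nine basal-ganglia subregions (pre/post caudate;
pre-dorsal, pre-ventral, post-dorsal, post-ventral putamen; accumbens;
globus pallidus; ventral pallidum) modelled as ellipsoids whose centres and
radii are loosely proportioned to basal-ganglia anatomy, inside nested
ellipsoidal tissue shells (grey matter, cerebral white matter, CSF, skull,
soft tissue) — 23 base regions. Report regions (caudate, pre-/post-commissural
putamen, putamen, striatum) are label-set composites, per side or bilateral.

Regions are painted in a fixed order and later paint never overwrites
earlier labels, so base regions are disjoint by construction and atlas
construction is deterministic. The head ellipsoid radii (58, 72, 58 mm plus
8 mm of skull/soft tissue) keep ≥ 25 mm — about 5 σ of the 12 mm-FWHM
kernel — between any content and the grid edge. Exact shapes are
configuration, not science: everything downstream is shape-agnostic.

## Forward model and template bank

A scan is modelled as *paint-and-smooth*: every voxel takes its region's
activity value (white matter ≡ 1 in arbitrary units) and the painted image
is convolved with an isotropic Gaussian, σ = FWHM / (2√(2 ln 2)), default
FWHM 12 mm, emulating SPECT resolution. Smoothing is separable with a
normalized kernel and periodic boundary handling; since the head is ~5 σ
from every edge, wrap-around never touches brain content and the image sum
is conserved to floating-point precision (tested at 10⁻⁶ relative).

The 17 disease-stage templates scale the putamen-left/right and
caudate-left/right healthy values by a fixed fraction table (template 1 all
100%; templates 2–7 single-putamen reductions 75/50/25%; templates 8–17 both
putamina at 0% with graded caudate reductions), all other regions at 100%,
then smooth. `fit_template_model` inverts the forward model for an arbitrary
target: the model is linear in the 23 regional values for fixed FWHM, so the
fit separates into inner nonnegative least squares over the smoothed
regional indicators and an outer bounded 1-D search over FWHM
(bounds 4–20 mm, init 10 mm, tolerance 10⁻³ mm). An all-zero target returns
zero values with the FWHM flagged unidentifiable.

Because painting and smoothing are linear, the post-smoothing mean of any
region is an exact linear function of the painted values
(`region_mean_matrix`). This gives phantom experiments *analytic* ground
truth, used throughout the tests and the image-tier simulator.

## Spatial normalization

A scan is brought into canonical space by a 12-parameter affine (translation
mm, rotation rad, scale, shear; fixed composition
`T · Rz · Ry · Rx · Shear · Scale` about the world origin) registered to a
nonnegative linear combination of the 17 templates, with a weight map that
emphasizes the basal ganglia (weight 10 over the 6 mm-dilated basal-ganglia
union vs 1 elsewhere in the head, softened by a 4 mm-FWHM kernel).

The joint estimation uses variable projection: for any affine the
combination weights have a closed-form weighted least-squares solution, so a
derivative-free Powell search runs over the affine parameters only, on a
deterministic sparse point set (≤ 5000 strided high-weight voxels plus
≤ 4000 strided head voxels). The global intensity scale is absorbed by the
unconstrained weight magnitude; the input scan is normalized to unit mean
(and held in float32) during optimization, making the estimated transform —
and hence all downstream quantification — invariant to global intensity
scaling of the input. Three stages:

1. **coarse** — both images smoothed by a further 8 mm, every third sample
   point, 9 parameters (no shear), trilinear sampling;
2. **bank** — full resolution against the 17-template combination (used when
   refinement is disabled, and to report the combination weights);
3. **refinement** — the template combination is replaced by the subject's own
   paint-and-smooth model: the 23 smoothed regional indicators form an
   intensity basis whose coefficients are solved in closed form at each
   affine trial. The 17 stage templates only span the discrete disease
   stages, so a scan whose regional pattern falls between stages would
   otherwise trade a slightly wrong affine against template mismatch; the
   per-region basis removes that bias (measured on misaligned phantoms it
   reduces worst-case regional SBR error from ~1.6% to ~0.02%).

Final combination weights are recomputed by nonnegative least squares at the
solution. Visual quality control is replaced by automatic flags: translation
> 25 mm, |rotation| > 0.35 rad, scale outside [0.75, 1.30], |shear| > 0.2,
or mean weighted residual above 5% of the unit-mean scan.

### Interpolation

Image resampling uses cubic B-splines. On 12 mm-FWHM-smooth images the
render → register → resample chain with repeated *trilinear* interpolation
blurs regional means enough to bias per-side SBR by several percent (up to
~20% of the small post-commissural putamen SBR); cubic resampling reduces
the same error below 0.2%. Trilinear interpolation is retained for the
sparse cost evaluations inside registration (where only the optimum
location matters and the coarse stage is smoothed anyway — the precise
stages sample a pre-filtered cubic interpolant), and nearest-neighbour is
reserved for label images.

## Quantification

`SBR = mean(target) / mean(reference) − 1` with unweighted voxel means over
masks at canonical resolution and cerebral white matter as reference; no
partial-volume correction. Bilateral values pool the combined left+right
mask (a single mean, robust to unequal mask sizes) rather than averaging
per-side ratios; per-side values are always retained for lowest-side
classification.

## Calibration conventions

* Level-2/3 regressions are ordinary least squares with the *new* tracer as
  response and the reference (or upstream) tracer as predictor — the
  orientation in which the mapping is defined. 95% CIs come from the
  standard OLS slope/intercept errors.
* Head-to-head pairs are matched per subject and region within a 100-day
  window (nearest in time); repeated paired sessions are treated as
  independent points by default, with a one-pair-per-subject switch for
  sensitivity analyses.
* A fitted slope ≤ 0 flags the mapping invalid rather than producing a
  reversed scale.
* CM values are not clipped: values below 0% and above 100% are legal
  outputs (linear extrapolation).
* Anchors are stored at full precision; two-decimal half-up rounding is
  presentation only.

The anchor identity `SBR@CM0 = b` holds exactly by construction, and a
level-3 mapping on self-consistent data equals the composed level-2 map
(both are test-pinned at 10⁻¹⁰).

## Age/sex correction and endpoints

The healthy-control CM of a region is modelled as
`CM = a·age + b·sex + c` (sex 0 = female, 1 = male), and an individual's
value is rescaled to the expectation of a 65-year-old sex-average person:
`CM* = CM × (a·65 + b·0.5 + c) / (a·age + b·sex + c)`. The anchor sex value
0.5 is a definition (the sex-average person), not the cohort's empirical
sex mean. A non-positive predicted denominator is an error (model
extrapolated beyond validity).

Deficit classification takes the lowest-sided putamen CM* against a 75%
threshold with a *strict* less-than at the boundary (documented and
test-pinned; the choice at exact equality is otherwise arbitrary).
Concordance between tracers reports percent agreement and Cohen's κ with
chance agreement from the marginal label frequencies; when both raters are
constant and identical (chance agreement 1), κ is defined as 1.

Annualized change fits one OLS slope per subject and region over the visit
times and averages slopes across subjects; the percentage version divides
the mean slope by the group mean baseline CM (a per-subject-percent variant
is available behind a switch, since the two differ under between-subject
heterogeneity).

## Synthetic cohorts

The simulator emulates the two study designs the calibration needs, with all
defaults taken from the published reference values:

* **healthy cohort** — 227 subjects, ages ~N(62, 11.8²) truncated to 30–85,
  60% male; per-region healthy mean SBR (striatum 1.41, putamen 1.56,
  caudate 1.23, pre-/post-commissural putamen 1.86/1.33); age slope
  −0.24 CM/yr and male offset −14.8 CM imposed on the CM scale and mapped to
  SBR through the scale anchor; multiplicative between-subject (CV 15%),
  per-region (5%) and per-side (2%) variability.
* **head-to-head cohort** — 68 subjects (66 parkinsonian-like), 23 single
  visits, 41 with three annual visits, 4 with four visits over two years:
  162 paired sessions. Disease severity d ~ U(0.3, 0.9) reduces CM with a
  regional gradient (caudate 0.55 < striatum 0.68 < pre-putamen 0.72 <
  putamen 0.78 < post-putamen 0.90 of d lost) and ±15% left/right asymmetry.
  The second tracer is linked per region by the published line
  `SBR_X = a·SBR_ref + b`; its measurement noise per region is pinned
  analytically so the simulated head-to-head R² matches the published
  per-region values (51–83%) — a design calibration, not a fit to any test.
  Longitudinal decline uses the published absolute CM/yr rates.

The image tier renders any tabular session through the forward model.
Subregion specific binding scales with the session's finest report-region CM
(mapped tracers push the subregion SBR through the region's line; the three
non-report subregions use the striatum line as a generic link), each session
gets a random misalignment (|t| ≤ 5 mm/axis, |r| ≤ 0.1 rad/axis, scale
±5%), and the exact post-smoothing SBR every ideal pipeline step would
measure is recorded from the linear forward model as image-tier ground
truth.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: SPECT/PET physics (attenuation, scatter, Poisson
counting noise, reconstruction artefacts), scanner and protocol variability,
nonlinear anatomical variability (the misalignment truth is exactly affine),
partial-volume geometry of real basal ganglia, and any nonlinearity in the
cross-tracer relationship (the generator imposes the linear model the
calibration assumes).

## Problem sizes and numerical tolerances

The test suite exercises image-level operations on a coarse 46 × 55 × 46 /
4 mm grid with identical physical geometry, and runs the full end-to-end
image pipeline (simulate → render → register → quantify → level-2 fit) on
the canonical 2 mm grid with 10 subjects × 2 tracers — sizes chosen to keep
a full run on one CPU within a few minutes while leaving every stage
identical to larger runs. Key tolerances: smoothing mass conservation and
intensity-scale invariance at 10⁻⁶; noise-free calibration algebra at
10⁻¹⁰; end-to-end regional SBR recovery within 1% relative and level-2
coefficient recovery within 5% relative of the forward-model ground truth.

## Known limitations

* The ellipsoid atlas reproduces topology, not anatomy; absolute spill-over
  fractions differ from real basal ganglia.
* Registration QC thresholds are calibrated for phantom data and would need
  re-tuning for clinical noise levels.
* The refinement stage assumes the scan is well described by the
  paint-and-smooth family; strongly non-uniform nonspecific binding would
  reduce its benefit (the bank stages still apply).
* `fit_template_model` estimates a single isotropic FWHM; anisotropic
  resolution is not modelled.
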
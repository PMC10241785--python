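# Methods

## Design and data model

The stimulus space crosses `k` object categories with two vertical display
locations: `2k` single-object conditions and `k(k−1)` ordered pair
conditions (the same two categories at swapped locations are distinct
conditions). The canonical design (`k = 4`) has 8 singles and 12 pairs.
The atomic measurement is one response estimate per
(unit, condition, run) — a GLM beta for a voxel, or a single activation
value per condition for a network unit (run axis absent, treated as
noiseless). Analyses operate on a dense `unit × condition (× run)` array
(`ResponseDataset`); tidy CSV is the interchange format.

## Synthetic population generator

Each unit draws an independent nonnegative mean response for every single
condition from a configurable tuning distribution (default lognormal with
log-mean 0 and log-SD 0.5 — beta responses to preferred objects in
object-selective cortex are predominantly positive, and the slope analysis
degenerates when summed responses cluster at zero). Pair means are formed
from the two constituent means by one of three combination rules:

- `weighted_sum`: pair = c·(A + B); c = 0.5 is perfect averaging, 1 is
  summation. c can be a constant or a per-unit draw (clipped normal),
  which is how slope heterogeneity is produced.
- `weighted_average`: pair = w·A + (1−w)·B with w ∈ [0, 1] (location
  weighting; the target of the weight sweep).
- `max`: winner-take-all.

Run-level measurement noise is additive, homoscedastic Gaussian (SD
`noise_sd`) — the minimal model producing the split-half attenuation the
analyses must tolerate; nothing in the target phenomena constrains a
richer noise model. Optionally each unit also receives a multiplicative
lognormal gain (`unit_gain_sigma`), modelling the large
overall-responsiveness differences between measured units. The gain
matters: with iid condition means only, a profile reliability of ~0.2
implies an across-unit abscissa reliability of ~0.3 and the measured
population slope would attenuate to a third of the generative coefficient,
which is not how measured populations behave; broad unit gains inflate
between-unit signal variance without changing within-unit profile
reliability, reconciling modest profile reliability with robust
across-unit regression.

Every subject is a pure function of `(seed, subject_index)` with a fixed
draw order (gains, tuning, coefficients, noise), so enlarging a cohort
never perturbs existing subjects.

Two presets define the study conditions:

- **brain_like** — 10 subjects × 150 units × 10 runs; coefficients
  Normal(0.55, 0.04) (the IT-like reference slope with a tight spread);
  `unit_gain_sigma = 0.8`; `noise_sd = 3.0`, calibrated (closed form plus a
  one-off simulation check) to a mean split-half reliability ≈ 0.2 across
  all units. Measured: ≈ 0.17 all units, ≈ 0.41 for the selected top 75.
- **layer_like** — run-free 500-unit activation matrices; coefficients
  Normal(0.5, 0.3) clipped at 0 (wide heterogeneity: ≈ 13% of units fall
  in the near interval, the regime in which mean slope and pattern
  averaging dissociate).

What the generator does *not* emulate: correlations between single-object
conditions within a unit (independence is assumed — real tuning is
category-structured), spatial structure across voxels, temporal
autocorrelation of fMRI noise, and condition-dependent noise. Passing
tests therefore certify the analysis machinery and its statistical
behaviour under the stated model, not the physiology of any particular
dataset.

## Analysis conventions

- **Split halves** are odd runs (1, 3, 5, … 1-based) vs even runs, averaged
  within each half.
- **Reliability** is the Pearson correlation of a unit's odd- and even-half
  condition profiles; constant profiles give an undefined reliability and
  are excluded from ranking (a constant profile carries no condition
  information). Top-N selection is stable: ties resolve to the earlier
  unit; retained units keep dataset order.
- **Responsiveness filter**: a unit enters the slope analyses iff its
  responses vary across the single conditions at the top location *and* at
  the bottom location. On noisy data this is almost surely a no-op; for
  activation matrices it removes dead and location-silent units.
- **Slope regressions** include an intercept (the fitted line is affine;
  nothing forces it through the origin, and the intercept is reported so
  users can assess it). The population regression uses one pair-averaged
  point per unit; the 12-points-per-unit variant exists only in the
  per-unit slopes.
- **Z-normalization** standardizes each (condition, run) pattern across
  units with the sample-SD convention (ddof = 1), fixed by tests.
- **Averaged-pair correlation** uses both split directions (pair-odd vs
  averaged-singles-even and vice versa) and averages the two r values
  arithmetically; the one-directional estimator is asymmetric and this is
  its natural symmetrization. Fisher-z averaging is available behind a
  flag, default off.
- **Ratios** are formed per pair and then averaged across pairs;
  the ratio-of-means variant is also reported. Pairs whose actual
  correlation is ≤ 0.05 (configurable) are excluded — a near-zero ceiling
  makes the ratio meaningless — and every exclusion is logged.
- **Weight sweep** grid is 0, 0.1, …, 1.0; ties at the maximum resolve to
  the weight closest to 0.5, then the smaller weight. In split-half mode
  the swept score is the noise-normalized ratio by default (the raw
  averaged-pair correlation is available via `score="averaged_r"`).
- **Near/far**: near is the *closed* interval [0.45, 0.55] (far is defined
  strictly as < 0.45 or > 0.55); undefined slopes are excluded from
  proportions. Proportions are reported per subject and pooled
  (unit-weighted) across subjects.
- **BH correction** uses explicit family ids and an explicit family size
  `m ≥ len(p)` (part of a family may be tested elsewhere); membership is
  declared in config, never inferred.

## A bias worth knowing: z-scoring caps the noise-free ratio below 1

Even with zero noise and exact equal averaging the noise-normalized ratio
is *not* exactly 1. The pair pattern is built in raw response space,
P = (A + B)/2, so it mixes the constituents in proportion to their raw
pattern SDs s_A, s_B; the averaged-singles predictor mixes the z-scored
(unit-SD) patterns equally. Their correlation is the ratio of the
arithmetic to the quadratic mean of (s_A, s_B) — ≤ 1, with equality only
when s_A = s_B. For iid lognormal tuning over 100 units this leaves the
noise-free ratio around 0.995–0.997 rather than 1. Exactness would require
averaging the constituents *before* per-condition normalization, which is
not the stated procedure; the implementation follows the stated order
(normalize → split → average halves → correlate), and the test suite pins
both facts (the ceiling is exactly 1; the averaged correlation is capped
just below it). With realistic noise the ratio's upward inflation (the
averaged-singles pattern carries half the noise variance of a single
pattern) dominates this small downward bias, which is why the one-tailed
below-1 test stays conservative under the averaging null.

## Attenuation

With run noise, the summed-singles regressor is measured with error and
the population slope attenuates by the regressor's reliability. For iid
tuning with variance τ² (no unit gain), the pair-averaged abscissa has
reliability ρ = τ² / (τ² + σ²/n_runs) for any category count, and the
expected measured slope is c·ρ. The test suite verifies this closed form
by Monte Carlo (200 subjects). No attenuation correction is applied —
the slope is reported as measured, matching standard practice; comparisons
against baselines should keep this in mind at low reliability.

## Problem sizes and tolerances

Simulation-based checks use: 200 subjects for the attenuation closed form
(tolerance 0.02 ≈ 3 Monte-Carlo SEs), 100 cohorts for the
reliability-monotonicity and group-difference checks, 1000 ten-subject
cohorts for the type-I calibration of the one-tailed ratio test (bound:
nominal 5% plus two binomial SEs), and 50 subjects per condition for the
slope/pattern dissociation (the wide-coefficient mean slope has
Monte-Carlo SE ≈ 0.01 at that size). Exact claims (noise-free slope
recovery, noiseless pattern correlation under a constant coefficient,
BH equivalence) are asserted at 1e-10–1e-12.

## Known limitations

- OLS slopes are attenuation-prone; no errors-in-variables or total-least-
  squares alternative is provided.
- Per-unit slopes from 12 noisy points are very unreliable at profile
  reliability ≈ 0.2: the measured near-unit fraction in the noisy
  brain-like condition (~0.1) is far below the generative fraction, so
  near/far proportions on noisy data should be interpreted as lower
  bounds unless per-unit slope reliability is high.
- The generator's independence assumptions (conditions within unit, units
  within subject) make its cohorts statistically cleaner than real data.
- Designs with more than two simultaneous locations are rejected rather
  than generalized.
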
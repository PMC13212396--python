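# Methods

## The model

Liver length `Y` (cm) conditional on one covariate `x` (age in years or
height in cm) is modeled as Box–Cox Power Exponential:

```
z = ((y/μ)^ν − 1) / (ν σ)        (ν ≠ 0;  log(y/μ)/σ at ν = 0)
f_Z(z) = τ exp(−|z/c|^τ / 2) / (c 2^(1+1/τ) Γ(1/τ)),   c² = 2^(−2/τ) Γ(1/τ)/Γ(3/τ)
```

`μ > 0` is the median, `σ > 0` the approximate coefficient of variation,
`ν` the skewness-correcting Box–Cox power, `τ > 0` the tail power. Special
cases anchor the implementation: `τ=2, ν=1` is the normal with mean `μ`
and sd `μσ`; `τ=2` with free `ν` is the Box–Cox normal (LMS) family. The
CDF and quantile function are closed forms in the regularized incomplete
gamma function and its inverse, so centiles need no root-finding (a
root-finding oracle backs this in the tests).

Positivity of `y` truncates the standardized variable at `−1/(σν)` (for
`ν>0`). The truncated mass is ignored while below 1e-6 and the law is
renormalized on the truncated support otherwise. Consequences: the median
identity `Q(0.5)=μ` is exact only up to that mass, and `ν` is treated as
exactly 0 below 1e-9 to avoid cancellation in the transform.

## Fitting

`μ`, `σ`, `ν` are modeled through link functions (log, log, identity) as
B-spline expansions; `τ` is a constant with a log link — the constancy
reflects that tail heaviness is poorly identified locally and tends to be
stable across the covariate. Estimation is the cyclic GAMLSS scheme: for
each parameter in turn, the per-observation score `u = ∂ℓ/∂η` and
curvature `w = −∂²ℓ/∂η²` are computed (central differences on the
predictor scale: step 1e-5 for the score; 1e-3 for the curvature, where a
smaller step would lose the second difference to rounding; non-positive
curvatures are floored), and the coefficients solve the penalized weighted
least-squares system

```
(Bᵀ W B + λ DᵀD) β = Bᵀ W (η + u/w)
```

with step-halving whenever the penalized deviance would increase, so
accepted cycles never increase it. `τ` is updated each cycle by bounded
one-dimensional likelihood maximization on `log τ` over `τ ∈ [0.3, 15]`.
Iteration stops when the global deviance changes by less than 1e-4
(default) or after 200 cycles; the `converged` flag reports which.
Initialization: `β_μ` from a ridge-regularized least-squares fit of
`log y`, constant `σ` from the residual spread, `ν = 1`, `τ = 2`.

### Basis and covariate scale

The basis is cubic B-splines on equally spaced knots spanning the training
range — `n_knots` spans give `n_knots + 3` basis functions (default 12
spans → 15 functions) — with a second-order difference penalty. No
extrapolation: evaluation outside the training range raises.

For age models the covariate enters as `age^0.5`. Liver growth is fastest
in infancy (the median gains ~2 cm in year one and ~0.1–0.5 cm/year later);
on the raw scale, equally spaced knots put a single 1.5-year span over the
entire infant rise, which no cubic can follow. The square-root scale is
the usual growth-chart device: it spends knot resolution where the curve
bends. Height models use the identity scale (liver length is close to
linear in height).

### Smoothing policy

Per-parameter smoothing `λ` is expressed relative to the information scale
`tr(BᵀWB)/tr(DᵀD)` so it is comparable across parameters and sample sizes.
Two policies are built in:

* **`"light"` (default)** — a fixed light ridge, `λ_rel = 1e-4`. At the
  sample sizes this package targets (thousands to tens of thousands of
  exams) a 15-function basis is itself the effective smoother (the
  regression-spline regime); the penalty's role is numerical
  regularization, and centile curves track local features — including the
  sharp infant rise — with negligible bias. This is the policy under which
  the recovery experiments below are run.
* **`"gaic"`** — coordinate-wise grid search (7 log-spaced points per
  parameter) minimizing GAIC with penalty k=3. This produces visibly
  smoother curves; on truths with localized curvature it trades a ~0.2 cm
  bias near the curve's bends for lower variance, because the affected
  observations are too few to move a global criterion. It is the right
  choice when the underlying curve is believed to be very smooth (and is
  used in the test suite on a constant-truth cohort).

Fixed numeric `λ` per parameter is also accepted. Centile curves from a
single fitted distribution per `x` cannot cross by construction; the
suite verifies `P5 < P15 < P50 < P85 < P95` on dense grids anyway.

## Screening

Hard bounds first: lengths outside [3, 25] cm are physically implausible
and removed. Then two robust rules run inside age bins (quarterly in year
one, half-yearly in year two, annual after) and 10-cm height bins:

* MAD-z: `z_r = (x − median)/(1.4826·MAD)`; `|z_r| ≥ 3.5` extreme,
  `3 ≤ |z_r| < 3.5` moderate. The 1.4826 factor makes the MAD consistent
  for the normal sd. The rule abstains when MAD = 0.
* Tukey fences: beyond `Q1/Q3 ± 1.5·IQR` moderate, beyond `± 3·IQR`
  extreme, quartiles by linear interpolation of order statistics; abstains
  for strata under 4 values or zero IQR. Fence values themselves are not
  flagged (strict inequalities).

A measurement with one extreme flag, or moderate flags under two distinct
(rule, stratification) pairs, goes to the review report. Because an
automated pipeline has no human reviewer, flagged records are retained in
the modeling set by default (`drop_review` excludes them); the review CSV
is the audit trail. Records without a matched height receive only
age-stratified flags, and two moderate age-only flags still trigger
review.

## Height matching and parsing

Heights attach to an exam when observed within ±90 days (age < 2 y), ±180
days (2–<9 y), ±90 days (9–<14 y), or ±180 days (≥14 y); the windows are
inclusive at the boundary, the closest observation wins and ties break to
the earlier date. Free-text lengths are taken as the first numeric mention:
explicit `cm`/`mm` units are honored (mm divided by 10); a unitless number
is read as cm in [3, 25], as mm in [30, 250], otherwise skipped — the two
ranges are disjoint and consistent with the hard bounds. Duplicate
mentions in one report resolve to the first. Exclusions are patient-level:
one abnormal-transaminase flag or one diagnosis code matching an excluded
ICD-10 prefix removes all of that patient's exams; otherwise all of a
patient's qualifying exams are kept and treated as independent.

## Synthetic cohorts

The generator's truth is anchored to published per-bin centile tables
(packaged as CSV under `liversize/anchors/`): for each bin, `(μ, σ, ν)`
are solved so the BCPE quantiles reproduce the printed P5/P50/P95 at the
bin midpoint exactly (to 1e-6). The solver uses the identity
`e^{ν·ln(q95/q50)} + e^{ν·ln(q5/q50)} = 2` — exact for any symmetric-τ
kernel — for a closed-form start, then polishes against the package's own
quantile function so truncation renormalization is honored. Between
midpoints, `(log μ, log σ, ν)` interpolate linearly; beyond the first/last
midpoint they extend as constants. The anchor skeleton defaults to `τ=2`
(the LMS case) because printed three-quantile rows cannot identify `τ`;
the implied P15/P85 then land within 0.3 cm of the printed ones for most
rows, which bounds how literally the τ=2 truth should be read.

Cohorts drawn from the truth emulate the features the pipeline must
survive, with defaults fixed once: 1% injected gross outliers (uniform on
[0.5, 2.94] ∪ [25.06, 60] cm — stopping 0.06 cm short of the hard bounds
so the 0.1-cm report quantization cannot round an outlier back inside);
half the records rendered as free-text (70% "… cm", 20% "… mm", 10%
unitless, all quantized to 0.1 cm as clinical reports are); height
observations in-window for 70% of age-cohort records (the reported share
of usable heights) and always for height-designed cohorts; 2% of patients
carrying an exclusion criterion; ~10% of patients contributing two exams;
sex drawn with the cohort's male share (2055/4611). The `cohort_like` age
law is a two-component Beta mixture fitted once to the cohort's age
quartiles (1.88/5.91/12.47 y); the recovery experiments use uniform
covariates so every bin is equally informed.

What the generator does not emulate: real report prose (only measurement
snippets), correlated repeat exams (a patient's two exams are independent
draws), measurement-device effects, secular trends, and any τ≠2 or
non-BCPE truth unless configured. Passing recovery tests therefore shows
the pipeline recovers a BCPE truth from realistic record plumbing — not
that the BCPE family is correct for any particular hospital's data; the
residual diagnostics are the tool for that question on real data.

## Diagnostics

Normalized quantile residuals `r_i = Φ⁻¹(F̂(y_i | x_i))` are standard
normal under a correct model. Three checks: residual-vs-covariate LOESS
(local linear, tricube weights over the span-nearest neighbors, span 0.5,
one pass, 100-point grid), normal Q–Q points against `Φ⁻¹((i−0.5)/n)`,
and Freedman–Diaconis histogram counts, plus summary moments and the
Kolmogorov–Smirnov distance. CDF values of exactly 0/1 (possible for
extreme points under truncation) are clamped to [1e-10, 1−1e-10] with a
warning.

## Tables and bands

Tables evaluate fitted centiles at bin midpoints (bins are half-open, so
"3–3.99" is [3, 4) with midpoint 3.5) and report a bin only when it holds
at least `min_n` cases — 100 by default, 50 for sex-stratified tables.
Printed centiles are rounded to 0.1 cm for display; band classification
always uses unrounded values. Bands: `y < P5` abnormal-low, `P5 ≤ y <
P15` low-normal, `P15 ≤ y ≤ P85` normal, `P85 < y ≤ P95` high-normal,
`y > P95` abnormal-high. When both covariates are available the height
table is preferred. Sex-stratified curves are two independent fits on the
subsets, mirroring separately reported tables; no interaction model is
attempted.

## Problem sizes and reproducibility

The recovery experiments simulate n = 20,000 exams per covariate — large
enough that centile estimation error at bin midpoints is a few hundredths
of a cm against a ±0.15 cm assessment band, and small enough that a full
pipeline run fits in seconds. Calibration checks of the generator use one
n = 60,000 cohort so that a 0.01 tolerance on tail frequencies sits at
~3.6 binomial σ. Every random stage takes an explicit seed; identical
seeds give byte-identical cohort CSVs and identical fits. Model JSON
round-trips bit-stably (floats serialized at full precision).

## Known limitations

* Numeric derivatives make each cycle a few likelihood sweeps; analytic
  BCPE derivatives would cut fit time roughly in half.
* A single covariate per model; no joint age-height surface, no random
  effects for repeat exams.
* The `τ=2` anchor skeleton is an assumption, not an estimate; a
  five-quantile τ estimator is a possible extension.
* The review stage replaces human adjudication with an exported report;
  no distribution-aware (model-based) outlier step is included.
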
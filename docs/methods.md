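# Methods notes

## Scope and model

`raschscale` covers the scoring side of Rasch measurement: given item
calibrations (or a finished raw-score → logit table), it produces
conversion tables, affine rescalings into user-defined integer ranges, and
range benchmarks. It does **not** estimate item parameters from response
data and does not assess model fit (unidimensionality, local independence,
DIF, threshold ordering) — calibrations are inputs, assumed to come from a
well-targeted, adequately sized sample using the final instrument.

Person measurement uses the partial credit parameterization with item
location δᵢ plus centered thresholds τₖᵢ (Σₖ τₖᵢ = 0); the category-x
log-weight is −Σ_{k≤x} τₖᵢ + x(β − δᵢ), with weight 1 for x = 0. Users
whose calibrations express thresholds as absolute locations δᵢ + τₖᵢ must
subtract the item location first. A dichotomous item is the special case of
a single zero threshold, reducing exactly to the basic Rasch model.

## Transformation

* `y = m + s·x`, `SE_y = s·SE_x`. The spacing factor `s` and location
  factor `m` are carried at full floating precision; two-decimal values in
  rendered tables are display-only. Rounding `s` to 2 d.p. before
  transforming fails to reproduce published tables and is deliberately not
  done.
* Integer locations round half away from zero. The packaged example
  contains no exact .5 case, so the convention is invisible there, but it
  is fixed for reproducibility.
* Transformed SEs are displayed at 1 decimal to match standard table
  layouts; machine-readable output keeps full precision alongside.
* The logit range used to resolve user transformations includes the
  extrapolated extreme-score rows by default (published scoring tables are
  anchored that way); `include_extremes=False` spans only directly
  measurable scores.
* `wanted_min` defaults to 0 in every mode.

## Benchmarking

Range comparisons use rounded integer endpoint widths (the 0–34 vs 0–24 vs
0–12 style of published narratives), not real-valued widths. Verdicts are
strict: a user width must *exceed* the LMD width to be OVERPRECISE and be
*below* the LSD width to be TOO_COARSE; boundary equality is ACCEPTABLE.
How far beyond the LMD width "considerably" wider begins is a judgment
call the package does not make — the report exposes the signed margins and
leaves the decision to the investigator.

The redefined-LMD search (`adjust_lmd`) keeps L/6 whenever it yields unique
integers, otherwise scans [L/9, L/4] from the bottom on a grid of step
L/360 (fine enough to resolve 0.1-integer spacing changes; configurable)
and returns the smallest passing factor. Because rounding collisions are
interval conditions on `s`, a very tight logit tie can have passing windows
narrower than any practical grid; if nothing in bounds passes, the function
warns and returns L/4.

## Person estimation

Non-extreme raw scores solve the sufficient-statistic equation
E[total | β] = r by safeguarded Newton–Raphson (tolerance 1e−8 on the score
residual, max 100 iterations, logistic-scale start, Brent fallback inside a
monotone bracket); SE = 1/√I with I the total score variance, which equals
dE/dβ. Category probabilities are stabilized by subtracting the maximum
exponent before exponentiation, so |β| up to several hundred logits is
safe.

Raw scores 0 and L have infinite ML locations. They are re-estimated at a
pseudo-score ε (default 0.3, configurable, 0 < ε < 1) inside the range —
0 → ε, L → L − ε — and flagged `is_extreme`. Estimation software differs
here (one widely used program derives extreme locations from a geometric
mean over the most extreme item estimates, with pseudo-scores such as
0.185/23.795); exposing ε makes the convention explicit without claiming
equivalence to any particular program, and extrapolated rows should be read
as extrapolations, not measurements.

## Synthetic data and recovery

The generator's default configuration emulates an 8-item instrument with
four ordered categories per item (L = 24) given to a general-population
sample: item locations evenly spaced over a 2-logit span, per-item centered
thresholds evenly spaced over a 2-logit span, person abilities
N(0, 1.5²) — a conventional shape for a short, reasonably targeted
patient-reported outcome scale. Instruments are deterministic functions of
the configuration; all sampling randomness flows from the single seed.

`recovery_experiment` simulates responses, sums them, re-estimates each
observed raw score once, and reports bias, RMSE and the fraction of
non-extreme persons whose true β lies within β̂ ± 1.96·SE. Extreme scorers
are excluded from these statistics because their locations are
extrapolations. The acceptance-level run uses 1000 persons, where binomial
noise on a 95% coverage proportion is about ±0.7 percentage points.

What the simulator does *not* emulate: misfit of any kind (DIF,
multidimensionality, disordered thresholds), missing responses, or
non-normal ability distributions (the population model is configurable but
normal by default). Passing recovery tests therefore show the estimator and
transformation pipeline are correct under the model, not that any
particular real data set fits the model.

## The packaged ESS example

The packaged fixture is the published Epworth Sleepiness Scale calibration
(25 raw scores, logits −4.323 … 4.265) together with its six published
transformations (0–24, 0–10, 0–100, LMD, SEM, LSD; integer locations and
1-d.p. SEs). The published table prints logit SEs at 2 d.p. but was
generated from higher-precision values: a handful of 1-d.p. transformed SE
cells are inconsistent with multiplying the 2-d.p. column directly. The
fixture's SE column therefore carries working values reconstructed by
intersecting, for each raw score, the value intervals implied by all seven
printed renderings (the 2-d.p. SE and the six 1-d.p. transformed SEs) and
taking the midpoint at 4 d.p. This reconstruction reproduces every printed
cell exactly and is the package's own choice of canonical fixture; the
original 2-d.p. values are recoverable by rounding.

## Known limitations

* Item calibration, fit assessment and DIF analysis are out of scope.
* Wald intervals β̂ ± 1.96·SE undercover in very short scales (small L),
  where the normal approximation to the score distribution is rough.
* The extreme-score ε is a convention, not an estimate; downstream ranges
  (and hence user spacing factors) depend on it through the extrapolated
  endpoints.
* `adjust_lmd` resolves uniqueness on a finite grid; pathological near-ties
  may be reported as not achievable even though a measure-zero set of
  passing factors exists.
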
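# Methods

This note documents the models, conventions and numerical choices behind
`poa_emergence`, and what the synthetic-data tests do and do not show
about real field data.

## Thermal time

Degree days accumulate daily from an anchor date as
`max(0, base − T_d)` ("below base", cooling degree days, the default) or
`max(0, T_d − base)` ("above base", growing degree days). Defaults:
base 21 °C, anchor June 21 (a fixed northern-hemisphere summer-solstice
date; the astronomical solstice falls on June 20 in some years, and the
anchor is configurable wherever it is accepted). The below-base default
reflects the autumn-emergence biology: only a handful of degree days
accumulate across a warm mid-South summer, and the clock starts running
as soils cool in September.

Conventions chosen deliberately:

* the anchor day itself is the first accumulation day (closed start);
* daily means from sub-daily records default to the arithmetic mean of
  all readings (`mean_of_readings`); the `(min+max)/2` midpoint is
  offered for stations logging only extremes. Which convention a given
  historical dataset used is often unknowable, hence the flag;
* a missing calendar day or missing temperature inside the accumulation
  range is a hard error. Silent interpolation would drift degree-day
  totals by unbounded amounts and is never done;
* `date_at_thermal_time` returns the *first* date whose cumulative total
  reaches the target (first-crossing rule), so plateaus resolve
  deterministically.

## Emergence curves

Counts are destructive (each seedling recorded then removed), so records
are per-interval new-seedling counts. Curves accumulate counts over
sorted observation dates, normalize by the yearly total (final point is
exactly 1), and annotate each date with its cumulative degree days.
Plots within a site are pooled by summation by default; per-plot curves
are available for dispersion work. Seasons are calendar years: autumn
emergence does not straddle January 1 here.

The early-season subset keeps points with cumulative fraction ≤ the
ceiling (default 0.5) and, when no kept point sits exactly at the
ceiling, the first point beyond it, so fits always see the crossing.

Weekly shares use ISO-8601 week-of-year by default (a `simple`
day-of-year//7+1 convention is available). A count observed after a
biweekly gap (> 9 days since the previous visit) covers two weeks and is
split evenly between the observation week and the week seven days
earlier. This maps mixed weekly/biweekly schedules onto a single weekly
axis at the cost of an even-split approximation within the fortnight.

## Models and fitting

Two families map thermal time `x` to cumulative emergence fraction `y`:

| family | form | parameters |
|---|---|---|
| Gompertz (early season) | `a·exp(−b·exp(−c·x))` | asymptote `a ∈ (0, 1.5]`, displacement `b > 0`, rate `c > 0` |
| saturating exponential (full season) | `−a + b·(1 − exp(−c·x))` | offset `−a` at 0, asymptote `−a + b ∈ (0, 1.5]`, rate `c > 0` |

Emergence is a fraction in [0, 1] internally; percent only at reporting
boundaries. The saturating form is stated multiplicatively
(`b` multiplies the bracket); the additive variant seen in some
transcriptions gives values near 1.9 at large thermal time and is
treated as a typographical corruption of the same curve.

Fitting is plain (unweighted) least squares on the cumulative points via
`scipy.optimize.least_squares` (trust-region reflective, bounded).
Cumulative points are serially dependent; like the usual practice with
these curves, the fit ignores that autocorrelation — parameter point
estimates are consistent, but the reported covariance understates
uncertainty. When no initial guess is supplied, a deterministic
multi-start grid is used — for the Gompertz: `a ∈ {0.5, 1.0}`,
`b = −ln(y₁/a)` clipped to [1e−3, 50], `c ∈ {0.001, 0.01, 0.1}`; for the
saturating form `a₀ = 0`, `b ∈ {0.5, 1.0}`, same `c` grid — and the
lowest-cost convergent start wins, in fixed order, so fits are
reproducible. Unidentifiable inputs (constant response, identical
thermal times, fewer than 4 points) raise before any optimizer runs;
total non-convergence raises with the best attempt attached rather than
returning silently.

Benchmark inversion solves `y(x) = q` with Brent's method on [0, hi],
doubling `hi` until the target is bracketed; monotonicity guarantees a
unique root, found to |y − q| < 1e−10. Targets outside the open interval
(value at 0, asymptote) are rejected with the attainable range named.

## Fit statistics and screening

R² = 1 − SS_res/SS_tot (about the observed mean; may be negative, and
undefined for constant observations), MAE = mean |y − ŷ|, and
MSLE = mean (log1p y − log1p ŷ)² (log1p is the standard definition;
values must exceed −1). Screening ranks predictors by |Pearson r|
against the response — per-interval emergence increments by default,
cumulative behind a flag. Zero-variance predictors are reported as
undefined and ranked last. No p-values and no multiple-testing
correction: the screen is exploratory, as in the practice it mirrors.

## Windows and edaphic summaries

The peak window slides a `weeks × 7`-day span across observation dates
(not all calendar days — matching the weekly sampling design) and keeps
the span with the largest emerged share, earliest start on ties; a
brute-force scan over all starts is the test oracle. Rapid-change weeks
aggregate weekly shares across site-years (25/50/75 percentiles, min,
max per week; absent weeks count as zero for that site-year) and report
the contiguous span maximizing the summed median share.

Rolling edaphic series are *trailing* means (window ending at each
date), 7 days by default; summaries over a date range report the mean of
each site-year's rolling values and the across-site-year population
standard deviation, labelled generically "spread". Day/night air means
split readings at fixed clock hours (07:00–19:00 local); solar-geometry
splitting is out of scope, and daily-only data are rejected rather than
guessed at.

## Synthetic data

The generator emulates a temperate mid-South study season:

| parameter | default | rationale |
|---|---|---|
| annual mean air temp | 15 °C | regional climatology (≈ 4 °C January, ≈ 26 °C July) |
| annual amplitude | 11 °C | same |
| warmest day | DOY 201 (late July) | same |
| daily noise sd | 2 °C | day-to-day synoptic variability |
| soil temperature | 3-day moving average of air, lagged 2 days | placeholder thermal inertia, parameterized |
| rainfall | Bernoulli(0.30) wet days × exponential, mean 9 mm | episodic rainfall at a realistic annual total |
| seedbank | 10,000 seeds/site, 4 plots | dense natural infestation |
| cadence | weekly Jan–May, biweekly Jun–Aug, weekly Sep–Dec | the monitored-study schedule |
| true model | Gompertz (0.485, 12.141, 0.081) | published early-season parameter set |

Counts per plot and interval are Binomial(seedbank/plots, ΔF) with ΔF
the true curve's increment — the simplest observation model consistent
with exhaustive destructive counting (equivalently multinomial over the
season). Rainfall is generated but does not drive emergence: the truth
is thermal-time-only, mirroring the fact that moisture effects are
discussed in this literature but not modelled; a moisture-modulation
hook exists and defaults off. All randomness flows from one seed through
spawned per-site streams; runs are fully reproducible.

What passing synthetic tests show: the pipeline's arithmetic,
conventions and estimator are correct against known truth at realistic
noise levels. What they do not show: robustness to the things real field
data add — model misspecification (no real seedbank follows a Gompertz
exactly), year-to-year shifts in the emergence–thermal-time relation,
sensor bias, spatial correlation between plots, and moisture-driven
departures. Parameter "recovery" here is recovery of the generator's own
curve, not validation of the curve family against nature.

A note on precision at the default design: with a 10,000-seed seedbank
and weekly visits, the binomial information in one season bounds the
displacement parameter `b` to a relative standard error of about 3 %
(the Cramér–Rao bound for the multinomial observation model; the
unweighted least-squares estimator is within ~10 % of that bound). Joint
sub-5 % recovery of all three parameters therefore succeeds in roughly
nine replicates out of ten, not essentially always; halving that error
requires roughly a fourfold larger seedbank or denser sampling through
the early rise.

## Pipeline

The end-to-end driver validates its config (file inputs XOR simulation),
chains the stages, and emits a JSON report validated against a published
schema (`schemas/run_report.schema.json`, generated from the report's
pydantic model) plus CSV sidecars; figures only behind a `plot` flag.
Reports contain no timestamps and are serialized with sorted keys, so a
fixed seed reproduces a byte-identical file. Stage failures propagate
with the stage name attached; logs carry stage timings and record
counts.

## Known limitations

* Daily-resolution degree days only; single-sine and double-triangle
  sub-daily methods are not implemented.
* One reconciled weather series per site is the contract; multi-source
  meteorological fusion is upstream of this package.
* The two curve families are fixed; logistic/Weibull/hydrothermal-time
  alternatives would slot into the same fit/invert interface but are not
  provided.
* Benchmark inversion propagates no parameter uncertainty; it inverts
  the point fit.
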
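# Methods

## Data model and rate definition

The empirical unit is the stage-duration table: per (stage, constant
temperature), the mean development duration `D` (days) of the surviving
cohort, its SE, cohort size `n`, and survival. Developmental rate is defined
as the reciprocal of the per-temperature **mean** duration, `r = 1/D`, not
the mean of individual reciprocals. The two differ by Jensen's inequality;
the reciprocal-of-the-mean convention is the one under which the packaged
table's published regressions are reproducible, and it is what field
practice uses when only summary tables survive.

Temperatures are Celsius at every interface. Kelvin conversion (adding
273.15) happens only inside the SSI evaluations.

## Exclusion rules for the linear range

Linear degree-day theory holds only on the rising, approximately straight
part of the thermal response. `select_linear_range` drops:

* temperatures with survival below `min_survival` (default 0.05 — a cohort
  with a few percent survival yields durations dominated by selection
  effects), and
* when `exclude_above_peak` is on (the default for linear fits),
  temperatures strictly above the temperature of the maximum observed rate;
  beyond the peak the response bends down and a straight line is biased.

Ties at the peak keep the cooler temperature. An explicit
`include_temperatures` set overrides both rules, so any published inclusion
choice is expressible. Nonlinear and SSI fits use the full curvilinear range
(above-peak exclusion off); for the packaged table that is 20–32 °C, and the
linear fits use 20–30 °C.

## Linear models

Both linear fits are unweighted OLS (statsmodels); weighting by cohort size
is available but off by default, because the canonical published tables this
package reproduces are fit to per-temperature means. `R²_adj` uses
`1 − (1−R²)(N−1)/(N−2)` (one predictor); the reported `P` is the two-sided
t-test p-value of the slope. A non-positive slope leaves the threshold
undefined; the result object is returned with `ok=False` and NaN derived
fields rather than raising, so a batch over all stages completes and the
report flags the degenerate stage.

SE formulas for the derived quantities (delta method):
`SE(T_min) = (r̄/b)·sqrt(S²/(N r̄²) + SE_b²/b²)` and `SE(K) = SE_b/b²`, with
`S²` the residual mean square, `r̄` the mean observed rate. For the
Ikemoto–Takai regression, `T_min` and `K` are the slope and intercept
themselves, so their SEs are the regression's own coefficient SEs.

## Nonlinear thermal performance curves

Analytis and Brière-2 are clamped to zero outside `[T_min, T_max]`; the
Brière exponent `1/d` is applied only to the nonnegative base `(T_max − T)`,
and negative fitted `d` (which arises in published egg fits, where the term
degenerates towards `(T_max − T)^0`) is accepted in evaluation. Lactin-2 is
a raw formula value that may be negative; its thermal limits are the zero
crossings of the curve, with `T_max` conventionally reported as the fitted
parameter.

Fitting minimises squared rate residuals with `scipy.optimize.least_squares`
(trust-region reflective, bounded), restarted from 64 Latin-hypercube points
within the bounds (scale parameters sampled log-uniformly). The default seed
is fixed (20170228) and results are deterministic given the seed; across
seeds the immature-stage fits agree to ~1e-6. Default bounds are
biologically plausible boxes for temperate insects — `T_min ∈ [0, 20]`,
`T_max ∈ [30, 45]` °C, shape exponents in (0, 5] — wide enough to bracket
published Lepidoptera estimates. Parameters that land on a bound are listed
in `at_bounds`; with five rate points and four or five parameters, boundary
solutions are common and should be read as "the data do not constrain this
parameter", not as a precise estimate.

`T_fast` is the argmax of the fitted curve, located by bounded scalar
minimisation to 1e-6 °C; for Analytis the closed form
`(n·T_max + m·T_min)/(n+m)` is used (the numeric argmax agrees to <1e-4 °C,
property-tested). Lactin-2's `T_min` is the lower zero crossing below
`T_fast`, found by scanning for a sign change and Brent root refinement; if
the curve never crosses zero there the result is NaN with a provenance flag.

`R²_adj` for the nonlinear fits uses `1 − (1−R²)(N−1)/(N−k)` with `k` the
number of fitted parameters; it is NaN when `N ≤ k` (e.g. five-parameter
Analytis on five points), which is reported rather than hidden.

## SSI model and the intrinsic optimum

The SSI rate is an Eyring-type numerator (activation enthalpy `dH_A`)
divided by `1 + exp[(dH_L/R)(1/T_L − 1/T)] + exp[(dH_H/R)(1/T_H − 1/T)]`,
the inverse probability that the rate-controlling enzyme is active;
`R = 1.987 cal/deg/mol` is fixed. `T_opt` is **defined** as the argmax of
that probability and computed in closed form from
`1/T_opt = [dH_H/T_H − dH_L/T_L − R·ln(−dH_L/dH_H)] / (dH_H − dH_L)`
(Kelvin), so it is never a free parameter: the enzyme-probability argmax and
the reported `T_opt` coincide by construction, and the effective free
parameters are six, not seven.

The fit is a nested deterministic search: exhaustive 0.5 °C grid over
`(T_L, T_H)`, inner bounded least squares over
`(rho_phi, dH_A, dH_L, dH_H)`, then a local polish of the best candidate
over all six. This design was chosen for determinism and desk-scale runtime
(seconds); no randomness enters, though a seed is accepted for interface
symmetry with the other fitters.

With five rate points the SSI fit is under-determined: enthalpies and
half-inactivation temperatures trade off along near-flat valleys, and an
unconstrained search drifts to activation enthalpies well below anything
reported for insect development. The default bounds therefore encode the
standard biological priors: `dH_A ∈ [10000, 30000] cal/mol` (published
insect values cluster at 12–20 kcal/mol), `dH_L ∈ [−200000, −10000]`,
`dH_H ∈ [10000, 1e6] cal/mol`, and a `(T_L, T_H)` grid of [8, 18] × [30, 40]
°C — half-inactivation in the cold must sit below the coldest temperature at
which cohorts thrive. Conclusions should rest on the fitted **curve** and
the derived temperatures (`T_opt`, `T_fast`), which are stable under these
priors, never on individual enthalpy point values; a noiseless nine-point
cohort recovers the generating curve to machine precision, but the raw
parameter vector is not identifiable from five points. All bounds are
user-overridable through `SSIFitConfig`.

The goodness-of-fit statistic `X²` is the Pearson form
`sum((obs − fit)²/fit)`; `R²_adj` uses `k = 7`.

## Synthetic cohorts

The generator emulates a constant-temperature rearing study. Per individual:
survival is an independent Bernoulli draw from a per-temperature survival
curve (no stage-to-stage carryover); duration is `1/r(T)` of a chosen true
model times mean-one lognormal noise with coefficient of variation `cv`
(durations are positive and right-skewed; laboratory SE/mean ratios of a few
percent correspond to `cv ≈ 0.02–0.1` at these cohort sizes, and the default
is 0.05 with cohorts of 100 per temperature); a daily census (default)
rounds the duration **up** to the next whole day, since a moult found at the
24 h check is recorded on that day.

What this does and does not show: recovery tests demonstrate that the
estimators are unbiased under the generator's assumptions (independent
lognormal noise, exact constant temperatures, survival independent of
development time). Real data violate these in ways the generator does not
emulate — temperature fluctuation within chambers, correlated maternal
effects, survival-duration dependence — so passing recovery tests validates
the estimation machinery, not the biology. The daily census induces a
quantified bias: durations inflate by up to one day, which at the default
design biases `K` high by roughly 3–4% and `T_min` low by ~0.3 °C; recovery
tests pin this, and continuous-census simulation (`census_interval = 0`)
recovers linear parameters exactly in the noiseless limit.

## Problem sizes and numerical choices

The packaged analyses are small by nature (4–6 temperatures per stage), so
every fit runs in seconds: 64 multi-starts for the 4–5 parameter curves, a
441-cell grid for SSI, 50-replicate recovery experiments. Optimizer
tolerances are `ftol = xtol = gtol = 1e-14` for the final solves; argmax and
root searches resolve to 1e-6 °C or better. Derived seeds stay below 2³¹.

## Known limitations

* Prepupal and pupal published regressions for the packaged table are not
  reproducible from its mean durations (the original analysis likely used
  individual-level data that no longer exists); the package reproduces the
  egg, larval and pooled-immature rows and makes no attempt to force-match
  the other two.
* The SSI enthalpy estimates are prior-bounded, not data-identified, at
  typical table sizes (see above).
* No bootstrap or profile confidence intervals for nonlinear parameters.
* No fluctuating-temperature or multi-stage linked life-cycle simulation.
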
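# Methods

`greycast` implements a hybrid grey–Markov forecasting procedure for very
short, strictly positive, fluctuating count series — the regime of annual
injury- or crash-incidence data where fewer than ten observations exist and
classical time-series models are unusable.  This note records the models,
the conventions the package commits to where the methodology admits
choices, and the known limitations.

## Pipeline overview

Given a panel of one dependent count series and several candidate factor
series over the same `n >= 4` uniformly spaced years, the pipeline runs
four stages:

1. **Grey relational screening** ranks factors by Deng's relational grade
   against the dependent series and drops those below a threshold.
2. **Model-order selection** fits the multivariate grey model MGM(1,n) for
   a range of orders `n` (factors entering by descending grade) and keeps
   the order with the smallest in-sample MAPE.
3. **Grey fit**: the selected MGM(1,n) produces a smooth fitted series.
4. **Markov residual correction** classifies relative fitting errors into
   equal-width states, estimates a state-transition chain, corrects each
   fitted value by its state midpoint, and corrects the one-step-ahead
   forecast by the modal future state's midpoint.

## Grey relational analysis

Series are first made dimensionless.  Two transforms are offered:
**initial-value** (divide by the first element; every curve starts at 1)
and **mean-value** (divide by the series mean).  The package default is
initial-value: for panels whose information is in the *growth shape* from a
common origin year it is the standard choice, and it is the convention
under which the bundled Michigan analysis is reproduced.  The relational
coefficient is

    zeta_i(k) = (d_min + rho * d_max) / (|x_1(k) - x_i(k)| + rho * d_max)

with `d_min`, `d_max` the two-level extrema of the absolute discrepancy
over *all* comparison series jointly, and the distinguishing coefficient
`rho` (default 0.5, the conventional midpoint: smaller `rho` sharpens the
penalty on the worst discrepancy).  The absolute value in the denominator
is required for `zeta` to stay in (0, 1]; formulations that omit the bars
are typographic shortcuts.  The grade is `r_i = mean_k zeta_i(k)`; the
default screening threshold is 0.7.  When all comparison series are
identical to the reference (`d_max = 0`) the coefficients are defined as 1.

## Grey models

All grey models work on the accumulated series (AGO)
`x1(k) = sum_{p<=k} x0(p)` and its adjacent-mean background
`z(k) = (x1(k) + x1(k-1))/2`, and recover original-scale values by first
differences anchored at the first observation (so the first fitted value
always equals the first actual).

**GM(1,1).**  `dx1/dt + a x1 = b`, estimated by least squares on
`x0(k) = -a z(k) + b`, solved by the whitening exponential.  A development
coefficient `a` that is numerically zero (constant input) is reported as a
degenerate model rather than silently producing an unstable fit.

**MGM(1,n)** (the pipeline's multivariate model).  One structural equation
for the dependent series with the accumulated factor series as drivers:

    x1^(0)(k) + a z1(k) = sum_{i=1..n} b_i xi^(1)(k),   k = 2..n_obs,

estimated by least squares, with fitted values from the classical
approximate time response

    x1hat^(1)(k) = (x1^(0)(1) - D(k)/a) e^{-a(k-1)} + D(k)/a,
    D(k) = sum_i b_i xi^(1)(k).

Because the response is an approximation to the exact convolution solution,
the model *smooths* the data instead of interpolating it — essential on a
6-point panel, where a fully coupled system has as many parameters as
equations and would reproduce the data exactly, leaving nothing to
correct or to compare.  Out-of-sample forecasts extend each factor's AGO
with that factor's own GM(1,1).

**Coupled system (`MGMSystem`).**  The package also provides the fully
coupled form `dX1/dt = A X1 + B` (one equation per series, rows of `[A|B]`
estimated independently by least squares on the background matrix plus a
constant).  Its continuous solution is evaluated through the augmented
matrix exponential `exp([[A, B], [0, 0]] (t-1))` acting on
`[X1(1); 1]` — the time shift makes the initial condition hold exactly and
the augmentation avoids inverting a possibly singular `A`.  This form is
appropriate when the panel is appreciably longer than the number of
modelled series; on short panels it degenerates as described above.

**Estimation conventions.**  All least squares go through an SVD
(rank-revealing) solver.  On a rank-deficient design — short panels with
many factors — the minimum-norm solution is used and an `EstimationWarning`
is emitted; this is the only well-defined estimate of such a system, but
the resulting model order should be treated as over-parameterised (see
Limitations).

**Discretization bias.**  Replacing the integral of the AGO over one step
by the trapezoidal background value biases estimates by `O(rho_A^2)` in the
system's spectral radius.  For `|a| ~ 0.1` the bias is well below 1%;
parameter-recovery tests therefore use a 5% band and forecast-continuation
tests a 1% band rather than machine precision.

## Markov residual correction

Relative errors are `delta(k) = (actual - fitted)/actual` by default.  The
actual-value denominator is the convention under which published
relative-error tables for count data are reproduced; the literal grey-theory
form with the fitted value in the denominator is available via
`residual_denominator="fitted"` (under that mode, residuals sitting exactly
at their state midpoints are corrected back to the actuals exactly; under
the default the recovery holds to first order in `delta`).

The residual range `[min delta, max delta]` is split into `s` equal-width
states (default `s = 3`: under-, normal, over-estimation), half-open
`[L, U)` except the last interval which is closed; interior boundary points
belong to the upper state.  With ~6 observations, three states keep at
least one observation per state; more states would leave empty rows.
Unvisited source states receive a uniform row with a warning (they cannot
influence analyses whose chains visit every state).

One-step transition probabilities are exact rationals `Q_ij / Q_i` from the
observed adjacent pairs; k-step matrices are exact matrix powers
(Chapman–Kolmogorov).  Matrix powers, not direct counting of k-separated
pairs, are used for k > 1: on short chains the direct counts are noisier
and do not satisfy the semigroup property.

The fitted series is corrected point-wise, including the first point, by
`y(k) = fitted(k) * (1 + (L_j + U_j)/2)`.  The one-step forecast takes, for
each lookback step `k = 1..3`, the row of `P^k` indexed by the state
observed `k` years before the target, sums the rows, takes the modal state
(ties break toward the lower state index, with a warning), and applies that
state's midpoint to the base value.  The base is the **last observed
actual** by default — the convention of the reference analysis, and the
conservative choice since it does not compound grey-model extrapolation
error — with the model's own one-step forecast available via
`forecast_base="model_forecast"`.

## Evaluation

MAPE (reported in %), MAE and RMSE (count units) are computed over all `n`
points including the anchored first point.  Fitted series are rounded to
whole counts (half away from zero) before the residual, correction and
metric stages by default (`round_fitted=True`): the quantities being
modelled are integer counts, and this is the convention under which the
reference analysis's tabulated relative errors, state bounds and error
metrics are reproduced digit-for-digit.  Full-precision fitted values
remain available on every Results object.

The dimension scan fits MGM(1,n) for `n` in a configured range (default
2..6), records the dependent-series MAPE per order and selects the argmin
(ties toward the smaller, more parsimonious order).  Orders whose fit fails
outright are recorded and excluded from the argmin.

## Synthetic data

The generators emulate the target regime — short (4–16 point) positive
panels with near-exponential trend and proportional fluctuation:

- `gen_linear_system_panel` integrates a known affine system
  `dX1/dt = A X1 + B` exactly at integer times (spectral radius capped at
  0.5 so integer sampling is well-conditioned), differences to the original
  scale and applies multiplicative lognormal noise of a given coefficient
  of variation.  Noise is multiplicative because counts are positive and
  fluctuate proportionally; additive Gaussian noise can produce negative
  counts at small levels.  Random system draws are rejected until the
  noise-free increments are strictly positive, keeping panels valid.
- `gen_gm11_series` generates from the GM(1,1) whitening solution.
- `gen_crashlike_panel` mimics the magnitudes of annual crash panels
  (dependent in the hundreds-to-thousands, 6–8 factors from units to
  hundreds) for end-to-end smoke tests.

What passing synthetic tests show: correct implementation of the estimators
and their noise response.  What they do not show: that real incidence
panels follow affine-AGO dynamics — the generators share the models'
structural assumptions, so they validate machinery, not the scientific
adequacy of grey dynamics for any particular dataset.

## Problem sizes

Everything in the test suite and the reproduction script is desk-scale:
the bundled panel is 6 x 9 values, synthetic recovery studies use 20
replicates of 2–3-variable systems at 8–10 time points, and the whole
pipeline runs in well under a minute on one CPU.

## Known limitations

- **Over-parameterised orders.**  On an `n_obs`-point panel, MGM(1,n) has
  `n + 1` parameters against `n_obs - 1` estimating equations.  Beyond
  `n = n_obs - 2` the design is rank deficient; the minimum-norm estimate
  is reported (with a warning) but such orders should not be selected, and
  results obtained from other software in this regime are solver artifacts
  and are not reproducible in principle.
- The in-sample dimension scan favours flexibility; with so few points no
  out-of-sample validation is possible, which is an inherent limit of the
  data regime, not of the implementation.
- Markov correction assumes residual-state dynamics are first-order
  stationary over a handful of transitions; with ~5 transitions the
  transition probabilities are crude (fractions with denominators 1–2).
- GM-family models require positive, broadly monotone accumulated trends;
  series with sign changes or structural breaks are out of scope.
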
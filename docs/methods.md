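# Methods

## Design model

A two-arm NI trial is described by the control-arm size `n`, allocation
ratio `r` (experimental size = round(r·n), halves away from zero), accrual
duration `Ta`, trial duration `Te`, and RMST horizon `tau ≤ Te` (default
`Te`).  The analysis clock starts at each subject's randomization; entry
affects only the administrative censoring horizon `Te − entry`.

**Event times.**  Both arms follow generalized gamma laws (Stacy form, scale
`a`, shapes `b`, `k`) sharing shapes and differing in scale.  The scale is
calibrated from the median via the inverse regularized incomplete gamma
function, `a = m / P⁻¹(k, ½)^{1/b}`, which satisfies S(m) = ½ to machine
precision; b = k = 1 is exponential, k = 1 Weibull, b = 1 gamma.  Raw
moments are `E(Tʳ) = aʳ Γ(k + r/b)/Γ(k)`; sampling uses `a·G^{1/b}` with
G ~ Gamma(k, 1).

**Accrual.**  Entry density is linear, `f_V(v) = a* + b*·v` on `[0, Ta]`:
decreasing (a* = 2/Ta, b* = −2/Ta²), uniform, or increasing (a* = 0,
b* = 2/Ta²), sampled by inverse CDF; `Ta = 0` puts everyone at time 0.

**Censoring.**  The censoring time is `min(D, Te − V)`, with dropout D
uniform on (0, u), exponential with rate λ, or absent (`censoring.prob =
"AC.only"`).  The dropout parameter is calibrated so the *total* control-arm
censoring probability under no switching, `P(min(D, Te − V) < T₁)`,
evaluated by nested adaptive quadrature (absolute tolerance 1e-8 on the
probability scale), matches the user's `censoring.prob`; the root is found
by Brent's method on the log parameter.  For the exponential family the
inner integral is computed on the scaled variable w = λc so the integrand
stays resolved at extreme rates.  A target below the administrative-only
probability is an error; a target equal to it returns the no-dropout law
with a warning.  The solved uniform support may exceed `Te`, which simply
means early entrants are never dropout-censored before the horizon.

**Switching.**  Switch times S are either S = X·T₁ with X independent of
T₁ — X ~ U(0,1) (forces r_s = ½), Beta(a,b), or Gamma(a,b) — or independent
of T₁: exponential with rate 1/(r_s·E(T₁)), or a fixed calendar time.  Beta
and gamma parameters are moment-matched in closed form: corr(X·T, T) = ρ
implies `Var(X) = r_s² Var(T)(1 − ρ²)/(ρ² E(T²))`, then mean/variance
matching gives the shape parameters; the solution is verified to reproduce
(r_s, ρ_s) to 1e-8 at construction, and infeasible (r_s, ρ_s) pairs raise
an error stating the attainable ρ_s range.  A subject is *eligible* only if
S < T₁ (the counterfactual transformation needs positive residual time —
with gamma/indepExp/fixed laws S ≥ T₁ is possible and such subjects never
switch); among eligible subjects an independent coin with probability `ps`
decides the actual switch.  Switching is decided on latent times before
censoring; a nominal switch after the censoring time is harmless because
the observed value is the minimum either way.  A switcher's event time
becomes `T* = s + (T − s)·accel` with `accel = af·m₂/m₁` for
control-to-experimental switching and `af·m₁/m₂` for the reverse direction
(the multiplier `af` supports sensitivity analyses around the common-
treatment-effect assumption).

**Analysis.**  Each simulated trial is analyzed by the product-limit
estimator (ties: events before censorings), RMST as the area under the step
function on [0, τ], and the variance
`Σ_{tᵢ ≤ τ} Aᵢ² dᵢ/(nᵢ(nᵢ − dᵢ))`, `Aᵢ = ∫_{tᵢ}^{τ} Ŝ`, with zero
contribution when nᵢ = dᵢ.  The internal fast path processes tied events
one at a time, which reproduces the grouped formula exactly (the per-event
terms telescope to d/(n(n−d))); this is verified against lifelines and a
frozen R `survival::survfit` reference in the tests.  If the largest
observed time precedes τ the curve is carried flat with a warning — this
deliberately reproduces the degradation of RMST estimates under heavy
late-entry censoring instead of erroring out.  The test rejects when
`Δ̂ − z₁₋α·SE > −margin` (strict inequality; normal quantile, no
small-sample correction).

## Margin adjustment

`delta_star = R_mixed − R_pure + delta` for control-arm switching, where
`R_pure` is the *analytic* RMST of the pure arm law (quadrature) and
`R_mixed` is the average of KM RMST estimates over `n_simulations`
simulated mixed arms; for experimental-arm switching the sign flips
(`delta + R_pure − R_mixed`), preserving the equivalence with the
no-switching test.  When `ps = 0` or the acceleration factor is exactly 1
the adjustment short-circuits to δ with no simulation.  A non-positive δ*
(switching shift exceeding the margin) is an infeasibility error.  The δ*
simulations use a seed substream independent of the power-evaluation
trials, avoiding a small reuse bias; δ* is computed under whatever
parameters the configuration carries, so null configurations (margin set to
R₁ − R₂) yield the type-I-error calibration and alternative configurations
yield power.

## Power and sample size

`calculate_power` solves all calibrations once, estimates δ* (or uses δ
when `adjust_margin=False`, the unadjusted analysis used to quantify
inflation), simulates `n_simulations` independent trials from per-replicate
`SeedSequence` substreams, and reports the rejection fraction, its MC
standard error, and the mean per-arm event counts over the full follow-up
(not truncated at τ).

`calculate_size` evaluates the power at `n_L + j·w` (j = 0..B,
w = round((n_U − n_L)/B); a zero step collapses to the integer range), fits
a monotone nondecreasing curve, and returns the smallest integer n whose
fitted power reaches `epwr`.  The fit uses an I-spline basis (integrated
clamped B-splines, degree 2, interior knots scaled to the grid size) with
nonnegative slope coefficients and a free intercept solved by nonnegative
least squares — a shape-constrained smoother in the same spirit as
shape-constrained additive models; with fewer than 4 grid points it falls
back to isotonic regression plus interpolation with a warning.  δ* is
re-estimated at every grid point (it is n-independent in expectation; the
re-estimation preserves fidelity of the per-point analysis), while the
dropout/switch/margin calibrations are solved once since they do not
depend on n.  Allocation is deterministic (exact arm counts), matching the
per-fixed-arm-size interpretation of expected event counts.

## Reproducibility

A single master seed drives everything through `numpy` `SeedSequence`
spawning: one child for the δ*-estimation stream, one per power replicate,
and one per size-search grid point, so any replicate is reproducible in
isolation and identical configurations give bit-identical results.

## Problem sizes used in validation

The packaged checks run the worked-example power and the type-I-error
calibrations at 5000 replicates, and the sample-size anchors at 1000–5000
replicates per grid point with 10-interval grids; sampler/calibration
identities use 4·10⁵–10⁶ draws.  These sizes put Monte-Carlo noise well
below the tolerances asserted (3·binomial SE plus a 0.005 slack for
rejection rates; ±5–8% for required sizes, reflecting grid/smoothing
noise).

## What the simulations do and do not show

The generator emulates the stated design model: independent subjects,
parametric event/entry/dropout laws shared across arms, switching governed
by (ps, r_s, ρ_s) and a common treatment effect via the RPSFT rule.  It
does not emulate covariate-driven switching, informative censoring,
non-proportional accrual beyond the linear family, or between-subject
effect heterogeneity — conclusions about real trials hold only insofar as
those assumptions do.  Known limitations inherited from the model: with
increasing entry and τ near Te, most subjects have short follow-up and the
adjusted-margin type-I error can exceed the nominal level by up to about
0.005; choosing τ below Te restores control.
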
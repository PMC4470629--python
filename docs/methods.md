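# Methods

## Scope and data model

The package analyses long-format monthly tables: visitation
(`park_id, year, month, recreation_visits`) and temperature
(`park_id, year, month, tmean_c`, °C), plus a future table
(`park_id, model, rcp, month, tmean_c`) and a gridded-product baseline.
Gridded extraction is outside the boundary: the package consumes
pre-extracted park × month values. Visit counts are accepted as
non-negative reals (agencies rescale some series); non-integers are
flagged at load with a warning, not an error.

Parks enter the analysis with ≥ 10 *complete* calendar years (all 12
months present) of visitation and a mean annual total ≥ 8,000 visits
over those complete years. "Complete years" is a deliberate reading:
partial years would deflate annual means and make the 8,000-visit
threshold incoherent. Long-term monthly means are taken over all
available years per month, with the per-month year count retained for
audit; a month with no records at all is a hard error, because a park
without a full seasonal profile cannot be modelled.

## System-wide model

The system GLM regresses each park-month's share of annual visits on a
raw polynomial (orders 0–3) in centered monthly mean temperature plus a
park categorical, binomial family with the canonical logit link, unit
weights. Unit weights are a substantive choice: the point of modelling
proportions is to compare seasonal *patterns* across parks whose annual
totals differ by three orders of magnitude, and count-weighting would
hand the model back to the busiest parks.

Model comparison uses BIC = *k*′ ln *n* − 2 lnL with the binomial-form
log-likelihood evaluated at the proportions (Σ y ln μ + (1−y) ln(1−μ)).
Order selection happens on that likelihood; the Pearson
(quasibinomial-style) dispersion is reported separately for standard
errors, mirroring the usual sequence of select-then-inflate. Two
consequences of this likelihood are worth knowing:

- it is extremely flat — the gap between the truth and the saturated
  model on a realistic synthetic system is ~10⁻³ log-likelihood units —
  so McFadden's R² (computed against the park-term-only null, which the
  order-0 fit equals by construction) is structurally small (≲ 0.2) on
  proportion data, and
- BIC differences between adjacent orders are modest, so hump-shaped
  (inverted-U) responses, whose within-park signature a quadratic plus
  park intercepts captures almost entirely, do not let a cubic win. The
  synthetic shared-response recovery surface therefore uses an S-shaped
  cubic latent, 0.08(T−10) + 0.0006(T−10)³, whose inflection no
  quadratic can mimic; at 60 parks × 20 years the cubic wins BIC
  selection in every seed tried (minimum ΔBIC ≈ 4.5).

`system_design_dims` exposes the design bookkeeping symbolically: with
*P* parks, 12 months and order *k*, there are 12 *P* rows, *P* + *k*
parameters and 12 *P* − *P* − *k* residual degrees of freedom (340 parks,
cubic: 4080 rows, 3737 df).

## Per-park models

Each park's 12 long-term monthly mean visit counts are regressed by OLS
on a raw polynomial in centered temperature, orders 0–3, compared by
Gaussian BIC = n ln(RSS/n) + k′ ln n at n = 12 (the additive constant
cancels in the argmin). Ties break toward the lower order, and an RSS
below the fit's numerical precision is clamped to a common floor so
that exact fits at several orders tie and parsimony resolves the order
(otherwise floating-point noise in a perfectly-fit park picks an
arbitrary order). If all 12 temperatures are identical the polynomial
columns are collinear; orders ≥ 1 are skipped with a warning. Centering
is purely for conditioning — fitted values, RSS and hence BIC are
invariant to any affine rescaling of temperature, which the tests
assert.

A park is temperature-sensitive iff its selected order is ≥ 1 and the
selected model's adjusted R² ≥ 0.5. Projection refuses insensitive
parks by raising, not by silently returning zeros.

Prediction standard errors are the OLS standard errors of the mean
prediction at the new temperature. Capping (below) carries a flag but
not a modified SE; the interval describes the uncapped regression
prediction.

## Scenario construction

The delta (change-factor) method is exact arithmetic:
δ(model, m) = future(model, m) − model-era baseline(m), then
scenario input(m) = observed baseline(m) + δ(model, m). Subtracting a
model's own baseline cancels its bias; composing the two steps with the
same baseline table returns the future field exactly, which is tested
to machine epsilon. Missing months are hard errors — a partial delta
table silently misaligned by month would be worse than a crash.

Low/high scenarios average the five members with the lowest/highest
annual mean temperature at the park (unweighted mean of the 12 monthly
values; no day-count weighting, since the ranking statistic only has to
order members). Ties break lexicographically on model id so the member
set is deterministic and independent of input row order.

## Projection and growth ceilings

Each sensitive park's selected polynomial is evaluated at the scenario
temperatures and every month clamped into
[0, (1+g) · max historical monthly mean] with g ∈ {0.05, 0.25}.
Negative polynomial extrapolations are floored at zero — visits cannot
be negative, and a cubic extrapolated 3–4 °C beyond its support can dip
below it. Capping is applied at the monthly level, before any seasonal
aggregation.

System summaries report, per scenario × ceiling: percent change in
annual and per-season totals (summed over projected parks), the
fraction of park-months increasing, mean season-length change, and the
fraction of parks whose peak/low windows move at most one month. The
default baseline for percent changes is the *model-consistent* one —
each park projected at its historical temperatures under the same
ceiling — so that a zero-warming scenario yields exactly 0% change and
any reported change is attributable to temperature, not to residual
lack of fit. The `baseline="observed"` option compares against the
measured climatology instead (the convention when quoting change
against the historical record); seasonal windows are always the
*historical* ones, and season-length change is always future minus
historical-observed.

## Season statistics

Windows are found by exhaustive enumeration of the 12 circular
candidates (ties → earliest start). A constant series is flagged
degenerate rather than forced into a window. Note that on adversarial
(non-unimodal) series the peak and low windows can legitimately share a
boundary month — a trough squeezed against a sharp peak; on seasonal
profiles like the synthetic system's they are disjoint, and the tests
assert exactly that.

Daily curves use a 365-day year (month lengths 31, 28, 31, …; leap days
are immaterial at the precision of long-term means). A periodic cubic
spline passes through each month's average daily rate at the month
midpoint; evaluating at day midpoints, clamping negative excursions to
zero and rescaling preserves the annual total to ~10⁻¹⁵ relative
(tested at 10⁻⁹ over 1000 random inputs) and avoids any artificial
December→January kink. The season runs from the interpolated crossing
of 10% of cumulative annual visitation to the crossing of 90%, with the
cumulative year anchored at January 1. Closed forms pin the
implementation: a uniform curve gives exactly 36.5 → 328.5, length
292.0 days; a uniform single-July pulse gives 0.8 × 31 = 24.8 days. For
winter-peaking parks the Jan-anchored year splits the active season;
the statistic is still computed on that anchoring, which is a
documented convention, not a claim of optimality.

## The synthetic study system

The generator emulates the statistical structure the analysis assumes,
with every parameter recorded as ground truth.

*Temperature.* T(y, m) = T₀ + A·cos(2π(m − 7)/12) + ε, ε ~ N(0, σ_T).
Defaults: T₀ ~ U(−5, 28) °C, A ~ U(3, 14) °C, σ_T = 1 °C — spanning
tropical to boreal parks with realistic interannual variability of
monthly means.

*Visitation.* The latent response is log q(T) with softmax
normalisation across the 12 months, so monthly weights live in (0, 1)
and sum to one; expected counts are μ_m = S·w_m with S the annual
scale (log-uniform over 8·10³–2·10⁶, the span of real annual totals)
and counts drawn negative-binomially with Var = φ·μ, φ = 2 by default
(overdispersion is why quasibinomial inference exists downstream). In
the default system q is a *positive polynomial* of known order in
standardized temperature (order mix 5/31/39/25% over orders 0–3,
echoing the best-fit-order distribution reported for a large real
system; ~85% of sloped parks oriented warm-peaked), which makes the
expected visit curve genuinely polynomial in temperature — so
"recovering the true order" is a well-posed claim. With
`response_space="log"` the latent is the polynomial itself, the natural
surface for the logit-link system GLM.

*Planning behaviour.* Expected visitation follows the park's
climate-normal cycle, not the realized yearly anomaly: visitors plan
trips months ahead on long-term averages. (An opt-in
`couple_to_realized` ties weights to realized temperatures; note that
the climatological visit curve is then a ratio of noisy polynomials and
order recovery is no longer exact.)

*Calendar structure.* Real visitation carries holiday and
school-vacation signal that temperature cannot explain. The generator
adds a calendar component — equal-and-opposite relative offsets
(SD 6%) within month pairs sharing a climate-normal temperature — which
is invisible to any temperature polynomial by construction. Besides
realism, this matters statistically: with *only* white noise, BIC at
n = 12 overfits at the F-tail rate (~16–21% per extra order, a ceiling
of ~84% order recovery no matter how small the noise, because selection
statistics are scale-invariant). A temperature-orthogonal residual
component inflates the error-variance estimate without biasing
coefficients, suppressing noise-chasing; measured recovery on the
default system is 96–100% across seeds, with ~100% of selected-model
coefficients within 2 SE of the pseudo-truth (the same-order fit to the
noise-free expected visits).

*Ensemble.* Each pathway gets 17 members; member j's monthly offset is
w_j + N(0, 0.3) with w_j ~ N(1.3, 0.5) °C for the moderate pathway and
N(3.4, 0.7) °C for the high pathway — the mean monthly warmings the
downscaled mid-century projections show. The gridded-product baseline
is the park's climate normal plus a fixed per-month product bias, which
the delta method must (and does, exactly) cancel. True member offsets
and the 5-lowest/5-highest sets are recorded for the sort oracles.

*What passing tests do and do not show.* The generator reproduces the
*structure* of the real analysis problem — seasonal cycles, polynomial
responses, overdispersion, calendar residuals, ensemble spread — not
any real system's numbers. Real archives add phenomena the generator
omits: autocorrelated and trending visitation, economic and population
drivers, closures and re-openings, fall-foliage and snow-sport
phenology, spatially correlated climate. Recovery results here certify
the machinery, not real-data effect sizes; the headline statistics of
the source analysis (e.g. a system R² of 0.69, 8–23% annual increases)
require the real archives and are not desk-reproducible.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng` seeded from
  explicit (seed, stream) pairs; identical configs reproduce outputs
  byte-for-byte (CSV floats printed at %.17g), which the tests assert.
- Softmax uses max-subtraction, so extreme latents scale internally
  rather than overflow.
- Binomial log-likelihoods use `xlogy` (exact at y = 0, 1) with fitted
  means clipped to [10⁻¹², 1 − 10⁻¹²]; fitted proportions within 10⁻¹⁰
  of the boundary are flagged as possible separation.
- GLM non-convergence after 200 IRLS iterations raises with
  diagnostics rather than returning a half-converged fit.
- The default problem sizes (50-park system for the study, 60-park
  shared-response systems for GLM recovery, 10⁴ window-oracle draws,
  10³ conservation draws) keep the full test suite and the acceptance
  script in the low minutes on one CPU while leaving selection margins
  measured rather than assumed.

## Known limitations

- Under strong temperature noise, errors-in-variables leak into the
  regressions: residuals correlate with the regressors and are
  slope-heteroskedastic, so nominal 2-SE prediction coverage degrades
  (measured ~86–89% under σ_T = 1 °C against ~92% in the OLS-clean
  regime — itself the t₉ ceiling for a 2·SE band at n = 12). The
  recovery oracle for prediction intervals is therefore run in the
  regime where the OLS error model holds; real-data interval coverage
  inherits the same caveat.
- The system GLM on the *default* mixed system selects order 0: fifty
  parks with park-specific standardized response shapes share no common
  polynomial in absolute temperature, and the flat likelihood (above)
  does not reward a compromise curve. This is the honest behaviour of
  the estimator under those conditions, not a defect; shared-response
  systems exist precisely to give system-level selection a recoverable
  truth.
- No mixed effects, autocorrelation, covariates beyond temperature and
  park identity, precipitation/humidity indices, sub-monthly data, or
  uncertainty propagation from ensemble spread into visitation SEs —
  all outside the single-variable design this package implements.
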
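# parkclim

Monthly mean air temperature is one of the strongest predictors of when
people visit protected areas. `parkclim` is a tested re-implementation of
the analysis behind that claim for a large park system: it fits
system-wide and per-park models of monthly visitation against
temperature, builds mid-century warming scenarios from a climate-model
ensemble by the delta (bias-correction) method, projects future monthly
visitation under growth ceilings, and measures how the visitation season
shifts and stretches. It is written for climate-adaptation analysts and
quantitative ecologists who want the full pipeline — inclusion filters,
model selection, scenario construction, season phenology — as a library
with a CLI, rather than a one-off script.

Because the historical visitation archive and gridded climate products
are external datasets, the package ships a first-class synthetic-data
module that generates park systems with known ground truth (polynomial
temperature responses, overdispersed counts, a 17-member pseudo-GCM
ensemble). Every stage of the analysis is exercised, and its parameter
recovery verified, without any download.

## The models

**System-wide GLM.** For park *i* and calendar month *m*, let
*p*<sub>im</sub> be the share of the park's annual visits falling in
month *m* (so Σ<sub>m</sub> *p*<sub>im</sub> = 1). The system model is a
binomial GLM with logit link,

  logit(*p*<sub>im</sub>) = α<sub>i</sub> + β₁*T*<sub>im</sub> + β₂*T*<sub>im</sub>² + β₃*T*<sub>im</sub>³,

with a park intercept α<sub>i</sub> in every candidate and polynomial
orders *k* = 0…3 compared by BIC = *k*′·ln *n* − 2·lnL, where lnL is the
binomial-form log-likelihood evaluated at the proportions. McFadden's
R² = 1 − lnL/lnL₀ is reported against the park-term-only null, and a
quasibinomial (Pearson) dispersion is carried for standard errors.

**Per-park regressions.** Each park's 12 long-term mean monthly visit
counts are regressed on a raw polynomial in centered temperature
(orders 0–3, OLS), compared by Gaussian BIC at *n* = 12 with ties broken
toward parsimony. A park is *temperature-sensitive* when its best model
includes temperature and reaches adjusted R² ≥ 0.5; only sensitive parks
are projected.

**Scenarios and projection.** Member deltas (future minus model-era
baseline, per month) are added to the observed historical baseline; the
five coolest members of the moderate pathway and five warmest of the
high pathway (ranked per park by annual mean temperature) are
ensemble-averaged into low/high scenarios. Projected months are clamped
into [0, (1+g) × busiest historical month] for growth ceilings g = 5%
and 25%.

**Seasons.** Peak season is the highest-sum 3 contiguous months
(circular), shoulders the 2 months either side, low season the
lowest-sum 3. Monthly totals are interpolated to daily rates with a
periodic cubic spline (conserving the annual total), and the visitation
season runs from the day cumulative visitation reaches 10% of the
annual total to the day 10% remains — the central 80% of visits.

## Worked example

The numbered drivers under `analysis/` run the study end-to-end on the
default 50-park synthetic system (they share `--seed` and `--out`):

```sh
python analysis/01_simulate.py          --seed 1
python analysis/02_filter_and_average.py --seed 1
python analysis/03_fit_models.py        --seed 1
python analysis/04_build_scenarios.py   --seed 1
python analysis/05_project_visitation.py --seed 1
python analysis/06_season_metrics.py    --seed 1
python analysis/07_report.py
```

At seed 1 the fitting stage prints

```
system GLM: order 0 best (McFadden R2 0.000); park best-fit orders
{0: 5, 1: 10, 2: 22, 3: 13}; 45/50 parks temperature-sensitive
```

— per-park BIC selection recovers every generating order (5 null, 10
linear, 22 quadratic, 13 cubic parks), and 45 parks pass the
sensitivity rule. (The default system deliberately mixes park-specific
response shapes, so no single system-wide polynomial wins; see
`docs/methods.md`.) Scenario construction reports the realized warming
of the ensemble-averaged bookends,

```
rcp45_low:  mean warming +0.53 C over the historical baseline
rcp85_high: mean warming +4.52 C over the historical baseline
```

and the season stage prints the system summary, e.g. for the low
scenario at the 5% ceiling: annual visits +6.1%, low-season visits
+26.7%, 67% of park-months increasing, mean season-length change
+0.3 days, and 78% of parks with peak/low timing stable within one
month. Under the high scenario at the 25% ceiling annual visits rise
38.9%. The same numbers are cross-checked and re-printed by
`analysis/07_report.py`.

The same pipeline is available as a CLI (`parkclim run --seed 1 --out
results/study`, with `simulate`/`filter`/`fit`/`scenarios`/`project`/
`seasons`/`report` subcommands) or as a library call
(`parkclim.run_pipeline(RunConfig(seed=1), "results/study")`). Re-running
with the same seed reproduces every output byte-for-byte.

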
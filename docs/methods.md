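# Methods

## Scope and data model

The package computes, from small-area administrative inputs, (i) per-episode
inpatient costs and per-cell averages by deprivation quintile, single-year
age and sex; (ii) the counterfactual cost of inequality against the least
deprived quintile; (iii) period life tables per quintile and sex; and (iv)
survival-weighted expected lifetime hospital costs. Five input tables drive
everything: episode records (one row per finished consultant episode),
an HRG reference-cost tariff, mid-year populations by area × sex × single
year of age (0–84, open 85+), death counts by area × sex × 5-year band, and
an area → deprivation-rank table. All files are headered CSV; the open age
group is written `85+` and coded 85 in memory.

The counting unit is the episode (FCE), not the admission or spell. Costs
are carried as exact integer pence through aggregation; division to
averages happens last, so cost totals and table margins are bit-exact.

## Quintile assignment

Areas are sorted by deprivation rank (1 = most deprived) and cut into five
groups of areas — fifths of areas, not population-weighted fifths. When the
area count is not divisible by 5 the remainder goes to the more-deprived
groups first, deterministically, so group sizes differ by at most one.
Duplicate ranks are a validation error.

## Costing and the missing-data rule

`cost = unit_cost + max(0, LOS − trim_point) × excess_per_diem`, per the
payment-by-results tariff logic; an unknown HRG code is a hard error, never
a silent zero. No market-forces-factor price adjustment is applied: the
object of study is variation in resource use, not local prices.

Episodes missing any of age, sex or area cannot be placed in an analysis
cell and are dropped; the dropped fraction π is reported and group cost
totals are multiplied by `1 + π`, under the assumption that missingness is
uniform across cells. The uplift applies to cost totals only — never to
populations or episode counts. Note that `1 + π` slightly under-corrects
relative to the unbiased `1 / (1 − π)` (for π = 0.088 the factors are 1.088
vs 1.0965); the simpler multiplicative uplift is retained as the package's
convention and the factor is recorded in every run log. A related
consequence: reported episode counts are raw kept counts, so count totals
and (inflated) cost totals are deliberately on different bases.

## Counterfactual cost of inequality

With `c̄(g,a,s)` the inflated average annual cost per head,

```
counterfactual(g,s) = Σ_a N(g,a,s) · c̄(Q5,a,s)
gap(g,s)            = observed(g,s) − counterfactual(g,s)
```

Both sides use inflated costs, so they are on the same basis, and the
observed side is evaluated as `Σ N · c̄` — algebraically the inflated total,
but the identical floating-point expression to the counterfactual — so the
reference quintile's gap is exactly zero, not merely close. Negative gaps
are reported, not floored. A populated cell with no reference-quintile
residents makes the counterfactual undefined and raises an error listing the
cells; the cure is a demographically denser input, not imputation.

## Life table

Band rates pool counts — `m = ΣD / ΣN` over areas within a quintile — never
a mean of area-level rates. Rates expand to single years piecewise-constant
(no graduation is applied, since none is implied by banded inputs), the 85+
rate is held constant to `max_age` (default 110; the inputs are truncated at
85, so old-age rates are assumed not to keep rising), and survival chains as
`S(a+1) = S(a)(1 − q(a))`. Defaults and options:

| parameter | default | alternative | note |
|---|---|---|---|
| `q_convention` | `central` (q = m) | `actuarial` (q = m/(1+m/2)) | central rate used directly as the annual probability |
| `max_age` | 110 years | any ≥ 86 | closes the open 85+ interval; survivorship past it is discarded |
| `survival_weighting` | `start` (S(a)) | `midyear` ((S(a)+S(a+1))/2) | weight applied to costs below |

Deaths exceeding population is a validation error; a band with zero deaths
and zero population gets rate 0 with a warning.

## Lifetime costs

`E(g,a,s) = S(g,a,s) · c̄(g,a,s)` with `c̄` frozen at the 85+ value beyond
age 84, and `L(g,s) = Σ_a E(g,a,s)` — a pure running sum, so lifetime costs
decompose exactly over admission-type strata. No discounting and no trend
projection: rates, costs and each person's deprivation are held at the
observed year's level. The start-of-year survival weight is the default
reading of "alive to incur the cost"; the mid-year option treats
survivorship beyond the terminal age as zero.

## Synthetic data generator

The generator emulates the restricted inputs' structure, not their content:

* **Mortality**: Gompertz hazard `h(a) = b·e^{ca}` with defaults
  `b = 3.3e-5`, `c = 0.095` per year and a female hazard factor of 0.55,
  giving period life expectancies of roughly 78 (male) and 85 (female) —
  realistic for England around 2011. A deprivation hazard gradient
  (default Q1/Q5 = 1.5) ramps log-linearly across quintiles
  (`factor(g) = gradient^((5−g)/4)`).
* **Age structure**: each quintile's population follows the stationary
  population of its own hazard, so deprived areas are younger — the same
  mechanism that produces their smaller elderly populations in real data —
  and the population and deaths files are internally consistent. Cell counts
  are Poisson around `mean_area_pop` × the quintile's share profile.
* **Admissions**: per-cell Poisson counts with a U-shaped age curve
  `r(a) = child·e^{−a/5} + old·e^{growth·(a−85)}` per admission type,
  calibrated so national crude rates land near ~20 000 elective and
  ~15 000 emergency episodes per 100 000; women aged 20–40 get a
  reproductive-age multiplier (default 2.0). Deprivation gradients default
  to 1.20 (elective) and 1.71 (emergency) per cell. Episode counts are
  Poisson — no over-dispersion, as nothing in the modelled inputs pins down
  a dispersion level.
* **Tariff catalogue**: 20 pseudo-HRG codes with gamma unit costs (mean
  £1 400, shape 2), integer trim points 5–30 days, per-diem excesses, and a
  geometric length of stay with mean half the trim point, so the
  excess-bed-day path is exercised. With only 20 codes the realised
  catalogue mean varies by roughly ±£220 between seeds; absolute cost
  levels therefore move between seeds while gradients and orderings do not.
* **Missingness**: each episode is independently blanked with probability
  `missing_rate` (default 0.088) in one of age/sex/area, chosen uniformly —
  carrying no deprivation signal, matching the uplift's uniformity
  assumption.
* **Determinism**: every stream derives from the master seed via a fixed
  integer label, so outputs are byte-reproducible and adding a generator
  never perturbs existing ones; the missingness stream is separate from the
  episode stream.

A `ground_truth.json` (plus cell-level CSVs) records expectation-level
quantities for recovery tests: expected populations, per-cell episode
counts, *crude* expected Q1/Q5 rate ratios, band death probabilities and
the survival curves they imply. Two subtleties are deliberate. First, the
quintiles' different age structures confound crude rate ratios, so the
expected crude ratio is below the configured per-cell gradient; recovery
tests compare realised crude ratios against the ground truth's expected
crude ratios, while direct age/sex standardisation
(`cohort_aggregation.standardised_rates`) recovers the configured gradient
itself. Second, the ground-truth survival applies the estimator's own
convention (expected band rates expanded piecewise-constant), so estimate
vs ground-truth comparisons isolate Monte-Carlo error from banding
discretisation.

What the generator does **not** emulate: clinical coding and real HRG case
mix (20 codes vs ~1 400), within-year readmission correlation, area-level
over-dispersion, migration, sex ratios at birth, or seasonal structure.
Passing recovery tests therefore demonstrates that the pipeline measures
what the generator encodes — gradients, survival, lifetime accumulation —
not that real HES data would be free of the confounds the generator omits.

## Problem sizes and test design

The generator's defaults are national scale (32 482 areas of ~1 500
residents). The recovery and acceptance runs use 2 000 areas × 1 500
residents (~3 million people, ~1.2 million episodes), which puts Monte-Carlo
error on the Q1/Q5 ratios near 0.4% — far below the gradients being
recovered — while a full pipeline run completes in seconds. Statistical
comparisons use 3-standard-error bounds: delta-method errors for survival
products and log rate ratios, and the sample standard error of 200 000
simulated life courses for the lifetime-cost oracle (an independent
straight-line micro-simulation: alive at the start of year a incurs
`c̄(a)`, dies with probability `q(a)`).

## Known limitations

* Quintiles are fifths of areas; population-weighted fifths would differ
  slightly when area sizes correlate with deprivation.
* The `1 + π` uplift under-corrects for missingness (see above), and count
  and cost totals sit on different bases by design.
* The life-table conventions (q = m, piecewise-constant expansion, terminal
  age 110) are the simplest defensible choices; all three are configurable,
  and at realistic hazards the terminal-age choice moves lifetime costs
  negligibly because survivorship past 110 is tiny.
* Lifetime projections hold rates, costs and deprivation fixed over the
  life course — period, not cohort, quantities.
* No need/morbidity adjustment is made: gaps quantify observed use, not
  equitable use.
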
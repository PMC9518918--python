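# Methods

This note documents the model implemented by `snakeburden`, the defaults
it ships, the numerical conventions it uses, and what its synthetic test
data can and cannot show.

## Model structure and assumptions

The model is a one-year cohort decision tree evaluated in expectation.
Three structural assumptions shape it:

1. **One bite per lifetime.** Victims enter the tree once; there are no
   repeat episodes or time dynamics.
2. **One accompanying relative.** Every admitted victim is accompanied
   by one relative who shares food costs and loses the same number of
   income days.
3. **Antivenom works through mortality only.** Treated indicated
   victims die with probability `death_treated`; every untreated
   indicated victim dies with probability
   `min(1, rr_death_untreated x death_treated)`. The default relative
   risk is 2.33 (95% interval 1.26–4.06). Non-envenomed victims never
   die in the model, and ADR after antivenom carries costs but no excess
   mortality.

Tree conventions that were genuinely open and are fixed here as package
design choices:

* Antivenom is only reachable through conventional care; the treated
  fraction among indicated victims at conventional care equals the
  access level `min(1, courses / indicated)`, where the denominator is
  *all* indicated victims (that is how supply sufficiency is defined in
  the field: courses available over victims needing them).
* Amputation applies to survivors of envenoming only — death and
  amputation are mutually exclusive — with a probability independent of
  treatment arm unless configured otherwise.
* Demographic strata share the tree probabilities; they differ in their
  victim share and in the representative age used for YLL and
  premature-death productivity loss (`mean_age_at_death` per stratum).
  Per-stratum counts are therefore exact share-scaled copies of the
  country totals, and sum to them by construction.

`decision_tree.enumerate_paths` walks every root-to-leaf path explicitly
and is kept deliberately independent of the closed-form bookkeeping in
`run_tree`; the two routes agreeing to 1e-9 relative on random inputs is
a standing test invariant, and the path table can be dumped to CSV as an
audit trail.

## Costing conventions

* All unit costs are entered in local currency and converted once at the
  2019 exchange rate. Computing in local currency and converting at the
  end is algebraically identical (tested).
* **Daily income** is GDP per capita / 365. The calendar-day divisor
  matches lengths of stay measured in calendar days; it is configurable
  (`daily_income_divisor`).
* **Hospitalization** covers victims reaching conventional care, with
  separate lengths of stay for envenomed (`los_indicated`) and
  non-envenomed (`los_not_indicated`) admissions. Traditional-healer-only
  victims incur no facility, transport or food costs, and no
  traditional-healer fees are modelled.
* **Episode productivity loss** applies to *all* victims (and one
  relative each) — illness time is lost regardless of care venue — using
  the indication-specific episode length.
* **Premature-death loss** is a discrete annual sum with the first lost
  year undiscounted (t = 0), whole remaining working years (fractions
  truncated), retirement at 60, discounting at 3%/year and adjustment
  for GDP-per-capita growth. With growth equal to discounting it
  reduces exactly to GDP x remaining years; at or beyond retirement it
  is zero. Deaths are allocated to strata by share, each stratum
  contributing its representative age.

## DALYs

YLL uses a standard reference life table (bundled as
`data/life_table.csv`, a reconstruction of the synthetic standard table
used in WHO/GBD burden work; editable) with linear interpolation between
knots. YLLs are undiscounted and not age-weighted by default; a
continuous-time discounting switch exists for sensitivity analyses.

YLD terms (bundled defaults in `data/disability_weights.csv`, all
reconstructions):

| condition | weight | duration |
|---|---|---|
| acute episode | 0.133 | 0.0211 y (~7.7 days) |
| amputation | 0.021 | lifelong (residual life expectancy) |
| PTSD (scenario) | 0.133 | 1 year |

The episode YLD applies to every envenomed victim, deaths included,
because the acute episode precedes death. Non-envenomed victims carry
no episode YLD by default. Disabilities beyond amputation and PTSD
(blindness, chronic ulcers, pregnancy loss) are out of scope.

## PTSD scenario

PTSD occurs in 8% (95% interval 2–18%) of envenoming survivors and 2%
(fixed) of non-envenomed victims; amputees are not double-counted (they
are already survivors). Each case adds `weight x duration` YLD and a
productivity cost of `duration x 365 x daily income x loss_fraction`
with a default loss fraction of 0.30. Weight, duration and loss
fraction are configurable; the defaults are reconstructions chosen to
sit at the scale of roughly 1,200 USD productivity loss per case for a
middle-income country. Scenario totals are base totals plus the PTSD
terms exactly, so scenario burden can never fall below base burden.

## Uncertainty analysis

Every uncertain input is a `(point, low, high, family)` quadruple with
the range read as a central 95% interval. Distribution families (the
choice was open; these are standard PSA practice and keep supports
valid):

* probabilities — beta, moment-matched to the point (mean) and the
  range-implied standard deviation `(high - low) / (2 x 1.96)`;
* costs, lengths of stay, counts — gamma, same moment matching;
* relative risk — lognormal with median at the point and sigma from the
  range on the log scale (so the geometric mean of draws equals the
  point estimate);
* demographic shares — Dirichlet with concentration moment-matched to
  the tightest stated share range;
* rates that may span zero (growth, discount) — uniform on the range.

When a range is too wide for the family to match (e.g. a beta variance
exceeding `m(1-m)`), the sampler falls back to a uniform on the range
with a warning rather than failing the run. The families used are
recorded in the run metadata JSON.

The PSA default is 1,000 draws; the sampler stream is vectorized per
parameter, so a fixed seed reproduces the draw matrix bit for bit.
Parameters are sampled independently (no correlation structure is
specified by the inputs), and countries within a region are sampled
independently and summed within each draw. Because the base-case
discount rate carries a plausible range, it is sampled in the PSA like
every other uncertain parameter.

The tornado analysis is a two-point evaluation of the same deterministic
pipeline per parameter — no hidden randomness — sorted by swing.
Demographic shares are excluded from the tornado because moving a single
share requires a renormalization convention; share uncertainty is
carried by the PSA instead.

## Synthetic data

The generator emulates the structure of real country input tables —
point estimate plus plausible range per parameter — across three
archetypes anchored to the spread observed in Southeast Asia: incidence
from ~5 to 250 per 100,000, antivenom coverage from ~2% to full, case
fatality under treatment from 0.05% to 15%. Victim strata put ~65% of
victims at working ages (representative death age 45–58) and the rest
past 60, which places the mean residual life expectancy of deaths in the
20–35 year band typical of this disease profile. Costs are drawn on a
USD scale and expressed in local currency through a log-uniform exchange
rate, exercising the currency-conversion path.

What the synthetic data does **not** emulate: correlation between
parameters (e.g. poorer countries having both higher incidence and lower
unit costs), reporting bias in incidence, seasonal or subnational
structure, or any attempt to reproduce a specific country's true values.
Passing tests on synthetic regions therefore demonstrates the
correctness and internal consistency of the machinery, not the accuracy
of any real-world burden estimate — real estimates are only as good as
the country parameter files supplied.

## Numerical choices

* Cohort expectations are kept fractional throughout; rounding happens
  only in display tables (counts to integers, costs to thousand USD).
* Credible intervals use `numpy` linear-interpolation quantiles,
  documented so results are reproducible across implementations.
* Division-by-zero surfaces (`indicated = 0`, zero victims, zero total
  cost) return defined values (access 1.0) or explicit blanks, never
  NaN.
* Composed branch probabilities are checked to [0, 1] with a 1e-12
  tolerance and clamped; a violation raises a consistency error rather
  than propagating.
* Configuration files are strictly validated: versioned schema, unknown
  keys are errors, probabilities bounded, and `victims` vs `incidence`
  cross-checked to 0.5% relative difference when both are given.

## Problem sizes

The test suite and the acceptance script run the model at the sizes the
analyses themselves use: 7-country regions, 1,000-draw PSAs,
1,000-country random sweeps for the tree oracle and conservation
properties, and a 10,000-draw PSA for the single-parameter
quantile-transform check. A full acceptance run completes in a few
seconds on one core.

## Known limitations

* No friction-cost alternative to the human-capital approach, and no
  payer vs out-of-pocket decomposition.
* No antivenom efficacy dose-response; supply is a single annual course
  count with no inter-country trade.
* Mortality and amputation probabilities are age/sex-invariant within a
  country unless strata are configured with overrides.
* The bundled life table and disability weights are reconstructions of
  the standard references, bundled as editable data files; analyses that
  need exact GBD-year values should replace them.
* Regional aggregation assumes independence across countries in the
  PSA; common shocks (e.g. a shared exchange-rate swing) would widen
  true intervals.
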
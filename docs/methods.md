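# Methods

## The adequacy model

Availability of food group *i* in a country-year, `q_i` (kcal/capita/day
available as food, from balance-sheet accounting of production, trade,
stocks, losses and non-food uses), is compared to the Healthy Diet Basket
benchmark `Q_i`.  The proportional shortfall is `s_i = max(0, (Q_i −
q_i)/Q_i)` and the index is `HDBI = 1 − mean(s_i)` over the six groups.
Properties that the test suite enforces:

- bounds `0 ≤ HDBI ≤ 1`, with 1 iff every `q_i ≥ Q_i`;
- monotone nondecreasing in each `q_i`, strictly increasing while
  `q_i < Q_i`, and flat above `Q_i` (no penalty and no credit for excess);
- piecewise linear: below target, `∂HDBI/∂q_i = 1/(6 Q_i)`;
- at the boundary `q_i = Q_i` the shortfall is zero (the open-interval
  condition in the defining sum makes the boundary term vanish either way).

The index is an availability measure under an assumption of perfect
within-country distribution; it is a conservative lower bound on true
shortfalls and deliberately carries no distribution buffer.

Free sugars are outside the basket.  We report `sugar_share =
sugar_kcal/total_kcal` and flag compliance with the WHO guideline as
`sugar_share < 0.10`, reading "less than 10%" strictly (a share of exactly
0.10 violates).

Default targets (kcal/day): starchy staples 1160, fruits 160, vegetables
110, animal-source foods 300, legumes/nuts/seeds 300, oils/fats 300; total
2330.  Targets are data (`data/hdb_targets.csv`) and can be replaced.

## Ingestion choices

Balance-sheet exports come in two methodological eras with a known level
discontinuity around 2010.  We merge at a fixed cutover year (default
2010): years before it come from the old-era table, years from it onward
from the new-era table, with **no** splicing or adjustment — overlap rows
from the losing era are dropped and counted.  Column layouts are mapped
per era through a configurable dialect, and only rows whose element is
daily per-capita dietary energy are kept.  Country codes are normalised to
an ISO3-style key space via a user-supplied alias table; no missing years
are imputed, and countries enter and leave the panel exactly as the data
do.  Floats are parsed with round-trip precision so writing and re-reading
a table is bit-identical.

## Commodity mapping

The mapping from commodity codes to the six groups (plus SUGAR and
EXCLUDED) is a data table, shipped as a best-effort default for standard
FBS item codes and fully overridable.  Defaults worth knowing: plantains
count as starchy staples while bananas are fruits; coconuts, soyabeans and
other oilcrops eaten as foods sit in legumes/nuts/seeds while extracted
oils and raw animal fats (butter, ghee, cream) sit in oils/fats; alcohol,
spices, stimulants, infant foods and aquatic plants are excluded from all
totals.  Unmapped commodities are treated as EXCLUDED with a logged
warning (strict mode raises instead).  `total_kcal` is the six groups plus
sugar; excluded energy is accounted for only in the conservation property
(groups + sugar + excluded = total input kcal, exactly).

## Aggregation

Two pathways, deliberately distinct:

- **Population-weighted per-capita supplies** (regional supply and energy
  totals): region value = Σ pop_c·q_c / Σ pop_c over member countries
  present that year, so regional kcal balances country kcal exactly and
  the world aggregate is invariant to the region partition.
- **Unweighted country means** (decade and projection summaries): the
  country is the unit of analysis; each country contributes its average
  HDBI over the years it has in the decade (no minimum-year threshold by
  default; configurable).

The decade interval is a two-sided 95% *t* interval on the across-country
mean (standard error across countries, n − 1 df).  This choice is
documented rather than inferred — a normal or bootstrap interval would be
a one-line swap — and the interval is undefined (NaN) for a single
country.  Decades default to 1961–1969, full interior decades, and
2020–2022 for the partial final bin.

## Projection

Scenario inputs are trajectories of proportional change per (scenario,
SSP, RCP, unit, group, year) relative to a base year (2010).  Deltas are
cumulative versus the base year — `q_i(t) = q_i(2010)·(1 + δ_i(t))` — not
chained growth rates; a chained interpretation is available behind a flag.
Validation requires `δ ≥ −1`, zero deltas at the base year and no
duplicate keys.  Sugar is held at its base level unless the trajectory
includes a SUGAR group, and units with no trajectory (e.g. high-income
countries outside an investment scenario) are held at base values.
Multi-country aggregates are formed with base-year populations only; an
aggregate with any member missing base-year data is skipped with a
warning.  Projecting then aggregating equals aggregating then projecting
whenever members share identical deltas.

## Synthetic data

The generator emulates the structure the analysis assumes, not real
FAOSTAT marginals.  Regional group means follow logistic curves between a
start and end level (midpoint/rate configurable), with archetypes that
reproduce qualitative dietary-transition shapes: staples flat near or
above target, animal foods and oils rising with income, fruits and
vegetables rising from low bases, legumes declining from a high start in
one archetype.  Countries scatter around their regional curve by a fixed
lognormal factor per (country, group) with 10% spread; each group's energy
is split over 2–6 synthetic commodities with Dirichlet(2) shares fixed per
country; reporting noise is multiplicative lognormal, mean one, per
(country, year, commodity), default scale σ = 0.05.  Populations grow
exponentially at per-country rates in [0.5%, 3%] from bases of 10⁶–10⁸, so
weighted and unweighted aggregation genuinely differ.  Sugar and excluded
commodities are generated so the exclusion logic is exercised.

All randomness derives from one seed through independent streams for
structure, noise, populations and trajectories, so changing σ alone leaves
every structural draw untouched; σ = 0 reproduces the stored ground truth
exactly through the full write→read→map→score pipeline (verified to
1e−9).  Scenario trajectories ramp smoothly (smoothstep) from zero at the
base year to a per-(unit, group) total at 2050, with the investment
scenario adding a strictly positive increment on the directly targeted
groups (staples, animal foods, legumes/oilseeds and oils) and a small
nonnegative indirect increment on fruits and vegetables, so investment
never projects below reference.

What passing tests on synthetic data do **not** show: robustness to real
reporting artifacts (revisions, level breaks beyond the modelled cutover,
informal-trade underreporting), to item-code churn across FAOSTAT
releases, or to real mapping-table ambiguity.  Those require the external
data themselves.

## Problem sizes and numerics

Default simulations use 7 regions × 4 countries over 1961–2022
(~30k records); the recovery checks use 5 regions × 10 countries, which is
enough for decade-mean noise (σ = 0.05) to average below 0.01 while
keeping the suite fast.  Vectorised scoring agrees with the scalar
brute-force evaluation to 1e−12 over 10⁴ random vectors.  Degenerate
inputs: an entity-year whose commodities are all unmapped still appears
(all-zero supplies, HDBI 0); missing group columns score as zero supply
with a warning; a zero `total_kcal` leaves the sugar share undefined
rather than dividing by zero.

## Known limitations

No consumer-waste adjustment, no penalty for excess availability, no
micronutrient adequacy, no subnational or seasonal disaggregation, and no
affordability analysis — the package measures availability against the
basket, nothing more.  The default commodity mapping is a reasonable
reconstruction for standard FBS items and should be replaced with a
project-specific table for serious use.
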
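# hdbasket

Do national food systems supply enough of the *right* foods, not just enough
calories?  `hdbasket` answers that question by scoring food-balance-sheet
(FBS) panels against the **Healthy Diet Basket (HDB)** — the reference diet
of six food groups that UN agencies and the World Bank use to monitor access
to healthy diets.  It is aimed at nutrition and food-policy analysts working
with FAOSTAT-style supply data or scenario outputs from agricultural
economic models.

## The index

The HDB specifies kilocalorie benchmarks `Q_i` for six food groups,
calibrated to the energy needs of a reference adult woman (2330 kcal/day in
total): starchy staples 1160; fruits 160; vegetables 110; animal-source
foods 300; legumes, nuts and seeds 300; oils and fats 300.

For a supply vector `q = (q_1, …, q_6)` of kcal/capita/day available as
food, the **Healthy Diet Basket Index** is one minus the mean proportional
shortfall:

```
HDBI = 1 − (1/6) Σᵢ sᵢ,   sᵢ = max(0, (Qᵢ − qᵢ)/Qᵢ)
```

Shortfalls are equally weighted and an excess in one group never offsets a
deficit in another, so `HDBI ∈ [0, 1]`, with 1 meaning every group meets its
benchmark.  Free sugars are not in the basket; sugar supply is assessed
against the WHO guideline that free sugars stay below 10% of dietary energy.

Around the index the package provides the full analysis pipeline:

- `fbs_io` — read FAOSTAT-style supply exports (old and new era dialects),
  populations and region schemes; merge eras at a fixed cutover year with
  no splicing or level adjustment.
- `food_groups` — map commodities to the six groups (+ sugar and
  exclusions) with a bundled, fully overridable mapping table.
- `hdbi_core` — shortfalls, the index, the WHO sugar-share check.
- `aggregation` — population-weighted regional per-capita supplies,
  decade means of country HDBI with 95% confidence intervals, energy totals.
- `projection` — apply scenario percentage-change trajectories (e.g. from
  a partial-equilibrium model run) to base-year supplies.
- `synthetic_data` — generate realistic FBS-like panels with known ground
  truth, so the whole pipeline is testable without downloads.
- `hdb` CLI — `hdb simulate|ingest|score|aggregate|project|report --config
  cfg.yaml`, plus `hdb all`.

## Worked example

Score a single country-year supply vector:

```python
import hdbasket as hb

targets = hb.HDBTargets.default()
supply = {
    "starchy_staples": 1321.0, "fruits": 88.0, "vegetables": 62.0,
    "animal_source_foods": 241.0, "legumes_nuts_seeds": 119.0, "oils_fats": 305.0,
    "sugar_kcal": 214.0, "total_kcal": 2350.0,
}
score = hb.compute_hdbi(supply, targets)
for g, s in score.shortfalls.items():
    print(f"{g:22s} shortfall {s:.3f}")
print(f"HDBI        = {score.hdbi:.3f}")
print(f"sugar share = {score.sugar_share:.3f} (within WHO limit: {score.sugar_within_limit})")
```

prints

```
starchy_staples        shortfall 0.000
fruits                 shortfall 0.450
vegetables             shortfall 0.436
animal_source_foods    shortfall 0.197
legumes_nuts_seeds     shortfall 0.603
oils_fats              shortfall 0.000
HDBI        = 0.719
sugar share = 0.091 (within WHO limit: True)
```

This country supplies ample staples and oils (zero shortfall; the staples
surplus earns no extra credit), but only about 40% of the legumes benchmark
and roughly half the fruit and vegetable benchmarks, so 71.9% of the basket
is met on average.  Sugar provides 9.1% of energy, just inside the WHO
limit.

Reference points: a diet of staples alone at full energy scores 0.167;
staples plus pulses at their benchmarks score 0.333; four groups at target
with two at half target score 0.833.

End-to-end on synthetic data:

```bash
cat > config.yaml <<EOF
outdir: out
seed: 7
simulate: {n_regions: 7, countries_per_region: 4}
EOF
hdb all --config config.yaml
cat out/report.txt
```

writes country-year scores, region-decade summaries with confidence
intervals, population-weighted energy totals and projected HDBI
trajectories under `out/`, plus a run manifest with the seed and row
counts.

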
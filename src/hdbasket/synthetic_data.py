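"""Synthetic food-balance-sheet panels with known ground truth.

The generator produces everything the analysis pipeline consumes — commodity
records in both era dialects, populations, a region scheme, a commodity
mapping and scenario trajectories — with the statistical structure the
analysis assumes, so every stage can be exercised end-to-end without any
external download.

Structure emulated:

* Per-region, per-food-group mean availability follows a logistic curve
  between a start and an end level, capturing dietary-transition shapes
  (staples plateauing near target, animal-source foods and oils rising,
  legumes declining before recovering, etc.).
* Countries within a region scatter around the regional curve by a fixed
  multiplicative factor per (country, group).
* Each group's kilocalories are split across 2-6 synthetic commodities with
  Dirichlet shares fixed per country, then perturbed by multiplicative
  lognormal noise per (country, year, commodity), mean one, scale ``sigma``.
  With ``sigma = 0`` the summed records reproduce the ground truth exactly.
* Sugar and excluded commodities (spices, stimulants) are included so the
  mapping-exclusion logic is exercised.
* Populations grow exponentially at per-country rates, so population-weighted
  and unweighted aggregation paths differ measurably.

All randomness flows from ``SimConfig.seed`` through independent
``numpy.random`` streams for structure, noise, populations and trajectories;
in particular the noise level can be changed without altering the drawn
commodity shares or country factors.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fbs_io import DEFAULT_REGIONS, RegionScheme
from .hdbi_core import EXCLUDED, GROUPS, SUGAR
from .hdbi_core import score_table


@dataclass(frozen=True)
class GroupTrend:
    """Logistic mean trajectory from ``start`` to ``end`` kcal/capita/day."""

    start: float
    end: float
    midpoint: float = 1990.0
    rate: float = 0.08

    def level(self, years: np.ndarray) -> np.ndarray:
        years = np.asarray(years, dtype=float)
        return self.start + (self.end - self.start) / (
            1.0 + np.exp(-self.rate * (years - self.midpoint))
        )


# Regional archetypes loosely following observed dietary transitions:
# staples flat near or above target, animal foods and oils rising with
# income, fruits/vegetables rising from low bases, legumes declining in
# South Asia from a high start. Levels in kcal/capita/day.
REGION_ARCHETYPES: Mapping[str, Mapping[str, GroupTrend]] = {
    "East Asia & Pacific": {
        "starchy_staples": GroupTrend(1500, 1350, 1985, 0.10),
        "fruits": GroupTrend(30, 170, 1995, 0.12),
        "vegetables": GroupTrend(40, 240, 1995, 0.15),
        "animal_source_foods": GroupTrend(100, 420, 1998, 0.12),
        "legumes_nuts_seeds": GroupTrend(130, 100, 1980, 0.08),
        "oils_fats": GroupTrend(80, 290, 1995, 0.10),
        SUGAR: GroupTrend(60, 160, 1995, 0.08),
        EXCLUDED: GroupTrend(20, 60, 1990, 0.08),
    },
    "Europe & Central Asia": {
        "starchy_staples": GroupTrend(1350, 1150, 1975, 0.10),
        "fruits": GroupTrend(100, 170, 1990, 0.08),
        "vegetables": GroupTrend(80, 130, 1990, 0.08),
        "animal_source_foods": GroupTrend(500, 600, 1985, 0.08),
        "legumes_nuts_seeds": GroupTrend(60, 75, 1995, 0.08),
        "oils_fats": GroupTrend(300, 450, 1985, 0.08),
        SUGAR: GroupTrend(290, 310, 1980, 0.08),
        EXCLUDED: GroupTrend(80, 120, 1990, 0.08),
    },
    "Latin America & Caribbean": {
        "starchy_staples": GroupTrend(1100, 1150, 1990, 0.08),
        "fruits": GroupTrend(120, 165, 1990, 0.08),
        "vegetables": GroupTrend(40, 70, 1995, 0.08),
        "animal_source_foods": GroupTrend(280, 450, 1995, 0.08),
        "legumes_nuts_seeds": GroupTrend(150, 120, 1985, 0.08),
        "oils_fats": GroupTrend(200, 350, 1990, 0.08),
        SUGAR: GroupTrend(340, 390, 1980, 0.08),
        EXCLUDED: GroupTrend(40, 70, 1990, 0.08),
    },
    "North America": {
        "starchy_staples": GroupTrend(900, 1060, 1990, 0.08),
        "fruits": GroupTrend(120, 160, 1990, 0.08),
        "vegetables": GroupTrend(90, 120, 1990, 0.08),
        "animal_source_foods": GroupTrend(600, 660, 1985, 0.08),
        "legumes_nuts_seeds": GroupTrend(90, 115, 1995, 0.08),
        "oils_fats": GroupTrend(450, 700, 1995, 0.08),
        SUGAR: GroupTrend(480, 590, 1990, 0.08),
        EXCLUDED: GroupTrend(90, 130, 1990, 0.08),
    },
    "South Asia": {
        "starchy_staples": GroupTrend(1380, 1450, 1985, 0.08),
        "fruits": GroupTrend(40, 110, 2000, 0.10),
        "vegetables": GroupTrend(30, 95, 2000, 0.10),
        "animal_source_foods": GroupTrend(80, 210, 2000, 0.10),
        "legumes_nuts_seeds": GroupTrend(300, 160, 1975, 0.10),
        "oils_fats": GroupTrend(120, 300, 2000, 0.10),
        SUGAR: GroupTrend(170, 235, 1985, 0.08),
        EXCLUDED: GroupTrend(20, 45, 1995, 0.08),
    },
    "Sub-Saharan Africa": {
        "starchy_staples": GroupTrend(1280, 1400, 1995, 0.06),
        "fruits": GroupTrend(60, 90, 1995, 0.06),
        "vegetables": GroupTrend(40, 65, 1995, 0.06),
        "animal_source_foods": GroupTrend(80, 120, 1995, 0.06),
        "legumes_nuts_seeds": GroupTrend(140, 185, 2000, 0.08),
        "oils_fats": GroupTrend(100, 220, 2000, 0.08),
        SUGAR: GroupTrend(90, 150, 1990, 0.06),
        EXCLUDED: GroupTrend(15, 35, 1990, 0.06),
    },
    "Western Asia & North Africa": {
        "starchy_staples": GroupTrend(1400, 1500, 1985, 0.08),
        "fruits": GroupTrend(100, 160, 1990, 0.08),
        "vegetables": GroupTrend(80, 140, 1990, 0.08),
        "animal_source_foods": GroupTrend(150, 250, 1995, 0.08),
        "legumes_nuts_seeds": GroupTrend(120, 110, 1985, 0.08),
        "oils_fats": GroupTrend(180, 330, 1995, 0.08),
        SUGAR: GroupTrend(200, 280, 1985, 0.08),
        EXCLUDED: GroupTrend(40, 70, 1990, 0.08),
    },
}

#: Groups whose yield gaps the investment scenario targets directly
#: (cereals/roots, animal foods, pulses and oilseeds; not fruits/vegetables).
INVESTMENT_TARGET_GROUPS: tuple[str, ...] = (
    "starchy_staples",
    "animal_source_foods",
    "legumes_nuts_seeds",
    "oils_fats",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study population.

    Defaults emulate the historical analysis window: a 1961-2022 panel over
    seven world regions, moderate reporting noise (``sigma = 0.05``
    lognormal scale per commodity-year) and country-level dispersion of 10%
    around regional mean trajectories.
    """

    n_regions: int = 7
    countries_per_region: int = 4
    start_year: int = 1961
    end_year: int = 2022
    sigma: float = 0.05
    country_sd: float = 0.10
    dirichlet_alpha: float = 2.0
    min_commodities: int = 2
    max_commodities: int = 6
    cutover_year: int = 2010
    pop_base_range: tuple[float, float] = (1e6, 1e8)
    pop_growth_range: tuple[float, float] = (0.005, 0.03)
    seed: int = 0
    trends: Mapping[str, Mapping[str, GroupTrend]] | None = None
    # trajectory generation
    base_year: int = 2010
    horizon_year: int = 2050
    ssp: str = "SSP3"
    rcp: str = "RCP8.5"

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.countries_per_region < 1:
            raise ValueError("need at least one region and one country per region")
        if self.end_year < self.start_year:
            raise ValueError("end_year before start_year")
        if self.sigma < 0 or self.country_sd < 0:
            raise ValueError("noise scales must be nonnegative")
        if not (1 <= self.min_commodities <= self.max_commodities):
            raise ValueError("commodity count bounds invalid")

    @property
    def region_names(self) -> list[str]:
        names = list(DEFAULT_REGIONS)
        while len(names) < self.n_regions:
            names.append(f"Synthetic Region {len(names) + 1}")
        return names[: self.n_regions]

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)


@dataclass
class SimResult:
    """Generated panel plus ground truth.

    ``truth_groups`` holds the noise-free per-(country, year) kcal by group
    (wide, same layout as a food-group supply table); ``truth_scores`` the
    HDBI computed from it.  ``mapping_table`` maps the synthetic commodity
    codes to groups in the standard mapping-file layout.
    """

    records: pd.DataFrame
    populations: pd.DataFrame
    scheme: RegionScheme
    truth_groups: pd.DataFrame
    truth_scores: pd.DataFrame
    mapping_table: pd.DataFrame


def _country_codes(config: SimConfig) -> dict[str, list[str]]:
    """Deterministic ISO3-style codes per region (no randomness involved)."""
    letters = string.ascii_uppercase
    out: dict[str, list[str]] = {}
    idx = 0
    for region in config.region_names:
        codes = []
        for _ in range(config.countries_per_region):
            codes.append("X" + letters[idx // 26] + letters[idx % 26])
            idx += 1
        out[region] = codes
    return out


def _trend_for(config: SimConfig, region: str, group: str) -> GroupTrend:
    trends = config.trends or REGION_ARCHETYPES
    if region in trends and group in trends[region]:
        return trends[region][group]
    # unseen synthetic regions cycle through the archetypes (stable, unsalted)
    keys = list(REGION_ARCHETYPES)
    arch = REGION_ARCHETYPES[keys[sum(ord(c) for c in region) % len(keys)]]
    return arch[group]


def simulate_fbs(config: SimConfig) -> SimResult:
    """Generate a commodity-record panel, populations, scheme and truth."""
    ss = np.random.SeedSequence(config.seed)
    rng_structure, rng_noise, rng_pop, _ = [np.random.default_rng(s) for s in ss.spawn(4)]

    by_region = _country_codes(config)
    years = config.years
    all_groups = [*GROUPS, SUGAR, EXCLUDED]

    # commodity catalogue: k commodities per group, shared across countries
    catalogue: dict[str, list[tuple[str, str]]] = {}
    map_rows = []
    for g in all_groups:
        k = int(rng_structure.integers(config.min_commodities, config.max_commodities + 1))
        items = []
        for j in range(k):
            code = f"S{all_groups.index(g)}{j:02d}"
            name = f"Synthetic {g.replace('_', ' ')} {j + 1}"
            items.append((code, name))
            map_rows.append(
                {
                    "commodity_code": code,
                    "commodity_name": name,
                    "display_aggregate": f"synthetic {g.replace('_', ' ')}",
                    "group": g,
                }
            )
        catalogue[g] = items
    mapping_table = pd.DataFrame(map_rows)

    scheme_rows = []
    rec_frames = []
    truth_rows = []
    pop_rows = []
    for region, codes in by_region.items():
        for ci, code in enumerate(codes):
            scheme_rows.append(
                {
                    "country_code": code,
                    "subregion": f"{region} subregion {ci % 2 + 1}",
                    "region": region,
                }
            )
            pop0 = float(np.exp(rng_pop.uniform(*np.log(config.pop_base_range))))
            rate = float(rng_pop.uniform(*config.pop_growth_range))
            pop_rows.extend(
                {"country_code": code, "year": int(y), "population": pop0 * np.exp(rate * (y - config.start_year))}
                for y in years
            )
            truth_country = {"entity": code}
            levels = {}
            for g in all_groups:
                trend = _trend_for(config, region, g)
                factor = float(np.exp(rng_structure.normal(0.0, config.country_sd)
                                      - config.country_sd ** 2 / 2))
                levels[g] = trend.level(years) * factor
            for g in all_groups:
                items = catalogue[g]
                shares = rng_structure.dirichlet([config.dirichlet_alpha] * len(items))
                lvl = levels[g]
                for (ccode, cname), share in zip(items, shares):
                    if config.sigma > 0:
                        noise = np.exp(
                            rng_noise.normal(-config.sigma ** 2 / 2, config.sigma, len(years))
                        )
                    else:
                        # separate noise stream, so structure draws are
                        # identical across sigma settings
                        noise = np.ones(len(years))
                    kcal = lvl * share * noise
                    rec_frames.append(
                        pd.DataFrame(
                            {
                                "country_code": code,
                                "year": years,
                                "commodity_code": ccode,
                                "commodity_name": cname,
                                "kcal": kcal,
                            }
                        )
                    )
            for yi, y in enumerate(years):
                row = {"entity": code, "year": int(y)}
                for g in GROUPS:
                    row[g] = float(levels[g][yi])
                row["sugar_kcal"] = float(levels[SUGAR][yi])
                row["total_kcal"] = sum(row[g] for g in GROUPS) + row["sugar_kcal"]
                truth_rows.append(row)

    records = pd.concat(rec_frames, ignore_index=True)
    records["era"] = np.where(records["year"] < config.cutover_year, "old", "new")
    populations = pd.DataFrame(pop_rows)
    scheme = RegionScheme(pd.DataFrame(scheme_rows), regions=config.region_names)
    truth_groups = pd.DataFrame(truth_rows)
    truth_scores = score_table(truth_groups)[["entity", "year", "hdbi"]]
    return SimResult(
        records=records,
        populations=populations,
        scheme=scheme,
        truth_groups=truth_groups,
        truth_scores=truth_scores,
        mapping_table=mapping_table,
    )


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def simulate_trajectories(
    config: SimConfig,
    units: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Generate reference and increased-investment scenario trajectories.

    Deltas are cumulative proportional changes versus ``config.base_year``,
    rising smoothly (smoothstep) to a per-(unit, group) total at the horizon.
    By construction the investment-scenario delta is at least the reference
    delta for every group at every year — strictly larger for the directly
    targeted groups — so investment never projects a lower supply.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(4)[3])
    if units is None:
        units = [c for codes in _country_codes(config).values() for c in codes]
    years = np.arange(config.base_year, config.horizon_year + 1)
    frac = _smoothstep((years - config.base_year) / (config.horizon_year - config.base_year))

    ref_totals = {
        "starchy_staples": 0.05,
        "fruits": 0.20,
        "vegetables": 0.25,
        "animal_source_foods": 0.30,
        "legumes_nuts_seeds": 0.10,
        "oils_fats": 0.25,
    }
    rows = []
    for unit in units:
        for g in GROUPS:
            ref_total = max(-0.9, ref_totals[g] + float(rng.uniform(-0.05, 0.05)))
            if g in INVESTMENT_TARGET_GROUPS:
                extra = float(rng.uniform(0.05, 0.15))
            else:
                # indirect income effect on fruits/vegetables: small, nonnegative
                extra = float(rng.uniform(0.0, 0.05))
            for scenario, total in (
                ("reference", ref_total),
                ("increased_investments", ref_total + extra),
            ):
                deltas = total * frac
                rows.extend(
                    {
                        "scenario": scenario,
                        "ssp": config.ssp,
                        "rcp": config.rcp,
                        "unit": unit,
                        "group": g,
                        "year": int(y),
                        "delta": float(d),
                    }
                    for y, d in zip(years, deltas)
                )
    return pd.DataFrame(rows, columns=["scenario", "ssp", "rcp", "unit", "group", "year", "delta"])
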
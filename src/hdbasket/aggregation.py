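"""Regional aggregation, decade summaries and total-energy tables.

Two aggregation pathways coexist and must not be conflated:

* **Population-weighted per-capita supplies** (:func:`regional_supply`,
  :func:`total_energy`): the regional per-capita availability of a food
  group is the population-weighted mean of member-country per-capita values
  — equivalently regional kcal divided by regional population.  This is the
  physically meaningful regional supply.
* **Unweighted country means** (:func:`decade_summary`): summaries of the
  HDBI across countries treat the country as the unit of analysis, so each
  country's decade-average index counts equally regardless of population.

Decades are configurable; by default the first decade runs 1961-1969 (the
balance sheets start in 1961) and the last covers whatever partial span the
data end with (2020-2022 by default).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fbs_io import RegionScheme
from .hdbi_core import GROUPS

logger = logging.getLogger(__name__)

KCAL_COLUMNS = [*GROUPS, "sugar_kcal", "total_kcal"]

#: (label, first year, last year) decade bins.
DEFAULT_DECADES: tuple[tuple[str, int, int], ...] = (
    ("1960s", 1961, 1969),
    ("1970s", 1970, 1979),
    ("1980s", 1980, 1989),
    ("1990s", 1990, 1999),
    ("2000s", 2000, 2009),
    ("2010s", 2010, 2019),
    ("2020s", 2020, 2022),
)


def _attach_region(df: pd.DataFrame, scheme: RegionScheme, by: str) -> pd.DataFrame:
    """Map country entities to 'region'/'subregion'/'world'; drop unmapped."""
    df = df.copy()
    if by == "world":
        df["_agg"] = "World"
        return df
    lookup = scheme._region if by == "region" else scheme._subregion
    df["_agg"] = df["entity"].map(lookup)
    unmapped = df["_agg"].isna()
    if unmapped.any():
        logger.warning(
            "excluding %d rows from unmapped countries: %s",
            int(unmapped.sum()), sorted(df.loc[unmapped, "entity"].unique()),
        )
        df = df[~unmapped]
    return df


def regional_supply(
    country_supplies: pd.DataFrame,
    populations: pd.DataFrame,
    scheme: RegionScheme,
    by: str = "region",
) -> pd.DataFrame:
    """Population-weighted per-capita food-group supply at region level.

    For each region and year, per-capita q_i = sum_c pop_c * q_{c,i} /
    sum_c pop_c over the member countries present that year.  Countries
    missing a population or region assignment are excluded with a warning.
    ``by`` may be "region", "subregion" or "world".
    """
    if by not in ("region", "subregion", "world"):
        raise ValueError(f"by must be region/subregion/world, got {by!r}")
    df = country_supplies.merge(
        populations.rename(columns={"country_code": "entity"}),
        on=["entity", "year"],
        how="left",
    )
    no_pop = df["population"].isna()
    if no_pop.any():
        logger.warning(
            "excluding %d country-years lacking population: %s",
            int(no_pop.sum()), sorted(df.loc[no_pop, "entity"].unique()),
        )
        df = df[~no_pop]
    df = _attach_region(df, scheme, by)
    if df.empty:
        return pd.DataFrame(columns=["entity", "year", *KCAL_COLUMNS])

    cols = [c for c in KCAL_COLUMNS if c in df.columns]

    def _wmean(g: pd.DataFrame) -> pd.Series:
        w = g["population"].to_numpy()
        return pd.Series(
            {c: float(np.dot(w, g[c].to_numpy()) / w.sum()) for c in cols}
        )

    out = (
        df.groupby(["_agg", "year"])[["population", *cols]]
        .apply(_wmean)
        .reset_index()
        .rename(columns={"_agg": "entity"})
    )
    return out[["entity", "year", *cols]]


def decade_summary(
    scores: pd.DataFrame,
    scheme: RegionScheme,
    decades: Sequence[tuple[str, int, int]] = DEFAULT_DECADES,
    *,
    conf_level: float = 0.95,
    min_years: int = 1,
) -> pd.DataFrame:
    """Region-by-decade mean of country HDBI with a t confidence interval.

    Each country contributes its average HDBI over the years it has within
    the decade (at least ``min_years`` of them); the regional mean is the
    unweighted mean across countries, with a two-sided t interval using the
    across-country standard error (n - 1 degrees of freedom).  With a single
    country the interval is undefined (NaN bounds).
    """
    df = scores[["entity", "year", "hdbi"]].copy()
    df = _attach_region(df, scheme, "region")
    rows = []
    for label, start, end in decades:
        sub = df[(df["year"] >= start) & (df["year"] <= end)]
        if sub.empty:
            continue
        per_country = sub.groupby(["_agg", "entity"])["hdbi"].agg(["mean", "size"])
        per_country = per_country[per_country["size"] >= min_years]
        for region, g in per_country.groupby(level="_agg"):
            vals = g["mean"].to_numpy()
            n = len(vals)
            mean = float(vals.mean())
            if n >= 2:
                se = float(vals.std(ddof=1)) / np.sqrt(n)
                half = float(stats.t.ppf(0.5 + conf_level / 2, n - 1)) * se
                lo, hi = mean - half, mean + half
            else:
                lo = hi = float("nan")
            rows.append(
                {
                    "region": region,
                    "decade": label,
                    "mean_hdbi": mean,
                    "ci_low": lo,
                    "ci_high": hi,
                    "n_countries": n,
                }
            )
    return pd.DataFrame(
        rows, columns=["region", "decade", "mean_hdbi", "ci_low", "ci_high", "n_countries"]
    )


def total_energy(
    country_supplies: pd.DataFrame,
    populations: pd.DataFrame,
    scheme: RegionScheme,
    periods: Sequence[tuple[str, int, int]] = (("1960s", 1961, 1969), ("2020s", 2020, 2022)),
    *,
    include_world: bool = True,
) -> pd.DataFrame:
    """Mean daily per-capita energy by region and period, plus a World row.

    Region-year values come from the population-weighted
    :func:`regional_supply` pathway; the period mean averages those yearly
    values.  The World row aggregates over all countries directly, so it is
    invariant to how countries are partitioned into regions.
    """
    regional = regional_supply(country_supplies, populations, scheme, by="region")
    frames = [regional]
    if include_world:
        frames.append(regional_supply(country_supplies, populations, scheme, by="world"))
    both = pd.concat(frames, ignore_index=True)
    rows = []
    for label, start, end in periods:
        sub = both[(both["year"] >= start) & (both["year"] <= end)]
        if sub.empty:
            continue
        agg = sub.groupby("entity")["total_kcal"].mean()
        for entity, kcal in agg.items():
            rows.append({"region": entity, "period": label, "mean_total_kcal": float(kcal)})
    return pd.DataFrame(rows, columns=["region", "period", "mean_total_kcal"])
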
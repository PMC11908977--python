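"""Scenario projection: apply percentage-change trajectories to base-year supplies.

Partial-equilibrium model runs (IMPACT-style) are consumed only as
trajectories of proportional change in each food group's availability
relative to a base year (2010 by default).  Projected supply is

    q_i(t) = q_i(base) * (1 + delta_i(t)),

i.e. deltas are cumulative changes versus the base year, not chained
year-on-year growth rates (``chained=True`` selects the chained reading).
The HDBI of the projected vector is then computed with the standard targets.

Units may be single countries or multi-country aggregates; aggregates are
formed from member countries with base-year populations only
(:func:`combine_country_aggregates`).  Units that appear in the base supply
but carry no trajectory (e.g. high-income countries outside the investment
scenarios) are held at base values.  Sugar is held at its base level unless
the trajectory file includes a SUGAR group.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hdbi_core import GROUPS, SUGAR, HDBTargets, score_table

logger = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = ("scenario", "ssp", "rcp", "unit", "group", "year", "delta")

DEFAULT_BASE_YEAR = 2010


def validate_trajectories(df: pd.DataFrame, base_year: int = DEFAULT_BASE_YEAR) -> pd.DataFrame:
    """Check trajectory invariants: delta >= -1, base-year rows = 0, no duplicates."""
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns {sorted(missing)}")
    df = df.copy()
    df["year"] = df["year"].astype(int)
    df["delta"] = df["delta"].astype(float)
    if (df["delta"] < -1).any():
        bad = df.index[df["delta"] < -1][:5].tolist()
        raise ValueError(f"delta < -1 (supply cannot fall below zero) at rows {bad}")
    key = ["scenario", "ssp", "rcp", "unit", "group", "year"]
    if df.duplicated(subset=key).any():
        raise ValueError("duplicate (scenario, ssp, rcp, unit, group, year) rows")
    series_key = ["scenario", "ssp", "rcp", "unit", "group"]
    base = df[df["year"] == base_year]
    have_base = set(map(tuple, base[series_key].itertuples(index=False)))
    all_series = set(map(tuple, df[series_key].drop_duplicates().itertuples(index=False)))
    if all_series - have_base:
        raise ValueError(
            f"{len(all_series - have_base)} trajectory series lack a base-year "
            f"({base_year}) row"
        )
    if (base["delta"].abs() > 1e-12).any():
        raise ValueError(f"base-year ({base_year}) deltas must be zero")
    bad_groups = set(df["group"]) - set(GROUPS) - {SUGAR}
    if bad_groups:
        raise ValueError(f"unknown trajectory groups: {sorted(bad_groups)}")
    return df


def load_trajectories(path: str | Path, base_year: int = DEFAULT_BASE_YEAR) -> pd.DataFrame:
    """Read and validate a trajectory table from delimited text."""
    df = pd.read_csv(path)
    return validate_trajectories(df, base_year)


def apply_changes(
    base: pd.DataFrame,
    trajectories: pd.DataFrame,
    targets: HDBTargets | None = None,
    *,
    base_year: int = DEFAULT_BASE_YEAR,
    chained: bool = False,
    hold_missing_units: bool = True,
) -> pd.DataFrame:
    """Project food-group supplies and HDBI under each scenario trajectory.

    ``base`` is a food-group supply table restricted to the base year (one
    row per unit).  Returns one row per (scenario, ssp, rcp, unit, year)
    with projected q columns, ``sugar_kcal``, ``total_kcal`` and ``hdbi``.
    A trajectory group absent from the base supply raises; base units
    without any trajectory are carried at base values for every projection
    year when ``hold_missing_units``.
    """
    targets = targets or HDBTargets.default()
    traj = validate_trajectories(trajectories, base_year)
    base = base.copy()
    if "year" in base.columns:
        wrong = base["year"] != base_year
        if wrong.any():
            raise ValueError(
                f"base supply must be the base year {base_year}; found years "
                f"{sorted(base.loc[wrong, 'year'].unique())}"
            )
    base = base.set_index("entity")
    unknown_units = set(traj["unit"]) - set(base.index)
    if unknown_units:
        raise ValueError(f"trajectory units absent from base supply: {sorted(unknown_units)}")

    traj_groups = sorted(set(traj["group"]))
    for g in traj_groups:
        col = "sugar_kcal" if g == SUGAR else g
        if col not in base.columns:
            raise ValueError(f"trajectory group {g!r} absent from base supply")

    if chained:
        traj = traj.sort_values("year").copy()
        grp = traj.groupby(["scenario", "ssp", "rcp", "unit", "group"])["delta"]
        traj["_factor"] = grp.transform(lambda d: (1.0 + d).cumprod())
    else:
        traj["_factor"] = 1.0 + traj["delta"]

    wide = traj.pivot_table(
        index=["scenario", "ssp", "rcp", "unit", "year"],
        columns="group",
        values="_factor",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None

    if hold_missing_units:
        scenario_years = traj[["scenario", "ssp", "rcp", "year"]].drop_duplicates()
        have = set(wide["unit"])
        held = [u for u in base.index if u not in have]
        if held:
            extra = scenario_years.merge(pd.DataFrame({"unit": held}), how="cross")
            wide = pd.concat([wide, extra], ignore_index=True)

    rows = wide.copy()
    for g in GROUPS:
        factor = rows[g].fillna(1.0) if g in rows.columns else 1.0
        rows[g] = base[g].reindex(rows["unit"]).to_numpy() * np.asarray(factor)
    sugar_base = (
        base["sugar_kcal"].reindex(rows["unit"]).to_numpy()
        if "sugar_kcal" in base.columns
        else np.zeros(len(rows))
    )
    sugar_factor = rows[SUGAR].fillna(1.0).to_numpy() if SUGAR in rows.columns else 1.0
    rows["sugar_kcal"] = sugar_base * sugar_factor
    rows = rows.drop(columns=[SUGAR], errors="ignore")
    rows["total_kcal"] = rows[list(GROUPS)].sum(axis=1) + rows["sugar_kcal"]

    supply = rows.rename(columns={"unit": "entity"})
    scored = score_table(supply, targets)
    out = pd.concat(
        [
            supply[["scenario", "ssp", "rcp", "entity", "year", *GROUPS,
                    "sugar_kcal", "total_kcal"]].reset_index(drop=True),
            scored[["hdbi"]].reset_index(drop=True),
        ],
        axis=1,
    ).rename(columns={"entity": "unit"})
    return out.sort_values(["scenario", "ssp", "rcp", "unit", "year"]).reset_index(drop=True)


def combine_country_aggregates(
    member_supplies: pd.DataFrame,
    pop_base: pd.DataFrame,
    membership: Mapping[str, Sequence[str]],
    *,
    base_year: int = DEFAULT_BASE_YEAR,
) -> pd.DataFrame:
    """Population-weighted base-year supply for multi-country aggregates.

    ``membership`` maps aggregate name -> member country codes.  An
    aggregate with any member missing base-year supply or population is
    skipped with a warning (mirroring the treatment of small-island
    aggregates whose members never report).
    """
    sup = member_supplies[member_supplies["year"] == base_year].set_index("entity")
    pop = pop_base[pop_base["year"] == base_year].set_index("country_code")["population"]
    cols = [c for c in [*GROUPS, "sugar_kcal", "total_kcal"] if c in sup.columns]
    rows = []
    for agg, members in membership.items():
        members = list(members)
        missing = [m for m in members if m not in sup.index or m not in pop.index]
        if missing:
            logger.warning(
                "aggregate %r skipped: members missing base-year data: %s", agg, missing
            )
            continue
        w = pop.loc[members].to_numpy(dtype=float)
        rec = {"entity": agg, "year": base_year}
        for c in cols:
            rec[c] = float(np.dot(w, sup.loc[members, c].to_numpy(dtype=float)) / w.sum())
        rows.append(rec)
    return pd.DataFrame(rows, columns=["entity", "year", *cols])


def project_summary(
    results: pd.DataFrame,
    scheme=None,
    *,
    include_world: bool = True,
) -> pd.DataFrame:
    """Unweighted mean projected HDBI per region, scenario and year.

    ``scheme`` maps units to regions (units without a region are pooled
    only into the World mean).  Returns rows (region, scenario, ssp, rcp,
    year, mean_hdbi, n_units).
    """
    df = results.copy()
    frames = []
    if scheme is not None:
        df["region"] = df["unit"].map(scheme._region)
        known = df[df["region"].notna()]
        if len(known):
            frames.append(known)
    if include_world:
        world = df.copy()
        world["region"] = "World"
        frames.append(world)
    if not frames:
        return pd.DataFrame(
            columns=["region", "scenario", "ssp", "rcp", "year", "mean_hdbi", "n_units"]
        )
    allrows = pd.concat(frames, ignore_index=True)
    out = (
        allrows.groupby(["region", "scenario", "ssp", "rcp", "year"], as_index=False)
        .agg(mean_hdbi=("hdbi", "mean"), n_units=("hdbi", "size"))
    )
    return out
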
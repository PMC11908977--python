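"""Commodity-to-food-group mapping and per-entity food-group supply tables.

Each food-balance-sheet commodity is assigned to one of the six HDB food
groups, to SUGAR, or to EXCLUDED (spices, beverages, stimulants, infant
foods and alcohol contribute to none of the reported totals).  Small
commodities may share a ``display_aggregate`` (e.g. demersal, pelagic and
other marine fish are all displayed as "other marine fish") used only for
composition reporting; the grouping itself is unaffected.

A best-effort default mapping for standard FBS items ships as package data
and is fully user-overridable — the mapping is data, not code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .hdbi_core import EXCLUDED, GROUPS, SUGAR

logger = logging.getLogger(__name__)

#: Legal group labels in a mapping file.
VALID_GROUP_LABELS: frozenset[str] = frozenset(GROUPS) | {SUGAR, EXCLUDED}

_MAPPING_COLUMNS = ("commodity_code", "commodity_name", "display_aggregate", "group")


@dataclass
class CommodityMapping:
    """Lookup from commodity code to HDB group and display aggregate."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        missing = set(_MAPPING_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"mapping missing columns: {sorted(missing)}")
        df = df.copy()
        df["commodity_code"] = df["commodity_code"].astype(str)
        dup = df["commodity_code"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate commodity codes: {sorted(df.loc[dup, 'commodity_code'])}"
            )
        bad = set(df["group"]) - VALID_GROUP_LABELS
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        df["display_aggregate"] = df["display_aggregate"].fillna(df["commodity_name"])
        self.table = df.reset_index(drop=True)
        self._by_code = df.set_index("commodity_code")

    def group_of(self, commodity_code: str) -> str | None:
        """Group label for a code, or None when unmapped."""
        try:
            return str(self._by_code.at[str(commodity_code), "group"])
        except KeyError:
            return None

    def display_of(self, commodity_code: str) -> str | None:
        try:
            return str(self._by_code.at[str(commodity_code), "display_aggregate"])
        except KeyError:
            return None

    def __contains__(self, commodity_code: str) -> bool:
        return str(commodity_code) in self._by_code.index

    def __len__(self) -> int:
        return len(self.table)


def load_mapping(path: str | Path) -> CommodityMapping:
    """Read a commodity mapping from a delimited text file.

    Expected columns: commodity_code, commodity_name, display_aggregate,
    group.  An empty display_aggregate falls back to the commodity name.
    """
    df = pd.read_csv(path, dtype=str)
    return CommodityMapping(df)


def default_mapping() -> CommodityMapping:
    """The bundled best-effort mapping for standard FBS item codes."""
    with resources.as_file(
        resources.files("hdbasket.data") / "default_commodity_mapping.csv"
    ) as p:
        return load_mapping(p)


def _grouped(records: pd.DataFrame, mapping: CommodityMapping, strict: bool) -> pd.DataFrame:
    df = records.copy()
    df["commodity_code"] = df["commodity_code"].astype(str)
    df["group"] = df["commodity_code"].map(mapping._by_code["group"])
    unmapped = df["group"].isna()
    if unmapped.any():
        codes = sorted(df.loc[unmapped, "commodity_code"].unique())
        if strict:
            raise ValueError(f"unmapped commodity codes: {codes}")
        logger.warning(
            "%d rows with unmapped commodities treated as EXCLUDED: %s",
            int(unmapped.sum()), codes,
        )
        df.loc[unmapped, "group"] = EXCLUDED
    return df


def group_supply(
    records: pd.DataFrame,
    mapping: CommodityMapping | None = None,
    *,
    strict: bool = False,
) -> pd.DataFrame:
    """Aggregate commodity records to per-(entity, year) food-group supply.

    Returns a wide table with columns ``entity``, ``year``, one column per
    HDB group (the q_i), ``sugar_kcal`` and ``total_kcal``.  EXCLUDED
    commodities contribute to none of these; ``total_kcal`` is the sum of
    the six groups plus sugar.
    """
    mapping = mapping or default_mapping()
    entity_col = "entity" if "entity" in records.columns else "country_code"
    if records.empty:
        return pd.DataFrame(
            columns=["entity", "year", *GROUPS, "sugar_kcal", "total_kcal"]
        )
    all_pairs = records[[entity_col, "year"]].drop_duplicates()
    df = _grouped(records, mapping, strict)
    df = df[df["group"] != EXCLUDED]
    wide = (
        df.pivot_table(
            index=[entity_col, "year"],
            columns="group",
            values="kcal",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(pd.MultiIndex.from_frame(all_pairs))
        .fillna(0.0)
        .reset_index()
        .rename(columns={entity_col: "entity", SUGAR: "sugar_kcal"})
    )
    wide.columns.name = None
    for g in GROUPS:
        if g not in wide.columns:
            wide[g] = 0.0
    if "sugar_kcal" not in wide.columns:
        wide["sugar_kcal"] = 0.0
    wide["total_kcal"] = wide[list(GROUPS)].sum(axis=1) + wide["sugar_kcal"]
    return wide[["entity", "year", *GROUPS, "sugar_kcal", "total_kcal"]]


def composition(
    records: pd.DataFrame,
    mapping: CommodityMapping | None = None,
    *,
    strict: bool = False,
) -> pd.DataFrame:
    """Kcal by display aggregate within each group, per entity-year.

    Rows for a group sum exactly to that group's q_i in :func:`group_supply`
    (SUGAR aggregates likewise sum to ``sugar_kcal``).
    """
    mapping = mapping or default_mapping()
    entity_col = "entity" if "entity" in records.columns else "country_code"
    if records.empty:
        return pd.DataFrame(columns=["entity", "year", "display_aggregate", "group", "kcal"])
    df = _grouped(records, mapping, strict)
    df = df[df["group"] != EXCLUDED]
    df["display_aggregate"] = (
        df["commodity_code"].map(mapping._by_code["display_aggregate"])
        .fillna(df.get("commodity_name", df["commodity_code"]))
    )
    out = (
        df.groupby([entity_col, "year", "display_aggregate", "group"], as_index=False)[
            "kcal"
        ]
        .sum()
        .rename(columns={entity_col: "entity"})
    )
    return out
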
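"""Reading and merging food-balance-sheet tables, populations and region schemes.

Food balance sheets (FBS) report the daily per-capita dietary energy
available in each country and year, by commodity.  Two "eras" of the FBS
exist: the historical series (through 2009/2013, compiled under the old
balancing methodology) and the current series (2010 onward).  The
methodological change introduces a level discontinuity between eras; this
module performs NO splicing or adjustment — data are passed through as
published, with the new era winning at a fixed cutover year.

Column layouts drift between FAOSTAT exports, so each era is read through a
configurable :class:`EraDialect` (column-name map plus the element label that
identifies kcal/capita/day rows).  Country codes are normalised to an
ISO3-style key space through an optional alias table so region-scheme joins
share one key space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

YEAR_MIN, YEAR_MAX = 1961, 2100

ERAS = ("old", "new")

#: The seven default world regions (configuration, not hard-coded logic).
DEFAULT_REGIONS: tuple[str, ...] = (
    "East Asia & Pacific",
    "Europe & Central Asia",
    "Latin America & Caribbean",
    "North America",
    "South Asia",
    "Sub-Saharan Africa",
    "Western Asia & North Africa",
)

#: Canonical record columns produced by :func:`read_supply_table`.
RECORD_COLUMNS = ("country_code", "year", "commodity_code", "commodity_name", "kcal", "era")


@dataclass(frozen=True)
class EraDialect:
    """How to interpret one era's export layout.

    ``columns`` maps canonical field names (country_code, year,
    commodity_code, commodity_name, kcal, element) to the column labels in
    the file; ``element_keep`` is the element label identifying daily
    per-capita dietary energy rows — all other elements are dropped with a
    logged count.
    """

    columns: Mapping[str, str]
    element_keep: str | None = "Food supply (kcal/capita/day)"


_FAOSTAT_COLUMNS = {
    "country_code": "Area Code (ISO3)",
    "year": "Year",
    "commodity_code": "Item Code",
    "commodity_name": "Item",
    "kcal": "Value",
    "element": "Element",
}

DEFAULT_DIALECTS: Mapping[str, EraDialect] = {
    "old": EraDialect(columns=dict(_FAOSTAT_COLUMNS)),
    "new": EraDialect(columns=dict(_FAOSTAT_COLUMNS)),
}


def normalize_country_codes(
    df: pd.DataFrame,
    aliases: Mapping[str, str] | None = None,
    column: str = "country_code",
) -> pd.DataFrame:
    """Uppercase codes and apply an alias table (historical entities etc.)."""
    df = df.copy()
    df[column] = df[column].astype(str).str.strip().str.upper()
    if aliases:
        up = {str(k).upper(): str(v).upper() for k, v in aliases.items()}
        df[column] = df[column].map(lambda c: up.get(c, c))
    return df


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce commodity-record invariants; raise on violation."""
    neg = df.index[df["kcal"] < 0]
    if len(neg):
        raise ValueError(f"negative kcal at rows {neg[:5].tolist()}")
    bad_year = df.index[(df["year"] < YEAR_MIN) | (df["year"] > YEAR_MAX)]
    if len(bad_year):
        raise ValueError(
            f"year outside [{YEAR_MIN}, {YEAR_MAX}] at rows {bad_year[:5].tolist()}"
        )
    key = ["country_code", "year", "commodity_code"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValueError(
            f"duplicate (country, year, commodity) keys: "
            f"{df.loc[dup, key].head().to_dict('records')}"
        )
    return df


def read_supply_table(
    path: str | Path,
    era: str,
    dialect: EraDialect | None = None,
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read one era's FBS export into validated commodity records.

    Rows whose element is not daily per-capita dietary energy are dropped
    (count logged).  Returns a DataFrame with :data:`RECORD_COLUMNS`; kcal
    values pass through bit-identically.
    """
    if era not in ERAS:
        raise ValueError(f"era must be one of {ERAS}, got {era!r}")
    dialect = dialect or DEFAULT_DIALECTS[era]
    raw = pd.read_csv(path, float_precision="round_trip")
    colmap = dialect.columns
    required = ["country_code", "year", "commodity_code", "commodity_name", "kcal"]
    for canon in required:
        if colmap[canon] not in raw.columns:
            raise ValueError(
                f"{path}: required column {colmap[canon]!r} (for {canon!r}) not found"
            )
    if dialect.element_keep is not None and colmap.get("element") in raw.columns:
        keep = raw[colmap["element"]] == dialect.element_keep
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("%s: dropped %d non-energy element rows", path, n_drop)
        raw = raw[keep]
    df = pd.DataFrame(
        {
            "country_code": raw[colmap["country_code"]].astype(str),
            "year": raw[colmap["year"]],
            "commodity_code": raw[colmap["commodity_code"]].astype(str),
            "commodity_name": raw[colmap["commodity_name"]].astype(str),
            "kcal": raw[colmap["kcal"]],
        }
    )
    if df.empty:
        logger.warning("%s: no data rows", path)
        df["year"] = df["year"].astype(int)
        df["kcal"] = df["kcal"].astype(float)
        df["era"] = pd.Series(dtype=str)
        return df.reset_index(drop=True)
    try:
        df["year"] = df["year"].astype(int)
    except (ValueError, TypeError) as e:
        raise ValueError(f"{path}: unparseable year values ({e})") from e
    df["kcal"] = df["kcal"].astype(float)
    df = normalize_country_codes(df, aliases)
    df["era"] = era
    return validate_records(df.reset_index(drop=True))


def write_supply_table(
    records: pd.DataFrame, path: str | Path, era: str, dialect: EraDialect | None = None
) -> None:
    """Write records in the era's file dialect (inverse of the reader)."""
    dialect = dialect or DEFAULT_DIALECTS[era]
    colmap = dialect.columns
    out = pd.DataFrame(
        {
            colmap["country_code"]: records["country_code"],
            colmap["commodity_code"]: records["commodity_code"],
            colmap["commodity_name"]: records["commodity_name"],
            colmap["year"]: records["year"],
            colmap["kcal"]: records["kcal"],
        }
    )
    if dialect.element_keep is not None and "element" in colmap:
        out[colmap["element"]] = dialect.element_keep
    out.to_csv(path, index=False)


def merge_eras(
    old_table: pd.DataFrame,
    new_table: pd.DataFrame,
    cutover_year: int = 2010,
) -> pd.DataFrame:
    """Concatenate eras at a fixed cutover: new era wins from ``cutover_year``.

    No statistical splicing or level adjustment is performed (the known
    methodological discontinuity between eras is left as published).  Rows
    from the losing era in the overlap are dropped and counted in the log.
    """
    if old_table.empty and new_table.empty:
        raise ValueError("both era tables are empty")
    for tbl, name in ((old_table, "old"), (new_table, "new")):
        if not tbl.empty:
            validate_records(tbl)
    old_keep = old_table[old_table["year"] < cutover_year] if not old_table.empty else old_table
    new_keep = new_table[new_table["year"] >= cutover_year] if not new_table.empty else new_table
    n_drop_old = len(old_table) - len(old_keep)
    n_drop_new = len(new_table) - len(new_keep)
    if n_drop_old or n_drop_new:
        logger.info(
            "merge_eras: dropped %d old-era rows >= %d and %d new-era rows < %d",
            n_drop_old, cutover_year, n_drop_new, cutover_year,
        )
    merged = pd.concat([old_keep, new_keep], ignore_index=True)
    if merged.empty:
        raise ValueError("merged panel is empty after cutover filtering")
    return merged


def read_population(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a (country_code, year, population) table; persons, > 0."""
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"country_code", "year", "population"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: population table missing columns {sorted(missing)}")
    df = normalize_country_codes(df[list(needed)].copy(), aliases)
    df["year"] = df["year"].astype(int)
    df["population"] = df["population"].astype(float)
    if (df["population"] <= 0).any():
        bad = df.index[df["population"] <= 0][:5].tolist()
        raise ValueError(f"{path}: nonpositive population at rows {bad}")
    if df.duplicated(subset=["country_code", "year"]).any():
        raise ValueError(f"{path}: duplicate (country, year) population rows")
    return df[["country_code", "year", "population"]]


@dataclass
class RegionScheme:
    """Country -> subregion -> world region mapping.

    The region list is configuration (default: the seven world regions in
    :data:`DEFAULT_REGIONS`); every country maps to exactly one subregion
    and one region.
    """

    table: pd.DataFrame = field(repr=False)
    regions: Sequence[str] = DEFAULT_REGIONS

    def __post_init__(self) -> None:
        df = self.table
        needed = {"country_code", "subregion", "region"}
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"region scheme missing columns: {sorted(missing)}")
        df = normalize_country_codes(df.copy())
        if df["country_code"].duplicated().any():
            dups = sorted(df.loc[df["country_code"].duplicated(), "country_code"])
            raise ValueError(f"countries mapped more than once: {dups}")
        unknown = set(df["region"]) - set(self.regions)
        if unknown:
            raise ValueError(
                f"unknown region names {sorted(unknown)}; configured: {list(self.regions)}"
            )
        self.table = df.reset_index(drop=True)
        self._region = df.set_index("country_code")["region"]
        self._subregion = df.set_index("country_code")["subregion"]

    def region_of(self, country_code: str) -> str | None:
        """World region for a country, or None when unmapped."""
        return self._region.get(str(country_code).upper())

    def subregion_of(self, country_code: str) -> str | None:
        return self._subregion.get(str(country_code).upper())

    def is_mapped(self, country_code: str) -> bool:
        return str(country_code).upper() in self._region.index

    def countries_in(self, region: str) -> list[str]:
        return sorted(self._region.index[self._region == region])

    def __len__(self) -> int:
        return len(self.table)


def read_region_scheme(
    path: str | Path, regions: Sequence[str] = DEFAULT_REGIONS
) -> RegionScheme:
    """Read a (country_code, subregion, region) scheme from delimited text."""
    df = pd.read_csv(path)
    return RegionScheme(df, regions=regions)
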
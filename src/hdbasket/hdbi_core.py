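"""Healthy Diet Basket Index (HDBI): per-group shortfalls and the adequacy index.

The Healthy Diet Basket (HDB) specifies kilocalorie benchmarks for six food
groups, calibrated to the energy needs of a reference adult woman (2330
kcal/day in total).  For a supply vector ``q = (q_1, ..., q_6)`` of available
kilocalories per capita per day, the index is

    HDBI = 1 - (1/6) * sum_i s_i,      s_i = max(0, (Q_i - q_i) / Q_i),

where ``Q_i`` is the HDB target for group *i*.  Shortfalls are equally
weighted and an excess in one group never offsets a shortfall in another, so
HDBI lies in [0, 1] and equals 1 exactly when every group meets its target.

Free sugars are not part of the basket; supply of sugar is assessed against
the WHO guideline that free sugars provide less than 10% of dietary energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six HDB food groups, in canonical order.
GROUPS: tuple[str, ...] = (
    "starchy_staples",
    "fruits",
    "vegetables",
    "animal_source_foods",
    "legumes_nuts_seeds",
    "oils_fats",
)

#: Sentinel group labels used by the commodity mapping.
SUGAR = "SUGAR"
EXCLUDED = "EXCLUDED"

#: Default HDB targets, kcal/capita/day per group (they sum to 2330).
DEFAULT_TARGET_KCAL: Mapping[str, float] = {
    "starchy_staples": 1160.0,
    "fruits": 160.0,
    "vegetables": 110.0,
    "animal_source_foods": 300.0,
    "legumes_nuts_seeds": 300.0,
    "oils_fats": 300.0,
}

#: WHO guideline: free sugars below 10% of total dietary energy (strict).
SUGAR_SHARE_LIMIT = 0.10


@dataclass(frozen=True)
class HDBTargets:
    """Kilocalorie targets Q_i for the six HDB food groups.

    Parameters
    ----------
    targets
        Mapping from each of the six group names to a positive kcal/day
        target.  Exactly the six canonical groups must be present.
    """

    targets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_KCAL)
    )

    def __post_init__(self) -> None:
        missing = set(GROUPS) - set(self.targets)
        extra = set(self.targets) - set(GROUPS)
        if missing:
            raise ValueError(f"targets missing groups: {sorted(missing)}")
        if extra:
            raise ValueError(f"unknown target groups: {sorted(extra)}")
        for g, q in self.targets.items():
            if not np.isfinite(q) or q <= 0:
                raise ValueError(f"target for {g!r} must be positive, got {q}")

    def __getitem__(self, group: str) -> float:
        return float(self.targets[group])

    @property
    def total(self) -> float:
        """Total basket energy, kcal/day (2330 for the default basket)."""
        return float(sum(self.targets.values()))

    def as_array(self) -> np.ndarray:
        """Targets as a vector in canonical group order."""
        return np.array([self.targets[g] for g in GROUPS], dtype=float)

    @classmethod
    def default(cls) -> "HDBTargets":
        return cls()

    @classmethod
    def from_file(cls, path: str | Path) -> "HDBTargets":
        """Read targets from a two-column delimited file (group, kcal)."""
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "group" not in cols or "kcal" not in cols:
            raise ValueError(
                f"targets file {path} must have columns 'group' and 'kcal'"
            )
        return cls(dict(zip(df[cols["group"]], df[cols["kcal"]].astype(float))))


def shortfall(q: float, Q: float) -> float:
    """Proportional shortfall of supply ``q`` below target ``Q``.

    Returns ``(Q - q)/Q`` when ``q < Q`` and 0 otherwise; a supply exactly at
    target has zero shortfall, and excess earns no credit.
    """
    if Q <= 0:
        raise ValueError(f"target must be positive, got {Q}")
    if q < 0:
        raise ValueError(f"supply must be nonnegative, got {q}")
    return max(0.0, (Q - q) / Q)


@dataclass
class HDBIScore:
    """HDBI result for one entity-year."""

    entity: str
    year: int
    shortfalls: dict[str, float]
    hdbi: float
    sugar_share: float | None = None
    sugar_within_limit: bool | None = None


def compute_hdbi(
    supply: Mapping[str, object] | pd.Series,
    targets: HDBTargets | None = None,
    *,
    strict: bool = False,
) -> HDBIScore:
    """Compute the HDBI for a single entity-year supply record.

    ``supply`` holds kcal/capita/day under the six group names and optionally
    ``entity``, ``year``, ``sugar_kcal`` and ``total_kcal``.  A missing group
    is treated as zero supply with a warning (an error when ``strict``),
    because sparse balance-sheet country-years genuinely lack some groups.
    """
    targets = targets or HDBTargets.default()
    q = {}
    for g in GROUPS:
        v = supply.get(g) if hasattr(supply, "get") else supply[g]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            if strict:
                raise ValueError(f"group {g!r} absent from supply record")
            logger.warning("group %r absent; treated as zero supply", g)
            v = 0.0
        v = float(v)
        if v < 0:
            raise ValueError(f"negative supply for {g!r}: {v}")
        q[g] = v

    s = {g: shortfall(q[g], targets[g]) for g in GROUPS}
    hdbi = 1.0 - sum(s.values()) / len(GROUPS)

    sugar_share: float | None = None
    within: bool | None = None
    sugar = supply.get("sugar_kcal") if hasattr(supply, "get") else None
    total = supply.get("total_kcal") if hasattr(supply, "get") else None
    if sugar is not None and total is not None and not pd.isna(sugar) and not pd.isna(total):
        if float(total) > 0:
            sugar_share = float(sugar) / float(total)
            within = sugar_share < SUGAR_SHARE_LIMIT

    return HDBIScore(
        entity=str(supply.get("entity", "") if hasattr(supply, "get") else ""),
        year=int(supply.get("year", 0) if hasattr(supply, "get") else 0),
        shortfalls=s,
        hdbi=hdbi,
        sugar_share=sugar_share,
        sugar_within_limit=within,
    )


def score_table(
    supplies: pd.DataFrame, targets: HDBTargets | None = None
) -> pd.DataFrame:
    """Vectorised HDBI over a food-group supply table.

    ``supplies`` must have columns ``entity``, ``year`` and the six group
    names (``sugar_kcal``/``total_kcal`` optional).  Returns one row per
    input row with per-group shortfall columns ``s_<group>``, ``hdbi``,
    ``sugar_share`` and ``sugar_within_limit``.
    """
    targets = targets or HDBTargets.default()
    if supplies.empty:
        cols = ["entity", "year"] + [f"s_{g}" for g in GROUPS]
        cols += ["hdbi", "sugar_share", "sugar_within_limit"]
        return pd.DataFrame(columns=cols)

    q = np.zeros((len(supplies), len(GROUPS)))
    for j, g in enumerate(GROUPS):
        if g in supplies.columns:
            col = supplies[g].to_numpy(dtype=float)
            col = np.where(np.isnan(col), 0.0, col)
        else:
            logger.warning("group column %r absent; treated as zero", g)
            col = np.zeros(len(supplies))
        if (col < 0).any():
            bad = supplies.index[col < 0][:5].tolist()
            raise ValueError(f"negative supply in column {g!r}, rows {bad}")
        q[:, j] = col

    Q = targets.as_array()
    s = np.clip((Q[None, :] - q) / Q[None, :], 0.0, None)
    out = pd.DataFrame(
        {"entity": supplies["entity"].to_numpy(), "year": supplies["year"].to_numpy()}
    )
    for j, g in enumerate(GROUPS):
        out[f"s_{g}"] = s[:, j]
    out["hdbi"] = 1.0 - s.mean(axis=1)

    if "sugar_kcal" in supplies.columns and "total_kcal" in supplies.columns:
        total = supplies["total_kcal"].to_numpy(dtype=float)
        sugar = supplies["sugar_kcal"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            share = np.where(total > 0, sugar / total, np.nan)
        out["sugar_share"] = share
        out["sugar_within_limit"] = pd.array(
            np.where(np.isnan(share), None, share < SUGAR_SHARE_LIMIT),
            dtype="boolean",
        )
    else:
        out["sugar_share"] = np.nan
        out["sugar_within_limit"] = pd.array([None] * len(out), dtype="boolean")
    return out
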
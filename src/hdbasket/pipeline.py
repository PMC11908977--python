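"""End-to-end orchestration of the adequacy analysis.

Stages (in dependency order): ``simulate`` writes a synthetic input bundle;
``ingest`` reads and merges the two balance-sheet eras; ``score`` maps
commodities to food groups and computes country-year HDBI; ``aggregate``
builds population-weighted regional supplies, decade summaries and energy
totals; ``project`` applies scenario trajectories to base-year supplies;
``report`` writes a run manifest and a plain-text summary.

Every artifact is delimited text, and each stage reads its upstream
artifacts only through the documented file dialects, so stages can be rerun
independently.  All randomness flows from the single seed in the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .aggregation import DEFAULT_DECADES, decade_summary, regional_supply, total_energy
from .fbs_io import (
    DEFAULT_REGIONS,
    merge_eras,
    read_population,
    read_region_scheme,
    read_supply_table,
    write_supply_table,
)
from .food_groups import default_mapping, group_supply, load_mapping
from .hdbi_core import HDBTargets, score_table
from .projection import apply_changes, load_trajectories, project_summary
from .synthetic_data import SimConfig, simulate_fbs, simulate_trajectories

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "ingest", "score", "aggregate", "project", "report")

#: File names the simulate stage writes under ``outdir/inputs``.
_SIM_INPUT_FILES = {
    "supply_old": "supply_old.csv",
    "supply_new": "supply_new.csv",
    "population": "population.csv",
    "scheme": "region_scheme.csv",
    "mapping": "mapping.csv",
    "trajectories": "trajectories.csv",
}


@dataclass
class PipelineConfig:
    """Run configuration, usually loaded from a YAML file."""

    outdir: Path = Path("hdb_output")
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)
    decades: Sequence[tuple[str, int, int]] = DEFAULT_DECADES
    regions: Sequence[str] = DEFAULT_REGIONS
    strict_mapping: bool = False
    cutover_year: int = 2010
    base_year: int = 2010
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "decades" in raw:
            raw["decades"] = [tuple(d) for d in raw["decades"]]
        cfg = cls(**raw)
        cfg.outdir = Path(cfg.outdir)
        spans = sorted((s, e) for _, s, e in cfg.decades)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"decade spans overlap: {(s1, e1)} and {(s2, e2)}")
        return cfg

    def path(self, key: str) -> Path | None:
        p = self.paths.get(key)
        if p:
            return Path(p)
        # fall back to where the simulate stage writes its input bundle, so
        # stagewise invocations compose without editing the config
        candidate = self.outdir / "inputs" / _SIM_INPUT_FILES.get(key, "")
        if key in _SIM_INPUT_FILES and candidate.exists():
            return candidate
        return None


def _require(path: Path | None, what: str, stage: str) -> Path:
    if path is None or not Path(path).exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs {what} ({path}); run its upstream stage or "
            f"set paths.{what} in the config"
        )
    return Path(path)


def run(config: PipelineConfig, stages: Sequence[str]) -> dict:
    """Run the requested stages in dependency order; return the manifest."""
    bad = set(stages) - set(STAGE_ORDER)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}; valid: {list(STAGE_ORDER)}")
    stages = [s for s in STAGE_ORDER if s in set(stages)]
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    if "simulate" in stages:
        sim_cfg = SimConfig(seed=config.seed, **config.simulate)
        sim = simulate_fbs(sim_cfg)
        traj = simulate_trajectories(sim_cfg)
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        old = sim.records[sim.records["era"] == "old"]
        new = sim.records[sim.records["era"] == "new"]
        write_supply_table(old, inputs / "supply_old.csv", era="old")
        write_supply_table(new, inputs / "supply_new.csv", era="new")
        sim.populations.to_csv(inputs / "population.csv", index=False)
        sim.scheme.table.to_csv(inputs / "region_scheme.csv", index=False)
        sim.mapping_table.to_csv(inputs / "mapping.csv", index=False)
        traj.to_csv(inputs / "trajectories.csv", index=False)
        sim.truth_groups.to_csv(inputs / "truth_groups.csv", index=False)
        sim.truth_scores.to_csv(inputs / "truth_scores.csv", index=False)
        defaults = {
            "supply_old": inputs / "supply_old.csv",
            "supply_new": inputs / "supply_new.csv",
            "population": inputs / "population.csv",
            "scheme": inputs / "region_scheme.csv",
            "mapping": inputs / "mapping.csv",
            "trajectories": inputs / "trajectories.csv",
        }
        for k, v in defaults.items():
            config.paths.setdefault(k, str(v))
        config = dataclasses.replace(config, regions=sim_cfg.region_names)
        counts["simulated_records"] = len(sim.records)

    if "ingest" in stages:
        old = read_supply_table(
            _require(config.path("supply_old"), "supply_old", "ingest"), era="old"
        )
        new = read_supply_table(
            _require(config.path("supply_new"), "supply_new", "ingest"), era="new"
        )
        merged = merge_eras(old, new, cutover_year=config.cutover_year)
        merged.to_csv(out / "records.csv", index=False)
        counts["records"] = len(merged)

    mapping = None
    targets = None

    def _mapping():
        p = config.path("mapping")
        return load_mapping(p) if p else default_mapping()

    def _targets():
        p = config.path("targets")
        return HDBTargets.from_file(p) if p else HDBTargets.default()

    if "score" in stages:
        records = pd.read_csv(
            _require(out / "records.csv", "merged records", "score"),
            dtype={"commodity_code": str, "country_code": str},
        )
        mapping = _mapping()
        targets = _targets()
        supplies = group_supply(records, mapping, strict=config.strict_mapping)
        supplies.to_csv(out / "country_supplies.csv", index=False)
        scores = score_table(supplies, targets)
        scores.to_csv(out / "country_scores.csv", index=False)
        counts["country_years_scored"] = len(scores)

    if "aggregate" in stages:
        supplies = pd.read_csv(
            _require(out / "country_supplies.csv", "country supplies", "aggregate")
        )
        scores = pd.read_csv(
            _require(out / "country_scores.csv", "country scores", "aggregate")
        )
        pops = read_population(_require(config.path("population"), "population", "aggregate"))
        scheme = read_region_scheme(
            _require(config.path("scheme"), "scheme", "aggregate"), regions=config.regions
        )
        regional = regional_supply(supplies, pops, scheme)
        regional.to_csv(out / "region_supplies.csv", index=False)
        region_scores = score_table(regional, targets or _targets())
        region_scores.to_csv(out / "region_scores.csv", index=False)
        decades = decade_summary(scores, scheme, config.decades)
        decades.to_csv(out / "decade_summary.csv", index=False)
        first, last = config.decades[0], config.decades[-1]
        energy = total_energy(supplies, pops, scheme, periods=[first, last])
        energy.to_csv(out / "total_energy.csv", index=False)
        counts["region_years"] = len(regional)

    if "project" in stages:
        supplies = pd.read_csv(
            _require(out / "country_supplies.csv", "country supplies", "project")
        )
        traj = load_trajectories(
            _require(config.path("trajectories"), "trajectories", "project"),
            base_year=config.base_year,
        )
        base = supplies[supplies["year"] == config.base_year]
        if base.empty:
            raise ValueError(f"no base-year ({config.base_year}) rows in country supplies")
        results = apply_changes(base, traj, targets or _targets(), base_year=config.base_year)
        results.to_csv(out / "projection.csv", index=False)
        scheme_path = config.path("scheme")
        scheme = (
            read_region_scheme(scheme_path, regions=config.regions)
            if scheme_path and scheme_path.exists()
            else None
        )
        summary = project_summary(results, scheme)
        summary.to_csv(out / "projection_summary.csv", index=False)
        counts["projection_rows"] = len(results)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": list(stages),
        "row_counts": counts,
        "artifacts": sorted(p.name for p in out.glob("*.csv")),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if "report" in stages:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        lines = [f"hdbasket {__version__} run (seed {config.seed})", ""]
        dec_path = out / "decade_summary.csv"
        if dec_path.exists():
            dec = pd.read_csv(dec_path)
            lines.append("Mean country HDBI by region and decade:")
            lines.append(dec.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        proj_path = out / "projection_summary.csv"
        if proj_path.exists():
            proj = pd.read_csv(proj_path)
            horizon = proj[proj["year"] == proj["year"].max()]
            lines.append("")
            lines.append(f"Projected mean HDBI at {int(proj['year'].max())}:")
            lines.append(horizon.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        (out / "report.txt").write_text("\n".join(lines) + "\n")
    return manifest
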
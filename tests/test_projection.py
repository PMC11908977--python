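"""Scenario-projection tests: trajectory validation, identity, ordering."""

import numpy as np
import pandas as pd
import pytest

from hdbasket import (
    GROUPS,
    HDBTargets,
    RegionScheme,
    apply_changes,
    combine_country_aggregates,
    load_trajectories,
    project_summary,
    score_table,
)
from hdbasket.projection import validate_trajectories

TARGETS = HDBTargets.default()


def base_supply(entities, levels=None):
    rows = []
    for i, e in enumerate(entities):
        r = {"entity": e, "year": 2010, "sugar_kcal": 150.0}
        for g in GROUPS:
            r[g] = float(levels[i][g]) if levels else 250.0
        r["total_kcal"] = sum(r[g] for g in GROUPS) + r["sugar_kcal"]
        rows.append(r)
    return pd.DataFrame(rows)


def traj_rows(unit, group, deltas_by_year, scenario="reference"):
    return [
        {"scenario": scenario, "ssp": "SSP3", "rcp": "RCP8.5", "unit": unit,
         "group": group, "year": y, "delta": d}
        for y, d in deltas_by_year.items()
    ]


def full_traj(units, delta_fn, years=(2010, 2030, 2050), scenario="reference"):
    rows = []
    for u in units:
        for g in GROUPS:
            rows += traj_rows(
                u, g, {y: (0.0 if y == 2010 else delta_fn(u, g, y)) for y in years},
                scenario,
            )
    return pd.DataFrame(rows)


class TestLoadValidate:
    def test_valid_series_roundtrip(self, tmp_path):
        df = full_traj(["XAA"], lambda u, g, y: 0.1)
        p = tmp_path / "traj.csv"
        df.to_csv(p, index=False)
        out = load_trajectories(p)
        assert len(out) == len(df)

    def test_delta_below_minus_one_rejected(self):
        df = full_traj(["XAA"], lambda u, g, y: -1.5)
        with pytest.raises(ValueError, match="-1"):
            validate_trajectories(df)

    def test_missing_base_year_rejected(self):
        df = full_traj(["XAA"], lambda u, g, y: 0.1)
        df = df[df["year"] != 2010]
        with pytest.raises(ValueError, match="base-year"):
            validate_trajectories(df)

    def test_nonzero_base_delta_rejected(self):
        df = full_traj(["XAA"], lambda u, g, y: 0.1)
        df.loc[df["year"] == 2010, "delta"] = 0.05
        with pytest.raises(ValueError, match="zero"):
            validate_trajectories(df)

    def test_duplicate_rows_rejected(self):
        df = full_traj(["XAA"], lambda u, g, y: 0.1)
        df = pd.concat([df, df.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            validate_trajectories(df)


class TestApplyChanges:
    def test_zero_deltas_reproduce_base_exactly(self):
        base = base_supply(["XAA", "XAB"])
        traj = full_traj(["XAA", "XAB"], lambda u, g, y: 0.0)
        out = apply_changes(base, traj, TARGETS)
        base_hdbi = score_table(base, TARGETS)["hdbi"]
        for e in ("XAA", "XAB"):
            rows = out[out["unit"] == e]
            expect = float(base_hdbi[base["entity"] == e].iloc[0])
            assert (rows["hdbi"] == expect).all()
            for g in GROUPS:
                assert (rows[g] == float(base.loc[base["entity"] == e, g].iloc[0])).all()

    def test_single_group_delta_scales_only_that_group(self):
        base = base_supply(["XAA"])
        traj = full_traj(["XAA"], lambda u, g, y: 0.10 if g == "fruits" else 0.0)
        out = apply_changes(base, traj, TARGETS)
        at_2050 = out[out["year"] == 2050].iloc[0]
        assert at_2050["fruits"] == pytest.approx(250.0 * 1.1)
        for g in GROUPS:
            if g != "fruits":
                assert at_2050[g] == pytest.approx(250.0)
        assert at_2050["sugar_kcal"] == pytest.approx(150.0)  # held at base

    def test_delta_minus_one_zeroes_group(self):
        base = base_supply(["XAA"])
        traj = full_traj(["XAA"], lambda u, g, y: -1.0 if g == "vegetables" else 0.0)
        out = apply_changes(base, traj, TARGETS)
        at_2050 = out[out["year"] == 2050].iloc[0]
        assert at_2050["vegetables"] == 0.0
        q = {g: at_2050[g] for g in GROUPS}
        from conftest import hdbi_bruteforce

        assert at_2050["hdbi"] == pytest.approx(
            hdbi_bruteforce([q[g] for g in GROUPS], TARGETS.as_array())
        )

    def test_unit_without_trajectory_held_at_base(self):
        base = base_supply(["XAA", "RICH"])
        traj = full_traj(["XAA"], lambda u, g, y: 0.2)
        out = apply_changes(base, traj, TARGETS)
        rich = out[out["unit"] == "RICH"]
        assert len(rich) == 3  # one row per scenario year
        assert (rich["starchy_staples"] == 250.0).all()

    def test_trajectory_group_missing_from_base_rejected(self):
        base = base_supply(["XAA"]).drop(columns=["oils_fats"])
        traj = full_traj(["XAA"], lambda u, g, y: 0.1)
        with pytest.raises(ValueError, match="oils_fats"):
            apply_changes(base, traj, TARGETS)

    def test_monotone_response_below_target(self, rng):
        """A larger delta on a shortfall group never lowers the index; a
        delta on a group already above target leaves it unchanged."""
        base = base_supply(["XAA"])  # all groups at 250: most below target
        for _ in range(25):
            g = rng.choice(GROUPS)
            d1, d2 = sorted(rng.uniform(-0.5, 1.0, 2))
            t1 = full_traj(["XAA"], lambda u, gg, y, g=g, d=d1: d if gg == g else 0.0)
            t2 = full_traj(["XAA"], lambda u, gg, y, g=g, d=d2: d if gg == g else 0.0)
            h1 = apply_changes(base, t1, TARGETS)["hdbi"]
            h2 = apply_changes(base, t2, TARGETS)["hdbi"]
            assert (h2.to_numpy() >= h1.to_numpy() - 1e-12).all()

    def test_saturated_group_insensitive(self):
        levels = [{g: (2000.0 if g == "starchy_staples" else 100.0) for g in GROUPS}]
        base = base_supply(["XAA"], levels)
        t_up = full_traj(["XAA"], lambda u, g, y: 0.5 if g == "starchy_staples" else 0.0)
        t_flat = full_traj(["XAA"], lambda u, g, y: 0.0)
        h_up = apply_changes(base, t_up, TARGETS)["hdbi"]
        h_flat = apply_changes(base, t_flat, TARGETS)["hdbi"]
        assert np.allclose(h_up, h_flat)

    def test_chained_interpretation(self):
        base = base_supply(["XAA"])
        rows = []
        for y, d in [(2010, 0.0), (2011, 0.1), (2012, 0.1)]:
            rows += traj_rows("XAA", "fruits", {y: d})
            for g in GROUPS:
                if g != "fruits":
                    rows += traj_rows("XAA", g, {y: 0.0})
        traj = pd.DataFrame(rows)
        out = apply_changes(base, traj, TARGETS, chained=True)
        at_2012 = out[out["year"] == 2012].iloc[0]
        assert at_2012["fruits"] == pytest.approx(250.0 * 1.1 * 1.1)

    def test_projection_aggregation_commute_with_identical_deltas(self):
        members = ["XAA", "XAB"]
        levels = [{g: 100.0 + 50 * i for g in GROUPS} for i in range(2)]
        base = base_supply(members, levels)
        pop = pd.DataFrame(
            {"country_code": members, "year": 2010, "population": [2.0, 8.0]}
        )
        delta = 0.25
        # aggregate then project
        agg = combine_country_aggregates(base, pop, {"AGG": members})
        traj_a = full_traj(["AGG"], lambda u, g, y: delta)
        out_a = apply_changes(agg, traj_a, TARGETS)
        # project then aggregate
        traj_m = full_traj(members, lambda u, g, y: delta)
        out_m = apply_changes(base, traj_m, TARGETS)
        for year in (2030, 2050):
            sub = out_m[out_m["year"] == year].rename(columns={"unit": "entity"})
            sub = sub.assign(year=2010)
            agg2 = combine_country_aggregates(sub, pop, {"AGG": members})
            row_a = out_a[out_a["year"] == year].iloc[0]
            for g in GROUPS:
                assert row_a[g] == pytest.approx(agg2[g].iloc[0], abs=1e-12)


class TestAggregates:
    def test_equal_population_mean(self):
        base = base_supply(["XAA", "XAB"],
                           [{g: 100.0 for g in GROUPS}, {g: 300.0 for g in GROUPS}])
        pop = pd.DataFrame(
            {"country_code": ["XAA", "XAB"], "year": 2010, "population": [5.0, 5.0]}
        )
        out = combine_country_aggregates(base, pop, {"AGG": ["XAA", "XAB"]})
        assert out["fruits"].iloc[0] == pytest.approx(200.0)

    def test_weighted_mean_hand_computed(self):
        # pops 2 and 8, q 100 and 200 -> 180
        base = base_supply(["XAA", "XAB"],
                           [{g: 100.0 for g in GROUPS}, {g: 200.0 for g in GROUPS}])
        pop = pd.DataFrame(
            {"country_code": ["XAA", "XAB"], "year": 2010, "population": [2.0, 8.0]}
        )
        out = combine_country_aggregates(base, pop, {"AGG": ["XAA", "XAB"]})
        assert out["vegetables"].iloc[0] == pytest.approx(180.0)

    def test_missing_member_skips_aggregate(self, caplog):
        base = base_supply(["XAA"])
        pop = pd.DataFrame({"country_code": ["XAA"], "year": 2010, "population": [1.0]})
        out = combine_country_aggregates(base, pop, {"AGG": ["XAA", "MISSING"]})
        assert out.empty


class TestProjectSummary:
    def make_results(self):
        rows = []
        for unit, h in (("XAA", 0.6), ("XAB", 0.8)):
            rows.append(
                {"scenario": "reference", "ssp": "SSP3", "rcp": "RCP8.5",
                 "unit": unit, "year": 2050, "hdbi": h}
            )
        return pd.DataFrame(rows)

    def test_unweighted_regional_mean(self):
        scheme = RegionScheme(
            pd.DataFrame({"country_code": ["XAA", "XAB"], "subregion": "s",
                          "region": "South Asia"})
        )
        out = project_summary(self.make_results(), scheme)
        sa = out[out["region"] == "South Asia"]
        assert sa["mean_hdbi"].iloc[0] == pytest.approx(0.7)
        world = out[out["region"] == "World"]
        assert world["mean_hdbi"].iloc[0] == pytest.approx(0.7)

    def test_single_unit_is_its_own_mean(self):
        res = self.make_results().iloc[:1]
        out = project_summary(res)
        assert out["mean_hdbi"].iloc[0] == pytest.approx(0.6)
        assert out["n_units"].iloc[0] == 1
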
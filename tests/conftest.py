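import numpy as np
import pandas as pd
import pytest

from hdbasket import CommodityMapping, SimConfig, simulate_fbs, simulate_trajectories
from hdbasket.hdbi_core import GROUPS


def hdbi_bruteforce(q, Q):
    """Independent scalar evaluation of the adequacy index."""
    s = 0.0
    for qi, Qi in zip(q, Q):
        if qi < Qi:
            s += abs(qi - Qi) / Qi
    return 1.0 - s / 6.0


@pytest.fixture(scope="session")
def sim_noise_free():
    return simulate_fbs(SimConfig(seed=11, countries_per_region=2, sigma=0.0))


@pytest.fixture(scope="session")
def sim_noisy():
    return simulate_fbs(SimConfig(seed=11, countries_per_region=2, sigma=0.05))


@pytest.fixture(scope="session")
def sim_mapping(sim_noise_free):
    return CommodityMapping(sim_noise_free.mapping_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def supply_row():
    """One complete food-group supply record meeting every target."""
    row = {"entity": "XAA", "year": 2000, "sugar_kcal": 100.0}
    row.update({g: 500.0 for g in GROUPS})
    row["total_kcal"] = 500.0 * 6 + 100.0
    return row
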
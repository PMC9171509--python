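import logging

import numpy as np
import pandas as pd
import pytest

from lungalloc.activity import ActivityTable
from lungalloc.geography import ROLE_LTC, ROLE_OPC
from lungalloc.optimizer import OptimizerConfig
from lungalloc.synthetic import ScenarioConfig, generate_scenario

logging.getLogger("lungalloc").setLevel(logging.ERROR)


def make_centres(opcs, ltcs):
    """Build a centre table from [(id, x, y, region), ...] lists."""
    rows = [
        {"id": i, "name": i, "role": ROLE_OPC, "x": x, "y": y, "region": r}
        for i, x, y, r in opcs
    ] + [
        {"id": i, "name": i, "role": ROLE_LTC, "x": x, "y": y, "region": r}
        for i, x, y, r in ltcs
    ]
    frame = pd.DataFrame(rows)
    frame.attrs["coordinate_system"] = "km"
    return frame


def make_activity(lungs, transplants, candidates=None, offers=None):
    return ActivityTable(
        lungs_recovered=lungs,
        transplants=transplants,
        candidates=candidates,
        offers=offers,
    )


#: scenario parameters used across the stochastic tests; sized so
#: eligibility pools stay enumerable on one CPU
SCENARIO_KWARGS = dict(
    n_opc=80, n_ltc=5, field_km=800.0, speed_kmh=80.0, demand_range=(15, 45)
)

#: optimizer settings matched to the scenario scale (uncapped shortlist:
#: the per-LTC enumerations stay small enough to keep whole)
EQUITY_CONFIG = OptimizerConfig(
    size_min=3, size_max=10, ratio_tolerance=0.4, shortlist_k=10**6
)


@pytest.fixture(scope="session")
def small_scenario():
    return generate_scenario(ScenarioConfig(seed=11, **SCENARIO_KWARGS))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
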
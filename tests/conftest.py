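import numpy as np
import pytest

from microcost.engine import CostingContext, WageSchedule
from microcost.unit_costs import bundled_price_table


@pytest.fixture(scope="session")
def price_table():
    return bundled_price_table("all")


@pytest.fixture(scope="session")
def wage_schedule():
    # physician $10/h, nurse $4/h; at the 0.5 h default that is $5 / $2 per visit
    return WageSchedule(wages={"physician": (1600.0, 160.0), "nurse": (640.0, 160.0)})


@pytest.fixture
def ctx(price_table, wage_schedule):
    return CostingContext(
        unit_table=price_table,
        wage_schedule=wage_schedule,
        per_day_overhead=10.0,
        capital_share_per_patient=0.0,
        lab_flat_rate=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
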
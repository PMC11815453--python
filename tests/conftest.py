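import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from t2dcea import costing, synthdata
from t2dcea.effects import EffectProfile
from t2dcea.microsim import EconomicParams


@pytest.fixture(scope="session")
def indices():
    return synthdata.fixture_price_indices()


@pytest.fixture(scope="session")
def unit_costs():
    return synthdata.fixture_unit_costs()


@pytest.fixture(scope="session")
def fixture_summary(indices, unit_costs):
    """The bundled ledger priced and aggregated at 2019/20 prices."""
    priced = costing.price_activities(
        synthdata.fixture_ledger(), unit_costs, indices, "2019/20"
    )
    return costing.aggregate_costs(priced)


@pytest.fixture(scope="session")
def low_engine():
    return synthdata.toy_engine("low")


@pytest.fixture(scope="session")
def calibration_engine():
    return synthdata.toy_engine("calibration")


@pytest.fixture(scope="session")
def small_cohort():
    return synthdata.gen_cohort(synthdata.CohortSpec(n=300, seed=42))


@pytest.fixture
def unit_utility_econ():
    """Utility pinned at 1, no costs, undiscounted - QALYs count life-years."""
    return EconomicParams(utility_intercept=1.0, discount_rate=0.0)


@pytest.fixture
def zero_profile():
    return EffectProfile.zero(40)
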
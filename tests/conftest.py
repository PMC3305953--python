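import numpy as np
import pytest

from crcscreen.natural_history import LifeTable, NaturalHistoryParams
from crcscreen.screening import strategy_presets
from crcscreen.synthetic import base_case_values, generate_life_table, reference_params
from crcscreen.uncertainty import build_model_inputs


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return generate_life_table()


@pytest.fixture(scope="session")
def ref_params() -> NaturalHistoryParams:
    return reference_params()


@pytest.fixture(scope="session")
def base_inputs() -> dict:
    return build_model_inputs(base_case_values())


@pytest.fixture(scope="session")
def presets() -> dict:
    return strategy_presets()


@pytest.fixture()
def flat_life_table() -> LifeTable:
    """Constant 1% other-cause mortality, absorption at 100."""
    ages = np.arange(0, 101)
    q = np.full(101, 0.01)
    q[100] = 1.0
    return LifeTable(ages, q)


@pytest.fixture()
def null_params() -> NaturalHistoryParams:
    """All neoplasia transitions switched off."""
    return NaturalHistoryParams(
        p_normal_to_lowrisk=np.zeros(5),
        p_low_to_high=0.0,
        p_high_to_crcI=0.0,
        p_stage_progress=np.zeros(3),
        p_symptomatic=np.zeros(4),
        p_crc_death=np.zeros(4),
        p_direct=0.0,
    )
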
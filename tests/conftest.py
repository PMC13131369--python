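import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mcmct_eval import BehaviorProfile, ErrorModel, SimConfig, emulate, simulate_herd
from mcmct_eval.farm_config import FarmConfig
from mcmct_eval.reference import reference_farms

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def farms():
    return reference_farms()


@pytest.fixture(scope="session")
def small_farm():
    return FarmConfig(
        farm_id="T1",
        n_cows=12,
        barn_area=120.0,
        n_cubicles=12,
        n_water_troughs=1,
        n_ams=1,
        n_cameras=2,
    )


@pytest.fixture(scope="session")
def small_sim(small_farm):
    """12 cows x 3 days on the default 5-minute grid."""
    sim = SimConfig(seed=11, n_days=3)
    truth, visits = simulate_herd(small_farm, sim)
    return truth, visits


@pytest.fixture(scope="session")
def small_emulation(small_sim):
    truth, visits = small_sim
    em = ErrorModel(
        daily_miss=0.10,
        ghost_rate=0.15,
        id_correct=0.80,
        id_swap_share=0.5,
        location_cooccur=0.8,
        location_base_rate=0.02,
        night_detect_drop=0.1,
    )
    records, snaps = emulate(truth, visits, em, 99)
    return truth, visits, em, records, snaps


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
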
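import dataclasses

import numpy as np
import pytest

from dsdge import tissue as ts
from dsdge.bm_core import Pool, PulseTrain, SimProtocol, water_pool
from dsdge.phantom import PhantomSpec, RegionSpec


@pytest.fixture(scope="session")
def table():
    return ts.load_tissue_table()


@pytest.fixture(scope="session")
def train():
    return ts.default_train()


@pytest.fixture(scope="session")
def protocol():
    return ts.default_protocol()


@pytest.fixture(scope="session")
def pulsed_protocol():
    """Literal pulse-train propagation, thermal start (for oracle tests)."""
    return ts.default_protocol(saturation_model="pulse_train",
                               initial_state="thermal")


@pytest.fixture(scope="session")
def water_oh_pools():
    """Water plus one hydroxyl pool at 1.28 ppm, tissue-like relaxation."""
    return [
        water_pool(1.2, 0.07),
        Pool("OH", 1.28, 1.2, 0.1, exchange_rate_hz=6500.0,
             proton_fraction=3e-4),
    ]


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Noiseless phantom small enough for per-voxel fitting in tests."""
    regions = {
        "WM": RegionSpec("WM", onset_dynamic=4, rise_time_dynamics=1.0),
        "GM": RegionSpec("GM", onset_dynamic=4, rise_time_dynamics=1.0),
        "TUMOR": RegionSpec("TUMOR", onset_dynamic=4, rise_time_dynamics=1.0),
        "CSF": RegionSpec("CSF", onset_dynamic=4, rise_time_dynamics=1.0),
        "vessel": RegionSpec("blood", onset_dynamic=4, rise_time_dynamics=1.0),
    }
    return PhantomSpec(
        grid_shape=(16, 16, 8),
        n_dynamics=12,
        infusion_start_dynamic=4,
        noise_sigma_fraction=0.0,
        seed=7,
        regions=regions,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
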
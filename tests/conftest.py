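import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from specfx.bpnn import BpnnConfig
from specfx.fingerprint import match_common_peaks, relative_content
from specfx.gra import gra_analysis
from specfx.pls import pls_analysis
from specfx.synthetic import SimConfig, simulate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def zero_noise_config():
    return SimConfig(seed=0, noise_sd=0.0, rt_jitter_sd=0.0)


@pytest.fixture(scope="session")
def zero_noise_data(zero_noise_config):
    """Full zero-noise dataset plus precomputed stage outputs (shared)."""
    tables, panel, binding, truth = simulate_dataset(zero_noise_config)
    matrix = match_common_peaks(tables)
    gra_res = gra_analysis(matrix, panel)
    _models, vips = pls_analysis(matrix, panel)
    return {
        "config": zero_noise_config,
        "tables": tables,
        "panel": panel,
        "binding": binding,
        "truth": truth,
        "matrix": matrix,
        "gra": gra_res,
        "vips": vips,
        "content": relative_content(matrix),
    }


@pytest.fixture(scope="session")
def noisy_data():
    cfg = SimConfig(seed=1)
    tables, panel, binding, truth = simulate_dataset(cfg)
    return {"config": cfg, "tables": tables, "panel": panel,
            "binding": binding, "truth": truth}


@pytest.fixture()
def fast_bpnn():
    """Cheaper training schedule for tests that do not need a perfect fit."""
    return BpnnConfig(epochs=3000, learning_rate=1.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
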
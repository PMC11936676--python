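import numpy as np
import pytest

import aspentherm as at


@pytest.fixture(scope="session")
def default_cfg():
    return at.default_config()


@pytest.fixture(scope="session")
def june_microclimate(default_cfg):
    return at.generate_microclimate(default_cfg.site, 6, default_cfg.scenarios[0])


@pytest.fixture(scope="session")
def large_heat_shock():
    """Heat-shock trials at the published truths, large n for MLE checks."""
    design = at.HeatShockDesign(
        shock_temperatures=(34, 36, 38, 40, 42, 44),
        n_per_temperature=500,
        true_lt50=37.4,
        true_slope=-0.25,
        seed=20,
    )
    return at.simulate_heat_shock(design)


@pytest.fixture(scope="session")
def emergence_records():
    return at.simulate_emergence(at.EmergenceDesign(seed=7))


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
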
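import dataclasses

import pytest

from cartiq import IndenterGeometry, SimulationConfig, generate_sites


@pytest.fixture(scope="session")
def geometry():
    return IndenterGeometry()


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def noiseless_config():
    """All stochastic scatter off: curves and images become closed-form."""
    return SimulationConfig(
        seed=7,
        force_noise_sd_N=0.0,
        image_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def sites64(default_config, geometry):
    return generate_sites(default_config, geometry)


@pytest.fixture(scope="session")
def noiseless_sites(noiseless_config, geometry):
    return generate_sites(noiseless_config, geometry)
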
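"""Shared fixtures: expensive simulations are computed once per session."""

import numpy as np
import pytest

from scratchcpg import (
    build_network,
    integrate,
    reduce_module,
    stimulus_drives,
)
from scratchcpg.slowphase import compute_landscape, measure_halfcenter


@pytest.fixture(scope="session")
def s_config():
    return build_network("S")


@pytest.fixture(scope="session")
def sce_config():
    return build_network("SCE")


@pytest.fixture(scope="session")
def s_module(s_config):
    return reduce_module(s_config)


@pytest.fixture(scope="session")
def pocket_drives_s():
    return stimulus_drives("S", "pocket")


@pytest.fixture(scope="session")
def rostral_drives_s():
    return stimulus_drives("S", "rostral")


@pytest.fixture(scope="session")
def pocket_trace(s_config, pocket_drives_s):
    return integrate(s_config.with_drives(pocket_drives_s), t_end=3000.0)


@pytest.fixture(scope="session")
def rostral_trace(s_config, rostral_drives_s):
    return integrate(s_config.with_drives(rostral_drives_s), t_end=3000.0)


@pytest.fixture(scope="session")
def baseline_rest_trace(s_config):
    return integrate(s_config, t_end=2500.0, init="rest")


@pytest.fixture(scope="session")
def pocket_measured(s_config, pocket_drives_s):
    return measure_halfcenter(s_config.with_drives(pocket_drives_s))


@pytest.fixture(scope="session")
def rostral_measured(s_config, rostral_drives_s):
    return measure_halfcenter(s_config.with_drives(rostral_drives_s))


@pytest.fixture(scope="session")
def pocket_landscape(s_config, s_module, pocket_drives_s, pocket_measured):
    return compute_landscape(pocket_drives_s, s_module, s_config,
                             measured=pocket_measured)


@pytest.fixture(scope="session")
def rostral_landscape(s_config, s_module, rostral_drives_s, rostral_measured):
    return compute_landscape(rostral_drives_s, s_module, s_config,
                             measured=rostral_measured)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
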
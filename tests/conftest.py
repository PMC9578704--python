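import numpy as np
import pytest

import gutlapse as gl


@pytest.fixture(scope="session")
def small_scene() -> gl.SimScene:
    """A mid-sized ground-truth scene reused by several suites."""
    params = gl.SimulationParams(
        n_founders=20, t_max=60.0, seed=3, field_size_um=(300.0, 300.0))
    return gl.simulate_lineages(params)


@pytest.fixture(scope="session")
def static_drifting_scene() -> gl.SimScene:
    """Static nuclei (no motility, no divisions) under a slow linear drift."""
    params = gl.SimulationParams(
        n_founders=10, t_max=10.0, seed=5, field_size_um=(64.0, 64.0),
        motility_step_mean=0.0, z_jitter_um=0.0,
        cycle_mean=1000.0, cycle_sd=0.0, gfp_onset_range=(0.0, 0.0))
    return gl.simulate_lineages(params).with_linear_drift((0.9, 0.6))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
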
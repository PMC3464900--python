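import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from priism import PriismDecomposer, interpolate_to_grid
from priism.synthdata import SimConfig, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A 40-gene simulated experiment for fast unit checks."""
    cfg = SimConfig(n_genes=40, n_clock_genes=8, n_responders=6, seed=0)
    control, treatment, truth = simulate(cfg)
    return control, treatment, truth


@pytest.fixture(scope="session")
def default_sim():
    """The default 200-gene fixture (seed 1) the property checks run on."""
    control, treatment, truth = simulate(SimConfig())
    return control, treatment, truth


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    """Fitted decomposers and component matrices for both conditions."""
    control, treatment, truth = default_sim
    out = {}
    for label, m in (("control", control), ("treatment", treatment)):
        dec = PriismDecomposer().fit(m)
        out[label] = {
            "decomposer": dec,
            "interpolated": interpolate_to_grid(m, 2.0),
            "parts": dec.transform(m),
        }
    return out, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
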
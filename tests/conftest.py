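import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import limdil as ld

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_config():
    """Light simulation budget for unit tests (not for calibration checks)."""
    return ld.SimulationConfig(
        n_sims=200_000, lambda_grid_points=100, q_grid_step=0.01, seed=7
    )


@pytest.fixture
def noninduced_experiment():
    """Replica plating with no hygromycin-sensitive wells (0 of 71 populated)."""
    return ld.LossExperiment(
        clone_id="A", condition="non-induced", wells_total=96,
        populated_wells=71, sensitive_wells=0, nominal_lambda=1.5,
    )


@pytest.fixture
def induced_experiment():
    """Replica plating with 6 sensitive wells of 76 populated."""
    return ld.LossExperiment(
        clone_id="A", condition="induced", wells_total=96,
        populated_wells=76, sensitive_wells=6, nominal_lambda=1.5,
    )
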
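import numpy as np
import pytest

from ablaheat.runner import SimulationConfig, SimulationContext


@pytest.fixture(scope="session")
def coarse_config():
    """Small, fast configuration used by tests that only need a valid pipeline."""
    return SimulationConfig(study=1, protected=False, power=30.0, target_elements=1500)


@pytest.fixture(scope="session")
def coarse_context(coarse_config):
    return SimulationContext(coarse_config)


@pytest.fixture(scope="session")
def body_T(coarse_context):
    return np.full(coarse_context.mesh.n_nodes, 310.15)
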
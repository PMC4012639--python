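import numpy as np
import pytest

from thermospike.model import NeuronParameters, Q10Set, StimulusProtocol
from thermospike.sweep import Q10Grid, run_sweep


@pytest.fixture(scope="session")
def ref_params() -> NeuronParameters:
    return NeuronParameters()


@pytest.fixture(scope="session")
def protocol() -> StimulusProtocol:
    return StimulusProtocol()


@pytest.fixture(scope="session")
def random_grid_models():
    """20 seeded random Q10 grid points (reused across oracle tests)."""
    grid = Q10Grid.default(4)
    rng = np.random.default_rng(1234)
    idx = rng.choice(grid.size, 20, replace=False)
    return [grid.q10set(int(i)) for i in idx]


@pytest.fixture(scope="session")
def smoke_sweep():
    """Full 2-step (512-model) smoke sweep at default settings."""
    return run_sweep(Q10Grid.default(2))


@pytest.fixture(scope="session")
def smoke_transduction(smoke_sweep):
    from thermospike.transduction import transduction_q10_distribution

    return transduction_q10_distribution(smoke_sweep.table)
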
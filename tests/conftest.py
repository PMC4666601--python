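import numpy as np
import pytest

from dcsflow import (
    CohortDesign,
    FitOptions,
    FlowModel,
    NoiseModel,
    OpticalProperties,
    default_lag_grid,
)


@pytest.fixture(scope="session")
def optics() -> OpticalProperties:
    return OpticalProperties()


@pytest.fixture(scope="session")
def lag_grid():
    return default_lag_grid()


@pytest.fixture
def flow() -> FlowModel:
    return FlowModel(bfi=1e-8, beta=0.5)


@pytest.fixture
def noiseless() -> NoiseModel:
    return NoiseModel(sigma0=0.0)


@pytest.fixture(scope="session")
def tiny_design() -> CohortDesign:
    """Two mice per group, three visits, two positions + contralateral, two separations."""
    return CohortDesign(
        n_autograft=2,
        n_allograft=2,
        weeks=(0, 1, 2),
        graft_positions=("P2", "P4"),
        separations_mm=(2.9, 5.0),
        repeats=3,
        master_seed=11,
    )
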
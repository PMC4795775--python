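import numpy as np
import pytest

from isopop import (
    BiochemParams,
    FitOptions,
    MeasurementModel,
    PopulationModel,
    PopulationState,
    default_panel,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def mm(panel):
    """Shared forward operator over the default panel and tracer."""
    return MeasurementModel(panel)


@pytest.fixture(scope="session")
def reference_biochem():
    """Branch parameters of the reference co-utilization scenario."""
    return BiochemParams(ap=0.9, rev=0.5, ppp=0.5, co2=0.1)


@pytest.fixture(scope="session")
def one_state_5050(reference_biochem):
    return PopulationModel.one_state(PopulationState(0.5, reference_biochem))


@pytest.fixture(scope="session")
def two_state_pure_5050(reference_biochem):
    return PopulationModel.two_state(
        0.5,
        PopulationState(1.0, reference_biochem),
        PopulationState(0.0, reference_biochem),
    )


@pytest.fixture()
def fast_options():
    """Reduced multistart for unit-test-sized fitting problems."""
    return FitOptions(multistart=4, seed=11)
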
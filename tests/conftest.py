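import warnings

import numpy as np
import pytest

from obtriad.cable import (
    CellModel,
    CompartmentGeometry,
    CurrentPulse,
    Network,
    PassiveParameters,
    SolverConfig,
)
from obtriad.cells import (
    build_granule,
    build_mitral,
    build_pg,
    load_granule_parameters,
    load_mitral_parameters,
    load_pg_parameters,
)

warnings.filterwarnings("ignore", message="stimulus .* truncated")


@pytest.fixture(scope="session")
def pg_params():
    return load_pg_parameters()


@pytest.fixture(scope="session")
def mitral_params():
    return load_mitral_parameters()


@pytest.fixture(scope="session")
def granule_params():
    return load_granule_parameters()


@pytest.fixture(scope="session")
def pg_cell(pg_params):
    return build_pg(pg_params)


@pytest.fixture(scope="session")
def mitral_cell(mitral_params):
    return build_mitral(mitral_params)


@pytest.fixture(scope="session")
def granule_cell(granule_params):
    return build_granule(granule_params)


@pytest.fixture()
def passive_cell():
    """Single 20x100 um passive cylinder; input resistance and time
    constant have closed forms."""
    return CellModel(
        name="passive",
        compartments=(CompartmentGeometry("soma", 100.0, 20.0),),
        passive=PassiveParameters(
            axial_resistivity=100.0,
            specific_capacitance=1.0,
            leak_conductance_density=1e-4,
            leak_reversal=-65.0,
            resting_potential=-65.0,
        ),
    )


@pytest.fixture(scope="session", autouse=True)
def _warm_solver():
    """Compile the simulation kernel once up front so individual test
    timings reflect the physics, not JIT compilation."""
    cell = CellModel(
        name="warm",
        compartments=(CompartmentGeometry("soma", 10.0, 10.0),),
        passive=PassiveParameters(),
    )
    Network(cell).run(SolverConfig(dt=0.05, t_stop=1.0),
                      [CurrentPulse((None, "soma"), 0.01, 0.1, 0.5)])
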
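"""Shared fixtures.

Simulation records that several tests consume are session-scoped and run at
deliberately coarse desk-scale resolution; per-test assertions state the
tolerances appropriate to that resolution.
"""

import numpy as np
import pytest

from pvsflow.parameters import default_parameters
from pvsflow.solver import run_coupled, run_rigid
from pvsflow.wall_motion import WallMotion


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def rigid_heartbeat_record(params):
    """One heartbeat cycle, rigid outer wall, Darcy-Brinkman fluid."""
    return run_rigid(params, WallMotion.heartbeat(params),
                     nr_pvs=10, nz=48, dt=2e-4, duration=0.1)


@pytest.fixture(scope="session")
def coupled_heartbeat_record(params):
    """One heartbeat cycle of the coupled FSI model (coarse mesh)."""
    return run_coupled(params, WallMotion.heartbeat(params),
                       nr_pvs=8, nz=24, nr_brain=10, dt=2.5e-4, duration=0.1)


@pytest.fixture(scope="session")
def coupled_hyperemia_record(params):
    """One 10 s functional-hyperemia event of the coupled FSI model."""
    return run_coupled(params, WallMotion.hyperemia(params),
                       nr_pvs=8, nz=24, nr_brain=10, dt=0.01, duration=10.0,
                       store_every=20)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
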
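import numpy as np
import pytest
from hypothesis import settings

import squirmtopo as sq

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

#: trajectory-level tests run at the default discretisation; the sphere
#: quadrature stays at the production N_s = 18 because the near-wall
#: physics degrades qualitatively below N_s ~ 14 even though the
#: free-space speed barely changes.
TEST_WALL = sq.WallPatchSpec()
TEST_NS = 4
TEST_NS_FINE = 18


@pytest.fixture
def free_state():
    return sq.SquirmerState(
        centre=np.zeros(3), orientation=[0.0, 0.0, 1.0], B1=1.5, beta=0.0
    )


@pytest.fixture
def stokeslet_kernel():
    return sq.KernelSpec("reg_stokeslet", 1e-3)


def patch_config(topo, max_time, **kw):
    """Discretised-wall simulation config at the defaults used in tests."""
    kw.setdefault("wall", TEST_WALL)
    kw.setdefault("n_s", TEST_NS)
    kw.setdefault("N_s", TEST_NS_FINE)
    return sq.SimulationConfig(
        topography=topo,
        kernel=sq.KernelSpec("reg_stokeslet", 1e-3),
        max_time=max_time,
        **kw,
    )


def start_state(phi, z0=1.2, y0=0.0, beta=7.0):
    """The standard initial condition: pitched towards the wall."""
    return sq.SquirmerState.from_angles(
        [0.0, y0, z0], -0.17 * np.pi, phi, B1=1.5, beta=beta
    )
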
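import numpy as np
import pytest

from hepakin.model import FrameSchedule, KineticParams, default_grid, model_tac, sample_frames
from hepakin.model import TissueCurve
from hepakin.simulate import arterial_input, portal_from_arterial


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def arterial(grid):
    return arterial_input(grid=grid)


@pytest.fixture(scope="session")
def portal(arterial):
    return portal_from_arterial(arterial)


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def hcc_params():
    # clinically plausible HCC-like parameter vector
    return KineticParams(0.65, 0.59, 0.14, 0.064, 0.67)


@pytest.fixture(scope="session")
def noiseless_tac(hcc_params, arterial, portal, grid, schedule):
    curve = model_tac(hcc_params, arterial, portal, grid)
    return TissueCurve(schedule, sample_frames(curve, schedule), label="HCC")


def ode_tissue_curve(params, arterial, portal, grid, rtol=1e-8):
    """Independent oracle: integrate the two-tissue ODE system directly.

    dC_f/dt = k1 C_B - (k2+k3) C_f + k4 C_p ; dC_p/dt = k3 C_f - k4 C_p ;
    C_T = C_f + C_p.  Kept free of the analytic-convolution code under test.
    """
    from scipy.integrate import solve_ivp

    from hepakin.model import blood_input

    cb = blood_input(arterial, portal, params.hpi)
    k1, k2, k3, k4 = (v / 60.0 for v in (params.k1, params.k2, params.k3, params.k4))

    def rhs(t, y):
        cf, cp = y
        return [k1 * cb(t) - (k2 + k3) * cf + k4 * cp, k3 * cf - k4 * cp]

    sol = solve_ivp(
        rhs, (grid[0], grid[-1]), [0.0, 0.0], t_eval=grid,
        rtol=rtol, atol=1e-12, max_step=1.0,
    )
    return sol.y.sum(axis=0)
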
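import numpy as np
import pytest

from ivdkit.histopath import ScoringScheme
from ivdkit.synth.design import StudyDesign
from ivdkit.synth.loops import HysteresisParams, simulate_loop


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(groups=("EST", "NOC"), n_sheep_per_cell=6)


@pytest.fixture
def noiseless_loop():
    """Canonical dual-stiffness loop with zero noise and known ground truth."""
    params = HysteresisParams(
        k_nz=0.015, k_el=0.7, nz_half_width=3.4, hysteresis_offset=0.02, noise_sd=0.0
    )
    return simulate_loop(params, seed=0)


def backbone_nz_width_oracle(params: HysteresisParams, grid_step: float = 0.001):
    """Dense-grid finite-difference neutral zone of the noiseless backbone.

    Independent of both the analytic formula and the polynomial pipeline:
    numerically differentiates the backbone torque and scans the threshold.
    """
    tl = params.theta_limit()
    grid = np.arange(-tl, tl + grid_step / 2, grid_step)
    torque = params.backbone_torque(grid)
    grad = np.gradient(torque, grid)
    sub = grad < 0.05
    mid = np.argmin(np.abs(grid))
    if not sub[mid]:
        return None
    i0 = i1 = mid
    while i0 > 0 and sub[i0 - 1]:
        i0 -= 1
    while i1 < sub.size - 1 and sub[i1 + 1]:
        i1 += 1
    return float(grid[i1] - grid[i0])
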
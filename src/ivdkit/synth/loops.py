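"""Synthetic cyclic torque-angle records for functional spinal units.

Emulates cyclic testing of an isolated spinal segment driven at a constant
angular rate to a fixed torque limit: the specimen is rotated at
``angular_rate`` deg/s between the angles at which the backbone torque
reaches ±``torque_limit`` Nm, for ``n_cycles`` cycles, with torque and angle
sampled at ``sample_rate`` Hz.  Loading and unloading sweeps are offset by a
constant hysteresis torque and corrupted by additive Gaussian noise.

The noiseless backbone is a smooth dual-stiffness "lazy-S" curve whose
gradient is

    g(theta) = k_nz + (k_el - k_nz) * (theta / a)**6

so the torque is an odd degree-7 polynomial in angle,

    T(theta) = k_nz*theta + (k_el - k_nz) * theta**7 / (7 * a**6).

The family is chosen to lie inside the span of the degree-7 polynomial used
by the downstream torque-angle analysis: with zero noise the least-squares
fit reproduces the backbone exactly, so the neutral zone, range of motion
and stiffness all have closed-form ground truths and estimator error under
noise can be measured against an exact oracle.  ``a`` is set from
``nz_half_width`` so that for a neutral-zone-capable mode (k_nz below the
0.05 Nm/deg gradient threshold) the analytic neutral zone is exactly
``[-nz_half_width, +nz_half_width]``; for a stiff mode with k_nz at or above
the threshold (axial rotation: no region of low stiffness, hence no neutral
zone) ``nz_half_width`` acts directly as the transition length scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

#: gradient threshold (Nm/deg) below which the torque-angle curve is "lax";
#: also the default band half-width for the initial-stiffness average.
NZ_GRADIENT_THRESHOLD = 0.05


@dataclass(frozen=True)
class HysteresisParams:
    """Shape parameters of one loading mode's synthetic torque-angle loop.

    k_nz / k_el are the gradients (Nm/deg) at the neutral position and at the
    edge of the low-stiffness transition respectively; beyond the transition
    the synthetic curve keeps stiffening toward the torque limit, emulating
    capsuloligamentous end-range behaviour.
    """

    k_nz: float
    k_el: float
    nz_half_width: float
    hysteresis_offset: float = 0.0
    torque_limit: float = 5.0
    angular_rate: float = 5.0
    sample_rate: float = 20.0
    n_cycles: int = 10
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.k_nz <= self.k_el):
            raise ValueError("require 0 <= k_nz <= k_el")
        if self.torque_limit <= 0:
            raise ValueError("torque_limit must be > 0")
        if self.nz_half_width < 0:
            raise ValueError("nz_half_width must be >= 0")
        if self.noise_sd < 0 or self.hysteresis_offset < 0:
            raise ValueError("noise_sd and hysteresis_offset must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    # -- backbone geometry ------------------------------------------------

    @property
    def is_linear(self) -> bool:
        """Pure single-stiffness loop (no transition region)."""
        return self.nz_half_width == 0.0 or self.k_nz == self.k_el

    @property
    def transition_scale(self) -> float:
        """Angle scale ``a`` of the gradient transition (deg)."""
        if self.is_linear:
            return 0.0
        dk = self.k_el - self.k_nz
        if self.k_nz < NZ_GRADIENT_THRESHOLD:
            # place the analytic NZ boundary exactly at +/- nz_half_width
            return self.nz_half_width * (dk / (NZ_GRADIENT_THRESHOLD - self.k_nz)) ** (1 / 6)
        return self.nz_half_width

    def backbone_torque(self, theta):
        theta = np.asarray(theta, dtype=float)
        if self.is_linear:
            return self.k_el * theta
        a = self.transition_scale
        return self.k_nz * theta + (self.k_el - self.k_nz) * theta**7 / (7 * a**6)

    def backbone_gradient(self, theta):
        theta = np.asarray(theta, dtype=float)
        if self.is_linear:
            return np.full_like(theta, self.k_el)
        a = self.transition_scale
        return self.k_nz + (self.k_el - self.k_nz) * (theta / a) ** 6

    def theta_limit(self) -> float:
        """Angle at which the backbone reaches the torque limit."""
        if self.is_linear:
            if self.k_el <= 0:
                raise ValueError("unreachable torque limit")
            return self.torque_limit / self.k_el
        a = self.transition_scale
        hi = max(10 * a, 10 * self.torque_limit / self.k_el, 1.0)
        while self.backbone_torque(hi) < self.torque_limit:
            hi *= 2
            if hi > 1e6:  # pragma: no cover - guarded by k_el > 0
                raise ValueError("unreachable torque limit")
        return brentq(lambda t: self.backbone_torque(t) - self.torque_limit, 0.0, hi)


@dataclass(frozen=True)
class LoopGroundTruth:
    """Closed-form values of every downstream biomechanical estimand."""

    theta_limit: float
    rom_deg: float
    nz_range: tuple[float, float] | None
    nz_width_deg: float | None
    k_nz: float
    initial_stiffness_pos: float
    initial_stiffness_neg: float
    final_stiffness: float


@dataclass
class LoadingRecord:
    """One specimen x loading-mode cyclic torque-angle time series."""

    specimen: str
    loading_mode: str
    time_s: np.ndarray
    angle_deg: np.ndarray
    torque_nm: np.ndarray
    cycle: np.ndarray        # 1-based cycle index per sample
    direction: np.ndarray    # +1 loading_positive (angle increasing), -1 otherwise
    torque_limit: float = 5.0
    ground_truth: LoopGroundTruth | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for arr in (self.angle_deg, self.torque_nm, self.cycle, self.direction):
            if len(arr) != n:
                raise ValueError("all sample columns must share one length")
        if n and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "specimen": self.specimen,
                "loading_mode": self.loading_mode,
                "time_s": self.time_s,
                "angle_deg": self.angle_deg,
                "torque_Nm": self.torque_nm,
                "cycle": self.cycle,
                "direction": np.where(self.direction > 0, "loading_positive", "loading_negative"),
            }
        )


def _analytic_neutral_zone(params: HysteresisParams) -> tuple[float, float] | None:
    """Angular range where the backbone gradient is < 0.05 Nm/deg, or None."""
    if params.k_nz >= NZ_GRADIENT_THRESHOLD:
        return None
    if params.is_linear:
        # gradient k_el everywhere; only lax if k_el below threshold
        if params.k_el < NZ_GRADIENT_THRESHOLD:
            t = params.theta_limit()
            return (-t, t)
        return None
    h = params.nz_half_width
    return (-h, h)


def _analytic_initial_stiffness(
    params: HysteresisParams, branch_offset: float, delta: float = NZ_GRADIENT_THRESHOLD
) -> float:
    """Closed-form value of the initial-stiffness estimand for one branch.

    The estimand is the mean backbone gradient over the maximal contiguous
    interval around the branch's zero-torque crossing where the gradient
    deviates from its crossing value by less than ``delta``.
    """
    tl = params.theta_limit()
    if params.is_linear:
        return params.k_el
    a = params.transition_scale
    dk = params.k_el - params.k_nz
    # zero-torque crossing of backbone + branch_offset
    t0 = brentq(lambda t: params.backbone_torque(t) + branch_offset, -tl, tl)
    g0 = float(params.backbone_gradient(t0))

    def inv_g(y: float) -> float:
        # |theta| at which the gradient equals y (y >= k_nz)
        if y <= params.k_nz:
            return 0.0
        return a * ((y - params.k_nz) / dk) ** (1 / 6)

    r_hi = min(inv_g(g0 + delta), tl)
    r_lo = inv_g(g0 - delta)
    if r_lo <= 0.0:
        lo, hi = -r_hi, r_hi
    elif t0 >= 0:  # pragma: no cover - offsets small in practice
        lo, hi = r_lo, r_hi
    else:  # pragma: no cover
        lo, hi = -r_hi, -r_lo
    # mean of k_nz + dk*(t/a)^6 over [lo, hi]
    return params.k_nz + dk * (hi**7 - lo**7) / (7 * a**6 * (hi - lo))


def ground_truth(params: HysteresisParams) -> LoopGroundTruth:
    """Closed-form ground truth for a loop simulated from ``params``."""
    tl = params.theta_limit()
    nz = _analytic_neutral_zone(params)
    s_pos = _analytic_initial_stiffness(params, +params.hysteresis_offset)
    s_neg = _analytic_initial_stiffness(params, -params.hysteresis_offset)
    return LoopGroundTruth(
        theta_limit=tl,
        rom_deg=2 * tl,
        nz_range=nz,
        nz_width_deg=None if nz is None else nz[1] - nz[0],
        k_nz=params.k_nz,
        initial_stiffness_pos=s_pos,
        initial_stiffness_neg=s_neg,
        final_stiffness=0.5 * (s_pos + s_neg),
    )


def simulate_loop(
    params: HysteresisParams,
    seed: int | np.random.Generator,
    specimen: str = "S1",
    loading_mode: str = "flexion_extension",
) -> LoadingRecord:
    """Simulate one cyclic torque-angle record.

    The angle follows a triangular waveform between the +/- torque-limit
    angles; each cycle is one full up sweep plus one full down sweep.  The
    loading (angle-increasing) branch carries +hysteresis_offset and the
    unloading branch -hysteresis_offset, so the loop encloses area like a
    real viscoelastic specimen.  Ground truth is attached to the record.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tl = params.theta_limit()
    step = params.angular_rate / params.sample_rate  # deg per sample
    n_half = max(int(round(2 * tl / step)), 4)  # samples per sweep

    up = np.linspace(-tl, tl, n_half, endpoint=False)
    down = np.linspace(tl, -tl, n_half, endpoint=False)
    angle = np.concatenate([np.concatenate([up, down]) for _ in range(params.n_cycles)])
    direction = np.concatenate(
        [np.concatenate([np.ones(n_half), -np.ones(n_half)]) for _ in range(params.n_cycles)]
    ).astype(int)
    cycle = np.repeat(np.arange(1, params.n_cycles + 1), 2 * n_half)
    time = np.arange(angle.size) / params.sample_rate

    torque = params.backbone_torque(angle) + params.hysteresis_offset * direction
    if params.noise_sd > 0:
        torque = torque + rng.normal(0.0, params.noise_sd, size=angle.size)

    return LoadingRecord(
        specimen=specimen,
        loading_mode=loading_mode,
        time_s=time,
        angle_deg=angle,
        torque_nm=torque,
        cycle=cycle,
        direction=direction,
        torque_limit=params.torque_limit,
        ground_truth=ground_truth(params),
    )
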
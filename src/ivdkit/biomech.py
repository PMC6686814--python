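"""Torque-angle analysis of cyclic spinal-segment tests.

Implements the standard functional-spinal-unit outcome measures from a
cyclic torque-angle record driven to a fixed torque limit:

* **ROM** — range of motion, the total angular deflection between the
  maximal-positive-torque and minimal-negative-torque samples of the final
  full cycle.
* **NZ** — neutral zone.  Each loading direction's branch of the final cycle
  is fitted with a seventh-order polynomial of torque on angle; the angular
  range where the fitted gradient is below 0.05 Nm/deg is found on a dense
  grid, and the final neutral zone is the common overlapping range of the
  two directions.  A branch with no sub-threshold region (e.g. axial
  rotation, which has no region of low stiffness) yields no neutral zone.
* **Initial / final stiffness** — per direction, the fitted gradient at the
  neutral position (the branch's zero-torque crossing), averaged over the
  maximal contiguous range where the gradient deviates from the
  neutral-position gradient by less than 0.05 Nm/deg; the final stiffness is
  the arithmetic mean of the two directions.

A seventh-order polynomial can contain several disjoint sub-threshold
gradient pockets; the per-direction neutral zone is taken as the pocket
containing the zero-torque crossing (or, failing that, the pocket nearest
to it), which resolves the ambiguity deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .synth.loops import NZ_GRADIENT_THRESHOLD, LoadingRecord

DEFAULT_POLY_DEGREE = 7
DEFAULT_GRID_STEP = 0.01  # deg; resolution of the gradient-threshold scan


@dataclass(frozen=True)
class DirectionFit:
    """Degree-7 least-squares fit of torque on angle for one loading branch."""

    poly: Polynomial
    domain: tuple[float, float]
    residual_rms: float
    direction: int

    def __call__(self, theta):
        self._check_domain(theta)
        return self.poly(np.asarray(theta, dtype=float))

    def gradient(self, theta):
        self._check_domain(theta)
        return self.poly.deriv()(np.asarray(theta, dtype=float))

    def _check_domain(self, theta) -> None:
        t = np.asarray(theta, dtype=float)
        lo, hi = self.domain
        eps = 1e-9 * max(1.0, abs(hi - lo))
        if np.any(t < lo - eps) or np.any(t > hi + eps):
            raise ValueError("evaluation outside fitted angle domain")


@dataclass(frozen=True)
class BiomechResult:
    """ROM, neutral zone and stiffness for one specimen x loading mode."""

    specimen: str
    loading_mode: str
    rom_deg: float
    nz_range: tuple[float, float] | None
    nz_width_deg: float | None
    initial_stiffness_pos: float
    initial_stiffness_neg: float
    final_stiffness: float
    threshold_used: float = NZ_GRADIENT_THRESHOLD


def extract_final_cycle(record: LoadingRecord) -> LoadingRecord:
    """Return only the last complete cycle of a cyclic record.

    A cycle is complete when it contains both loading directions and spans
    both angle extremes of the record (to within one sample spacing).
    """
    if record.cycle.size == 0:
        raise ValueError("incomplete record: no samples")
    step = np.median(np.abs(np.diff(record.angle_deg)))
    a_max, a_min = record.angle_deg.max(), record.angle_deg.min()
    for c in np.unique(record.cycle)[::-1]:
        m = record.cycle == c
        if (
            len(np.unique(record.direction[m])) == 2
            and record.angle_deg[m].max() >= a_max - step
            and record.angle_deg[m].min() <= a_min + step
        ):
            return LoadingRecord(
                specimen=record.specimen,
                loading_mode=record.loading_mode,
                time_s=record.time_s[m],
                angle_deg=record.angle_deg[m],
                torque_nm=record.torque_nm[m],
                cycle=record.cycle[m],
                direction=record.direction[m],
                torque_limit=record.torque_limit,
                ground_truth=record.ground_truth,
            )
    raise ValueError("incomplete record: no complete cycle found")


def compute_rom(cycle: LoadingRecord) -> float:
    """Angular deflection from maximal positive to minimal negative torque."""
    t = cycle.torque_nm
    if t.max() <= 0 or t.min() >= 0:
        raise ValueError("torque does not change sign; ROM undefined")
    rom = float(cycle.angle_deg[np.argmax(t)] - cycle.angle_deg[np.argmin(t)])
    return abs(rom)


def fit_direction(
    cycle: LoadingRecord, direction: int, degree: int = DEFAULT_POLY_DEGREE
) -> DirectionFit:
    """Least-squares polynomial of torque on angle for one loading branch."""
    m = cycle.direction == direction
    theta = cycle.angle_deg[m]
    torque = cycle.torque_nm[m]
    if theta.size < degree + 2:
        raise ValueError(f"need >= {degree + 2} samples in direction {direction}")
    if np.unique(theta).size < degree + 1:
        raise ValueError("rank deficiency: fewer distinct angles than coefficients")
    poly = Polynomial.fit(theta, torque, deg=degree)
    resid = torque - poly(theta)
    return DirectionFit(
        poly=poly,
        domain=(float(theta.min()), float(theta.max())),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        direction=direction,
    )


def _shared_grid(fit_pos: DirectionFit, fit_neg: DirectionFit, step: float) -> np.ndarray:
    lo = max(fit_pos.domain[0], fit_neg.domain[0])
    hi = min(fit_pos.domain[1], fit_neg.domain[1])
    if hi <= lo:
        raise ValueError("direction fits have disjoint angle domains")
    return np.arange(lo, hi + step / 2, step)


def _zero_crossing(fit: DirectionFit, grid: np.ndarray) -> float | None:
    """Zero-torque crossing of the fitted branch nearest to zero angle."""
    vals = fit.poly(grid)
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if idx.size == 0:
        return None
    mids = 0.5 * (grid[idx] + grid[idx + 1])
    return float(mids[np.argmin(np.abs(mids))])


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of contiguous True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _direction_nz(
    fit: DirectionFit, grid: np.ndarray, threshold: float
) -> tuple[float, float] | None:
    """Maximal contiguous sub-threshold gradient interval anchored at the
    branch's zero-torque crossing (strict '<' at the threshold)."""
    sub = fit.poly.deriv()(grid) < threshold
    runs = _runs(sub)
    if not runs:
        return None
    anchor = _zero_crossing(fit, grid)
    if anchor is None:
        anchor = 0.0
    best = None
    best_dist = np.inf
    for i0, i1 in runs:
        lo, hi = grid[i0], grid[i1 - 1]
        dist = 0.0 if lo <= anchor <= hi else min(abs(anchor - lo), abs(anchor - hi))
        if dist < best_dist:
            best, best_dist = (float(lo), float(hi)), dist
    return best


def neutral_zone(
    fit_pos: DirectionFit,
    fit_neg: DirectionFit,
    threshold: float = NZ_GRADIENT_THRESHOLD,
    grid_step: float = DEFAULT_GRID_STEP,
) -> tuple[float, float] | None:
    """Common overlapping low-gradient range of the two direction fits.

    Returns the intersection of the per-direction neutral zones, or None if
    either direction has no sub-threshold region or the intersection is
    empty.
    """
    grid = _shared_grid(fit_pos, fit_neg, grid_step)
    nz_p = _direction_nz(fit_pos, grid, threshold)
    nz_n = _direction_nz(fit_neg, grid, threshold)
    if nz_p is None or nz_n is None:
        return None
    lo = max(nz_p[0], nz_n[0])
    hi = min(nz_p[1], nz_n[1])
    if hi <= lo:
        return None
    return (lo, hi)


def initial_stiffness(
    fit: DirectionFit,
    delta_threshold: float = NZ_GRADIENT_THRESHOLD,
    grid_step: float = DEFAULT_GRID_STEP,
) -> float:
    """Fitted gradient at the neutral position, averaged over the contiguous
    range where the gradient stays within ``delta_threshold`` of it."""
    grid = np.arange(fit.domain[0], fit.domain[1] + grid_step / 2, grid_step)
    t0 = _zero_crossing(fit, grid)
    if t0 is None:
        raise ValueError("no neutral position: fitted torque does not cross zero")
    g = fit.poly.deriv()(grid)
    g0 = float(fit.poly.deriv()(t0))
    near = np.abs(g - g0) < delta_threshold
    i_anchor = int(np.argmin(np.abs(grid - t0)))
    near[i_anchor] = True  # numeric guard: the anchor itself is in-band
    for i0, i1 in _runs(near):
        if i0 <= i_anchor < i1:
            return float(np.mean(g[i0:i1]))
    raise AssertionError("unreachable: anchor forced into band")  # pragma: no cover


def final_stiffness(s_pos: float, s_neg: float) -> float:
    """Average of the two loading directions' initial stiffnesses."""
    return 0.5 * (s_pos + s_neg)


def analyze(
    record: LoadingRecord,
    threshold: float = NZ_GRADIENT_THRESHOLD,
    degree: int = DEFAULT_POLY_DEGREE,
    grid_step: float = DEFAULT_GRID_STEP,
) -> BiomechResult:
    """Full torque-angle analysis of one cyclic record."""
    cyc = extract_final_cycle(record)
    rom = compute_rom(cyc)
    fit_p = fit_direction(cyc, +1, degree=degree)
    fit_n = fit_direction(cyc, -1, degree=degree)
    nz = neutral_zone(fit_p, fit_n, threshold=threshold, grid_step=grid_step)
    s_p = initial_stiffness(fit_p, delta_threshold=threshold, grid_step=grid_step)
    s_n = initial_stiffness(fit_n, delta_threshold=threshold, grid_step=grid_step)
    return BiomechResult(
        specimen=record.specimen,
        loading_mode=record.loading_mode,
        rom_deg=rom,
        nz_range=nz,
        nz_width_deg=None if nz is None else nz[1] - nz[0],
        initial_stiffness_pos=s_p,
        initial_stiffness_neg=s_n,
        final_stiffness=final_stiffness(s_p, s_n),
        threshold_used=threshold,
    )
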
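"""Synthetic two-observer histopathology score sheets with exact moments.

Observer 1 draws each criterion score from a discretised, range-clipped
normal distribution centred on the criterion mean; observer 2 re-scores the
same section with small ordinal jitter (+/-1 with probability ``jitter_p``
each way, clipped to the criterion range).  Because every step of the chain
(discretisation, clipping, jitter, rounded-mean consensus, summation over
criteria) is discrete, the exact mean and SD of the cohort-level cumulative
consensus score have closed forms; presets use them to calibrate criterion
means so cohort expectations equal target summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from ..histopath import CRITERIA, ScoringScheme
from .design import StudyDesign, substream


def criterion_pmf(mu: float, sigma: float, cmax: int) -> np.ndarray:
    """PMF over {0..cmax} of round-half-up(N(mu, sigma)) clipped to range."""
    k = np.arange(cmax + 1)
    if sigma == 0:
        p = np.zeros(cmax + 1)
        p[int(np.clip(np.floor(mu + 0.5), 0, cmax))] = 1.0
        return p
    upper = norm.cdf((k + 0.5 - mu) / sigma)
    lower = norm.cdf((k - 0.5 - mu) / sigma)
    p = upper - lower
    p[0] = upper[0]          # fold lower tail
    p[-1] = 1.0 - lower[-1]  # fold upper tail
    return p


def consensus_moments(
    mu: float, sigma: float, cmax: int, jitter_p: float
) -> tuple[float, float]:
    """Exact (mean, variance) of one criterion's consensus score.

    Consensus = round-half-up of the two-observer mean.  With observer 2 =
    clip(observer 1 + J), J in {-1, 0, +1}, the consensus equals observer 1
    plus one only when J = +1 and the score is below the criterion maximum.
    """
    p = criterion_pmf(mu, sigma, cmax)
    k = np.arange(cmax + 1)
    up = jitter_p * (k < cmax)  # probability the consensus exceeds observer 1
    e1 = float(np.sum(p * (k + up)))
    e2 = float(np.sum(p * ((1 - up) * k**2 + up * (k + 1) ** 2)))
    return e1, e2 - e1**2


def cumulative_moments(
    mus: np.ndarray, sigma: float, scheme: ScoringScheme, jitter_p: float
) -> tuple[float, float]:
    """Exact (mean, SD) of the consensus cumulative score (criteria independent)."""
    stats = [
        consensus_moments(mu, sigma, scheme.criterion_max[c], jitter_p)
        for mu, c in zip(mus, scheme.criteria)
    ]
    return float(sum(m for m, _ in stats)), float(np.sqrt(sum(v for _, v in stats)))


def generate_histo_profiles(
    preset,
    design: StudyDesign,
    seed: int,
    scheme: ScoringScheme | None = None,
    label: str | None = None,
) -> pd.DataFrame:
    """Two-observer score sheets for one cohort (one L1L2 disc per sheep).

    Long table: (disc_id, sheep, observer, criterion, score, true_mu).
    """
    label = label or preset.name
    scheme = scheme or ScoringScheme()
    mus = np.asarray(preset.histo_criterion_means, dtype=float)
    sigma = preset.histo_criterion_sd
    jp = preset.observer_jitter_p
    for mu, c in zip(mus, scheme.criteria):
        if not (0.0 <= mu <= scheme.criterion_max[c]):
            raise ValueError(f"criterion {c}: mean {mu} outside [0, {scheme.criterion_max[c]}]")
    rng = substream(seed, "histo", label)
    rows = []
    for i in range(1, design.n_sheep_per_cell + 1):
        sheep = f"{label}-{i:02d}"
        disc_id = f"{sheep}-L1L2"
        for c, mu in zip(scheme.criteria, mus):
            cmax = scheme.criterion_max[c]
            if sigma == 0:
                s1 = int(np.clip(np.floor(mu + 0.5), 0, cmax))
            else:
                s1 = int(np.clip(np.floor(rng.normal(mu, sigma) + 0.5), 0, cmax))
            j = rng.choice([-1, 0, 1], p=[jp, 1 - 2 * jp, jp])
            s2 = int(np.clip(s1 + j, 0, cmax))
            for obs, s in (("obs1", s1), ("obs2", s2)):
                rows.append(
                    {
                        "disc_id": disc_id,
                        "sheep": sheep,
                        "observer": obs,
                        "criterion": c,
                        "score": s,
                        "true_mu": mu,
                    }
                )
    return pd.DataFrame(rows)


def calibrate_criterion_means(
    base_means: np.ndarray,
    target_mean: float,
    target_sd: float,
    scheme: ScoringScheme | None = None,
    jitter_p_cap: float = 0.15,
) -> tuple[np.ndarray, float, float]:
    """Solve for (criterion means, criterion SD, jitter probability) such
    that the exact consensus cumulative score has the target mean and SD.

    A common additive shift of the base means controls the mean and a common
    per-criterion SD controls the dispersion; the two are solved by a short
    fixed-point alternation (each sub-problem is monotone).  The observer
    jitter probability is tied to the criterion SD (min(cap, sigma^2)) so
    that near-deterministic cohorts also have near-perfect inter-observer
    agreement, as the dispersion of the printed summaries implies.
    """
    from scipy.optimize import brentq

    scheme = scheme or ScoringScheme()
    base = np.asarray(base_means, dtype=float)
    maxima = np.array([scheme.criterion_max[c] for c in scheme.criteria], dtype=float)

    def jp(sigma: float) -> float:
        return min(jitter_p_cap, sigma**2)

    def mean_of(shift: float, sigma: float) -> float:
        mus = np.clip(base + shift, 0.0, maxima)
        return cumulative_moments(mus, sigma, scheme, jp(sigma))[0]

    def sd_of(shift: float, sigma: float) -> float:
        mus = np.clip(base + shift, 0.0, maxima)
        return cumulative_moments(mus, sigma, scheme, jp(sigma))[1]

    shift, sigma = 0.0, max(target_sd / np.sqrt(len(base)), 1e-3)
    for _ in range(6):
        shift = brentq(lambda d: mean_of(d, sigma) - target_mean, -3.0, 3.0, xtol=1e-10)
        sigma = brentq(lambda s: sd_of(shift, s) - target_sd, 1e-4, 4.0, xtol=1e-10)
    mus = np.clip(base + shift, 0.0, maxima)
    return mus, sigma, jp(sigma)
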
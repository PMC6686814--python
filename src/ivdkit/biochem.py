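"""Standard-curve quantitation of sulfated GAG and hydroxyproline.

Both chromogenic assays (DMMB dye binding for sulfated glycosaminoglycan,
the dimethylaminobenzaldehyde reaction for hydroxyproline) are used in their
linear range, so calibration is an ordinary least-squares line of signal on
known analyte amount.  Sample amounts are back-calculated from the mean of
triplicate signals and expressed per mg wet tissue after scaling by the
digest-volume / aliquot-volume dilution factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress


@dataclass(frozen=True)
class StandardCurve:
    analyte: str
    slope: float       # signal per µg
    intercept: float
    r_squared: float
    amount_range: tuple[float, float]

    def amount(self, signal) -> np.ndarray:
        """Back-calculated µg for a signal (vectorised)."""
        return (np.asarray(signal, dtype=float) - self.intercept) / self.slope

    def in_range(self, signal) -> np.ndarray:
        a = self.amount(signal)
        return (a >= self.amount_range[0]) & (a <= self.amount_range[1])


@dataclass(frozen=True)
class ZonalResult:
    sheep: str
    zone: str
    ug_per_mg: float
    ug_per_mg_sd: float   # propagated from replicate scatter
    extrapolated: bool
    clamped: bool


def fit_standard_curve(standards: pd.DataFrame, analyte: str = "GAG") -> StandardCurve:
    """OLS line through a (amount_ug, signal) standard series."""
    amounts = np.asarray(standards["amount_ug"], dtype=float)
    signals = np.asarray(standards["signal"], dtype=float)
    if np.unique(amounts).size < 3:
        raise ValueError("need >= 3 distinct standard amounts")
    fit = linregress(amounts, signals)
    if fit.slope == 0:
        raise ValueError("flat standard curve")  # pragma: no cover
    return StandardCurve(
        analyte=analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        amount_range=(float(amounts.min()), float(amounts.max())),
    )


def quantify(
    signals: np.ndarray,
    wet_weight_mg: float,
    curve: StandardCurve,
    dilution_factor: float,
    sheep: str = "",
    zone: str = "",
) -> ZonalResult:
    """µg analyte per mg wet tissue from triplicate signals.

    Signals outside the calibrated range are flagged ``extrapolated`` but
    still quantified; negative back-calculated amounts are clamped to zero
    and flagged ``clamped``.
    """
    signals = np.asarray(signals, dtype=float)
    if wet_weight_mg <= 0:
        raise ValueError("wet weight must be > 0")
    mean_sig = float(np.mean(signals))
    amount = float(curve.amount(mean_sig))
    extrapolated = not bool(curve.in_range(mean_sig))
    clamped = amount < 0
    amount = max(amount, 0.0)
    per_rep = np.maximum(curve.amount(signals), 0.0) * dilution_factor / wet_weight_mg
    return ZonalResult(
        sheep=sheep,
        zone=zone,
        ug_per_mg=amount * dilution_factor / wet_weight_mg,
        ug_per_mg_sd=float(np.std(per_rep, ddof=1)) if signals.size > 1 else 0.0,
        extrapolated=extrapolated,
        clamped=clamped,
    )


def quantify_table(
    samples: pd.DataFrame, curve: StandardCurve, dilution_factor: float
) -> pd.DataFrame:
    """Quantify every (sheep, zone) triplicate group of a sample table."""
    rows = []
    for (sheep, zone), g in samples.groupby(["sheep", "zone"], sort=False):
        res = quantify(
            g["signal"].to_numpy(),
            float(g["wet_weight_mg"].iloc[0]),
            curve,
            dilution_factor,
            sheep=str(sheep),
            zone=str(zone),
        )
        rows.append(
            {
                "sheep": sheep,
                "zone": zone,
                "analyte": curve.analyte,
                "ug_per_mg": res.ug_per_mg,
                "ug_per_mg_sd": res.ug_per_mg_sd,
                "extrapolated": res.extrapolated,
                "clamped": res.clamped,
            }
        )
    return pd.DataFrame(rows)
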
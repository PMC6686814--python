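"""Relative copy-number quantitation from qPCR Ct values.

Per-gene standard curves fitted to pooled-cDNA dilution series follow
Ct = intercept + slope * log10(copies); amplification efficiency is
10^(-1/slope) - 1 (slope -3.32 at 100%).  Sample relative copy numbers are
back-calculated from the mean of triplicate Cts and normalised by the total
RNA loaded into the reaction — deliberately not by a housekeeping gene,
whose expression shifts with disease state.  Copy numbers are anchored to
the top standard (relative copies = 1).  Cohort effects are summarised as
fold changes of group geometric means over the nonoperated-control
geometric mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress


@dataclass(frozen=True)
class GeneStandardCurve:
    gene: str
    slope: float       # Ct per log10(copies); negative
    intercept: float   # Ct at relative copies = 1
    r_squared: float
    ct_range: tuple[float, float]

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def copies(self, ct) -> np.ndarray:
        return 10.0 ** ((np.asarray(ct, dtype=float) - self.intercept) / self.slope)


def fit_ct_curve(dilutions: pd.DataFrame, gene: str = "") -> GeneStandardCurve:
    """OLS fit of Ct on log10(relative copies) for one gene's series."""
    x = np.asarray(dilutions["log10_copies"], dtype=float)
    y = np.asarray(dilutions["ct"], dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 dilutions")
    fit = linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(f"non-amplifying standard for gene {gene or '?'}")
    curve = GeneStandardCurve(
        gene=gene or str(dilutions.get("gene", pd.Series(["?"])).iloc[0]),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        ct_range=(float(y.min()), float(y.max())),
    )
    if not (0.0 < curve.efficiency <= 1.2):
        raise ValueError(f"implausible amplification efficiency {curve.efficiency:.2f}")
    return curve


def fit_ct_curves(standards: pd.DataFrame) -> dict[str, GeneStandardCurve]:
    return {
        str(gene): fit_ct_curve(g, gene=str(gene))
        for gene, g in standards.groupby("gene", sort=False)
    }


def relative_copies(
    ct_table: pd.DataFrame,
    curves: dict[str, GeneStandardCurve],
    replicate_range_flag: float = 1.0,
) -> pd.DataFrame:
    """RNA-normalised relative copy number per (sample, gene).

    Triplicates are summarised by mean Ct before back-calculation; groups
    whose replicate Ct range exceeds ``replicate_range_flag`` cycles, or
    whose mean Ct falls outside the standard-curve range, are flagged.
    """
    rows = []
    keys = [c for c in ("sheep", "zone", "disc_level") if c in ct_table.columns]
    for key, g in ct_table.groupby(keys + ["gene"], sort=False):
        gene = str(key[-1])
        if gene not in curves:
            raise KeyError(f"no standard curve for gene {gene}")
        curve = curves[gene]
        cts = g["ct"].to_numpy(dtype=float)
        mean_ct = float(np.mean(cts))
        loading = float(g["rna_loading_ug"].iloc[0])
        if loading <= 0:
            raise ValueError("RNA loading must be > 0")
        row = dict(zip(keys, key[:-1]))
        row.update(
            {
                "gene": gene,
                "mean_ct": mean_ct,
                "rel_copies_per_ug": float(curve.copies(mean_ct)) / loading,
                "replicate_outlier": bool(cts.max() - cts.min() > replicate_range_flag),
                "ct_out_of_range": not (
                    curve.ct_range[0] <= mean_ct <= curve.ct_range[1]
                ),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def fold_vs_noc(
    copies: pd.DataFrame, group_col: str = "cohort", noc_label: str = "NOC"
) -> pd.DataFrame:
    """Fold change of each cohort's geometric mean over the NOC geometric
    mean, per gene (and per zone when present)."""
    keys = ["gene"] + (["zone"] if "zone" in copies.columns else [])
    gm = (
        copies.assign(logc=np.log(copies["rel_copies_per_ug"]))
        .groupby(keys + [group_col])["logc"]
        .mean()
        .reset_index()
    )
    noc = gm[gm[group_col] == noc_label].set_index(keys)["logc"]
    if noc.empty:
        raise ValueError(f"no {noc_label} cohort present")
    out = gm[gm[group_col] != noc_label].copy()
    idx = pd.MultiIndex.from_frame(out[keys]) if len(keys) > 1 else out[keys[0]]
    out["fold_change"] = np.exp(out["logc"].to_numpy() - noc.loc[idx].to_numpy())
    return out.drop(columns="logc")
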
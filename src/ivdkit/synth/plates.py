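"""Synthetic plate-reader and qPCR tables.

Generates (i) a chondroitin-sulfate standard series and triplicate sample
absorbances for the DMMB sulfated-GAG assay, (ii) the analogous series for
the hydroxyproline (Stegemann-Stalder) assay, and (iii) per-gene qPCR
dilution-series standards plus triplicate sample Ct values.  Sample signals
are back-computed from the preset's zonal tissue contents (µg analyte per mg
wet tissue) through the same volume bookkeeping the quantitation stage uses,
so zero-noise generation round-trips exactly.

qPCR standards follow the log-linear model Ct = intercept + slope*log10(c)
with slope = -1/log10(1 + efficiency); sample copy numbers are relative to
the top standard (= 1) and scale with the RNA loading of each reaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import StudyDesign, substream

GENES = (
    "COL1A1", "COL2A1", "ACAN", "IL1RN", "MMP2", "MMP3", "MMP9", "MMP13",
    "ADAMTS4", "ADAMTS5", "TIMP1", "TIMP3",
)


@dataclass(frozen=True)
class AssayConfig:
    """Volume bookkeeping and calibration shape of one chromogenic assay."""

    analyte: str
    standard_amounts_ug: tuple[float, ...]
    slope: float               # signal per µg
    intercept: float           # blank signal
    digest_volume_ul: float = 2000.0
    aliquot_volume_ul: float = 10.0
    signal_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        amounts = np.asarray(self.standard_amounts_ug)
        if amounts.size < 3 or np.any(np.diff(amounts) <= 0):
            raise ValueError("standard series must be >= 3 strictly increasing amounts")

    @property
    def dilution_factor(self) -> float:
        return self.digest_volume_ul / self.aliquot_volume_ul


GAG_ASSAY = AssayConfig(
    analyte="GAG",
    standard_amounts_ug=(0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0),
    slope=0.020,
    intercept=0.05,
    aliquot_volume_ul=10.0,
    signal_noise_sd=0.004,
)

HYP_ASSAY = AssayConfig(
    analyte="hydroxyproline",
    standard_amounts_ug=(0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0),
    slope=0.080,
    intercept=0.04,
    aliquot_volume_ul=4.0,
    signal_noise_sd=0.004,
)


def generate_standards(assay: AssayConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for amt in assay.standard_amounts_ug:
        for rep in (1, 2, 3):
            sig = assay.intercept + assay.slope * amt
            if assay.signal_noise_sd > 0:
                sig += rng.normal(0.0, assay.signal_noise_sd)
            rows.append({"amount_ug": amt, "replicate": rep, "signal": sig})
    return pd.DataFrame(rows)


def generate_assay_samples(
    preset, design: StudyDesign, assay: AssayConfig, seed: int, label: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(standards, samples) tables for one cohort and one analyte.

    Samples carry triplicate signals per (sheep, zone) with recorded wet
    weights and the generator's true µg/mg.
    """
    label = label or preset.name
    zonal = preset.gag_ug_per_mg if assay.analyte == "GAG" else preset.hyp_ug_per_mg
    rng = substream(seed, "plate", assay.analyte, label)
    standards = generate_standards(assay, rng)
    rows = []
    for i in range(1, design.n_sheep_per_cell + 1):
        sheep = f"{label}-{i:02d}"
        for zone in design.zones:
            mean, sd = zonal[zone]
            true = -1.0
            while true <= 0:
                true = rng.normal(mean, sd)
            weight = rng.uniform(120.0, 180.0)  # mg wet tissue digested
            amount_in_aliquot = true * weight / assay.dilution_factor
            for rep in (1, 2, 3):
                sig = assay.intercept + assay.slope * amount_in_aliquot
                if assay.signal_noise_sd > 0:
                    sig += rng.normal(0.0, assay.signal_noise_sd)
                rows.append(
                    {
                        "sheep": sheep,
                        "zone": zone,
                        "disc_level": "L5L6",
                        "wet_weight_mg": weight,
                        "replicate": rep,
                        "signal": sig,
                        "true_ug_per_mg": true,
                    }
                )
    return standards, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR

QPCR_SLOPE_100 = -1.0 / np.log10(2.0)  # Ct per log10(copies) at 100% efficiency
QPCR_INTERCEPT = 18.0                  # Ct of the top standard (relative copies = 1)
QPCR_DILUTIONS = (0, -1, -2, -3, -4)   # log10 relative copies of the series
#: anchor expression of the NOC cohort, relative copies per µg RNA
BASE_EXPRESSION = 1.0e-3


def generate_qpcr_standards(
    rng: np.random.Generator,
    genes: tuple[str, ...] = GENES,
    slope: float = QPCR_SLOPE_100,
    ct_noise_sd: float = 0.0,
) -> pd.DataFrame:
    if slope >= 0:
        raise ValueError("non-amplifying standard: slope must be negative")
    rows = []
    for gene in genes:
        for log10c in QPCR_DILUTIONS:
            for rep in (1, 2, 3):
                ct = QPCR_INTERCEPT + slope * log10c
                if ct_noise_sd > 0:
                    ct += rng.normal(0.0, ct_noise_sd)
                rows.append(
                    {"gene": gene, "log10_copies": float(log10c), "replicate": rep, "ct": ct}
                )
    return pd.DataFrame(rows)


def generate_qpcr_samples(
    preset,
    design: StudyDesign,
    seed: int,
    slope: float = QPCR_SLOPE_100,
    ct_noise_sd: float = 0.15,
    label: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(standards, ct_table) for one cohort's L3L4 discs, all zones/genes."""
    label = label or preset.name
    rng = substream(seed, "qpcr", label)
    standards = generate_qpcr_standards(rng, ct_noise_sd=min(ct_noise_sd, 0.05))
    rows = []
    for i in range(1, design.n_sheep_per_cell + 1):
        sheep = f"{label}-{i:02d}"
        for zone in design.zones:
            loading = rng.uniform(0.8, 1.2)  # µg total RNA in the reaction
            for gene in GENES:
                mult = preset.expr_mult.get(gene, 1.0)
                mult = mult[zone] if isinstance(mult, dict) else mult
                copies = BASE_EXPRESSION * mult * loading
                ct_true = QPCR_INTERCEPT + slope * np.log10(copies)
                for rep in (1, 2, 3):
                    ct = ct_true + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                    rows.append(
                        {
                            "sheep": sheep,
                            "zone": zone,
                            "disc_level": "L3L4",
                            "gene": gene,
                            "replicate": rep,
                            "ct": ct,
                            "rna_loading_ug": loading,
                            "true_mult": mult,
                        }
                    )
    return standards, pd.DataFrame(rows)
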
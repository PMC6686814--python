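"""Named cohort presets: the study conditions the generator emulates.

Four archetypes cover the cohort states the downstream analyses compare:

* ``NOC`` — age-matched nonoperated control discs.
* ``degenerate-baseline`` — lesion discs at the time of injection, after
  4-12 weeks of degeneration (cumulative histopathology 22 +/- 2.2).
* ``PBS-endpoint`` — vehicle-injected lesion discs at study completion
  (histopathology remains 19 +/- 2.5; 15-25% disc height loss; catabolic
  gene expression elevated; GAG depleted).
* ``MSC-endpoint`` — MSC-injected lesion discs at study completion
  (histopathology 4 +/- 0.4; 92-95% of pre-lesion disc height re-attained;
  expression and GAG normalised toward NOC).

Histopathology criterion means are calibrated at load time so the EXACT
expectation and SD of the consensus cumulative score equal the cohort
summary targets; the per-criterion allocation of those totals (``histo_base``
below) is an implementer choice, not study data.  Biomechanical presets are
long-plateau dual-stiffness loops (plateau gradient well below the
0.05 Nm/deg laxity threshold, neutral zones 6-8.5 deg wide, ROM 12-17 deg),
representative of lumbar segments tested to +/-5 Nm with posterior elements
removed; established-lesion discs are laxer (wider NZ, lower elastic
stiffness) and MSC-treated discs sit between lesion and control.  Axial
rotation is stiff everywhere (no sub-threshold gradient region, hence no
neutral zone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from ..histopath import ScoringScheme
from .histo import calibrate_criterion_means
from .loops import HysteresisParams

#: canonical torque-angle loop for demonstrations and recovery properties
DEFAULT_LOOP = HysteresisParams(
    k_nz=0.015, k_el=0.7, nz_half_width=3.4, hysteresis_offset=0.02, noise_sd=0.05
)


@dataclass(frozen=True)
class CohortPreset:
    """Generator parameters for one cohort state."""

    name: str
    loop_params: dict[str, HysteresisParams]
    dhi_ratio_mean: float
    dhi_ratio_sd: float
    histo_criterion_means: tuple[float, ...]
    histo_criterion_sd: float
    observer_jitter_p: float
    histo_target: tuple[float, float]  # (mean, sd) of consensus cumulative score
    gag_ug_per_mg: dict[str, tuple[float, float]]
    hyp_ug_per_mg: dict[str, tuple[float, float]]
    expr_mult: dict[str, float | dict[str, float]]

    def __post_init__(self) -> None:
        if not (0.0 < self.dhi_ratio_mean <= 1.2):
            raise ValueError("dhi_ratio_mean must lie in (0, 1.2]")
        if self.dhi_ratio_sd < 0 or self.histo_criterion_sd < 0:
            raise ValueError("dispersions must be >= 0")
        for table in (self.gag_ug_per_mg, self.hyp_ug_per_mg):
            for zone, (m, s) in table.items():
                if m <= 0 or s < 0:
                    raise ValueError(f"invalid zonal content for {zone}")


def _loops(fe, lb, ar) -> dict[str, HysteresisParams]:
    return {
        "flexion_extension": HysteresisParams(*fe),
        "lateral_bending": HysteresisParams(*lb),
        "axial_rotation": HysteresisParams(*ar),
    }


# (k_nz, k_el, nz_half_width, hysteresis_offset, torque_limit, rate, fs, cycles, noise)
_NOISE = 0.05
_ARCHETYPES: dict[str, dict] = {
    "NOC": dict(
        loops=_loops(
            (0.020, 0.70, 3.0, 0.02, 5.0, 5.0, 20.0, 10, _NOISE),
            (0.020, 0.80, 2.8, 0.02, 5.0, 5.0, 20.0, 10, _NOISE),
            (1.60, 2.20, 2.0, 0.30, 5.0, 5.0, 20.0, 10, _NOISE),
        ),
        dhi=(1.00, 0.015),
        histo_base=(1, 1, 1, 0, 0, 0),
        histo_target=(3.0, 0.8),
        gag={"AF1": (18, 2.0), "AF2": (28, 3.0), "NP": (45, 5.0)},
        hyp={"AF1": (20, 2.0), "AF2": (15, 2.0), "NP": (8, 1.0)},
        expr={g: 1.0 for g in (
            "COL1A1", "COL2A1", "ACAN", "IL1RN", "MMP2", "MMP3", "MMP9", "MMP13",
            "ADAMTS4", "ADAMTS5", "TIMP1", "TIMP3")},
    ),
    "degenerate-baseline": dict(
        loops=_loops(
            (0.014, 0.55, 4.0, 0.02, 5.0, 5.0, 20.0, 10, _NOISE),
            (0.015, 0.60, 3.8, 0.02, 5.0, 5.0, 20.0, 10, _NOISE),
            (1.20, 1.80, 2.0, 0.30, 5.0, 5.0, 20.0, 10, _NOISE),
        ),
        dhi=(0.88, 0.03),
        histo_base=(4, 4, 4, 4, 3, 3),
        histo_target=(22.0, 2.2),
        gag={"AF1": (13, 2.0), "AF2": (20, 3.0), "NP": (25, 4.0)},
        hyp={"AF1": (24, 3.0), "AF2": (17, 2.0), "NP": (10, 1.5)},
        expr={
            "COL1A1": 1.8, "COL2A1": 0.55, "ACAN": 0.5, "IL1RN": 1.8,
            "MMP2": 2.5, "MMP3": 5.0, "MMP9": 3.5, "MMP13": 4.0,
            "ADAMTS4": 3.5, "ADAMTS5": 2.5, "TIMP1": 1.4, "TIMP3": 1.3,
        },
    ),
    "PBS-endpoint": dict(
        loops=_loops(
            (0.014, 0.55, 4.2, 0.02, 5.0, 5.0, 20.0, 10, _NOISE),
            (0.015, 0.60, 4.0, 0.02, 5.0, 5.0, 20.0, 10, _NOISE),
            (1.25, 1.80, 2.0, 0.30, 5.0, 5.0, 20.0, 10, _NOISE),
        ),
        dhi=(0.80, 0.04),
        histo_base=(4, 4, 3, 3, 3, 2),
        histo_target=(19.0, 2.5),
        gag={"AF1": (13, 2.0), "AF2": (20, 3.0), "NP": (25, 4.0)},
        hyp={"AF1": (25, 3.0), "AF2": (18, 2.0), "NP": (10, 1.5)},
        expr={
            "COL1A1": 2.0, "COL2A1": 0.5, "ACAN": 0.5, "IL1RN": 2.0,
            "MMP2": 3.0, "MMP3": 6.0, "MMP9": 4.0, "MMP13": 5.0,
            "ADAMTS4": 4.0, "ADAMTS5": 3.0, "TIMP1": 1.5, "TIMP3": 1.5,
        },
    ),
    "MSC-endpoint": dict(
        loops=_loops(
            (0.018, 0.65, 3.4, 0.02, 5.0, 5.0, 20.0, 10, _NOISE),
            (0.018, 0.70, 3.1, 0.02, 5.0, 5.0, 20.0, 10, _NOISE),
            (1.50, 2.10, 2.0, 0.30, 5.0, 5.0, 20.0, 10, _NOISE),
        ),
        dhi=(0.935, 0.02),
        histo_base=(1, 1, 1, 0, 1, 0),
        histo_target=(4.0, 0.4),
        gag={"AF1": (17, 2.0), "AF2": (27, 3.0), "NP": (42, 5.0)},
        hyp={"AF1": (21, 2.0), "AF2": (15, 2.0), "NP": (8, 1.0)},
        expr={
            "COL1A1": 1.2, "COL2A1": 1.3, "ACAN": 1.2, "IL1RN": 1.2,
            "MMP2": 1.2, "MMP3": 1.3, "MMP9": 1.1, "MMP13": 1.2,
            "ADAMTS4": 1.2, "ADAMTS5": 1.1, "TIMP1": 1.2, "TIMP3": 1.1,
        },
    ),
}

PRESET_NAMES = tuple(_ARCHETYPES)


@lru_cache(maxsize=None)
def get_preset(name: str) -> CohortPreset:
    """Load a named preset, calibrating its histopathology distributions."""
    if name not in _ARCHETYPES:
        raise KeyError(f"unknown preset {name!r}; known: {PRESET_NAMES}")
    a = _ARCHETYPES[name]
    mean, sd = a["histo_target"]
    mus, sigma, jp = calibrate_criterion_means(
        np.asarray(a["histo_base"], dtype=float), mean, sd, scheme=ScoringScheme()
    )
    return CohortPreset(
        name=name,
        loop_params=a["loops"],
        dhi_ratio_mean=a["dhi"][0],
        dhi_ratio_sd=a["dhi"][1],
        histo_criterion_means=tuple(float(m) for m in mus),
        histo_criterion_sd=float(sigma),
        observer_jitter_p=float(jp),
        histo_target=(float(mean), float(sd)),
        gag_ug_per_mg=a["gag"],
        hyp_ug_per_mg=a["hyp"],
        expr_mult=dict(a["expr"]),
    )


def preset_for_cell(group: str, arm: str) -> CohortPreset:
    """Map a (group, arm) study cell to its cohort archetype."""
    if group == "NOC" or arm == "none":
        return get_preset("NOC")
    if arm == "PBS":
        return get_preset("PBS-endpoint")
    if arm == "MSC":
        return get_preset("MSC-endpoint")
    raise ValueError(f"no preset for cell ({group}, {arm})")
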
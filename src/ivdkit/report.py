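"""End-to-end synthetic study: generate, analyse, compare, summarise.

``run_study`` builds a complete synthetic cohort study from the named
presets, pushes every modality through its analysis stage (torque-angle
biomechanics, disc height index, consensus histopathology scoring,
standard-curve biochemistry, qPCR quantitation), compares MSC against PBS
arms within each lesion group by exact Mann-Whitney tests under a
study-wide Benjamini-Hochberg correction, and appends a ground-truth
recovery table comparing every estimate with the generator's analytic
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import biochem, biomech, qpcr, radiograph
from .histopath import ScoringScheme, cohort_scores, consensus_cumulative_scores
from .stats import ComparisonResult, apply_bh, mann_whitney_u
from .synth import landmarks as lmgen
from .synth import plates
from .synth.design import LOADING_MODES, StudyDesign, substream
from .synth.histo import generate_histo_profiles
from .synth.loops import simulate_loop
from .synth.presets import preset_for_cell


@dataclass
class StudyReport:
    design: StudyDesign
    seed: int
    biomech_results: pd.DataFrame
    dhi_results: pd.DataFrame
    histo_results: pd.DataFrame
    biochem_results: pd.DataFrame
    qpcr_results: pd.DataFrame
    qpcr_folds: pd.DataFrame
    comparisons: list[ComparisonResult] = field(default_factory=list)
    recovery: pd.DataFrame | None = None

    def cohort_summaries(self, table: pd.DataFrame, value: str) -> pd.DataFrame:
        rows = []
        for (g, a), sub in table.groupby(["group", "arm"], sort=False):
            s = cohort_scores(sub[value].dropna())
            s.update({"group": g, "arm": a, "endpoint": value})
            rows.append(s)
        return pd.DataFrame(rows)

    def comparison_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.comparisons])

    def summary(self) -> dict:
        """JSON-able digest of the study."""
        comp = self.comparison_frame()
        return {
            "seed": self.seed,
            "n_sheep": len(self.design.sheep_ids()),
            "histo": self.cohort_summaries(self.histo_results, "cumulative").to_dict("records"),
            "percent_dhi": self.cohort_summaries(self.dhi_results, "percent_dhi").to_dict("records"),
            "n_comparisons": int(len(comp)),
            "n_significant": int(comp["significant"].sum()) if len(comp) else 0,
            "bh_corrected_threshold": (
                float(comp.loc[comp["significant"], "p_value"].max())
                if len(comp) and comp["significant"].any()
                else None
            ),
        }


def _cell_label(group: str, arm: str) -> str:
    return f"{group}-{arm}"


def _generate_and_analyze(design: StudyDesign, seed: int, scheme: ScoringScheme):
    bio_rows, dhi_rows, histo_frames, chem_frames, qpcr_frames = [], [], [], [], []
    for group, arm in design.cells():
        preset = preset_for_cell(group, arm)
        label = _cell_label(group, arm)

        # --- biomechanics: one L5L6 record per sheep per loading mode
        for i in range(1, design.n_sheep_per_cell + 1):
            sheep = f"{label}-{i:02d}"
            for mode in LOADING_MODES:
                rng = substream(seed, "loop", label, sheep, mode)
                rec = simulate_loop(
                    preset.loop_params[mode], rng, specimen=sheep, loading_mode=mode
                )
                res = biomech.analyze(rec)
                gt = rec.ground_truth
                bio_rows.append(
                    {
                        "sheep": sheep, "group": group, "arm": arm, "loading_mode": mode,
                        "rom_deg": res.rom_deg,
                        "nz_width_deg": res.nz_width_deg,
                        "final_stiffness": res.final_stiffness,
                        "true_rom_deg": gt.rom_deg,
                        "true_nz_width_deg": gt.nz_width_deg,
                        "true_final_stiffness": gt.final_stiffness,
                    }
                )

        # --- radiographs: paired pre/endpoint landmark sets, all levels
        lm = lmgen.generate_landmarks(preset, design, seed, label=label)
        for (sheep, level), sub in lm.groupby(["sheep", "disc_level"], sort=False):
            pre = lmgen.landmarks_from_frame(sub[sub.timepoint == "pre_surgery"])
            end = lmgen.landmarks_from_frame(sub[sub.timepoint == "endpoint"])
            r = radiograph.percent_dhi(end, pre)
            dhi_rows.append(
                {
                    "sheep": sheep, "group": group, "arm": arm, "disc_level": level,
                    "dhi": r.dhi, "percent_dhi": r.percent_dhi,
                    "true_percent_dhi": 100.0 * float(sub["true_dhi_ratio"].iloc[0]),
                }
            )

        # --- histopathology: two-observer consensus cumulative scores
        sheets = generate_histo_profiles(preset, design, seed, scheme=scheme, label=label)
        cum = consensus_cumulative_scores(sheets, scheme)
        cum["group"], cum["arm"] = group, arm
        histo_frames.append(cum)

        # --- biochemistry: GAG and hydroxyproline per zone
        for assay in (plates.GAG_ASSAY, plates.HYP_ASSAY):
            standards, samples = plates.generate_assay_samples(
                preset, design, assay, seed, label=label
            )
            curve = biochem.fit_standard_curve(standards, analyte=assay.analyte)
            q = biochem.quantify_table(samples, curve, assay.dilution_factor)
            q["group"], q["arm"] = group, arm
            truth = samples.groupby(["sheep", "zone"], sort=False)["true_ug_per_mg"].first()
            q["true_ug_per_mg"] = truth.loc[
                pd.MultiIndex.from_frame(q[["sheep", "zone"]])
            ].to_numpy()
            chem_frames.append(q)

        # --- qPCR: RNA-normalised relative copies
        standards, cts = plates.generate_qpcr_samples(preset, design, seed, label=label)
        curves = qpcr.fit_ct_curves(standards)
        rc = qpcr.relative_copies(cts, curves)
        rc["group"], rc["arm"] = group, arm
        rc["cohort"] = label
        truth = cts.groupby(["sheep", "zone", "gene"], sort=False)["true_mult"].first()
        rc["true_mult"] = truth.loc[
            pd.MultiIndex.from_frame(rc[["sheep", "zone", "gene"]])
        ].to_numpy()
        qpcr_frames.append(rc)

    return (
        pd.DataFrame(bio_rows),
        pd.DataFrame(dhi_rows),
        pd.concat(histo_frames, ignore_index=True),
        pd.concat(chem_frames, ignore_index=True),
        pd.concat(qpcr_frames, ignore_index=True),
    )


def _msc_vs_pbs(report: StudyReport, alpha: float) -> list[ComparisonResult]:
    comps: list[ComparisonResult] = []
    lesion_groups = [g for g in report.design.groups if g != "NOC"]

    def add(endpoint: str, table: pd.DataFrame, value: str, group: str, extra_mask=None):
        sub = table[table.group == group]
        if extra_mask is not None:
            sub = sub[extra_mask[sub.index]]
        x = sub.loc[sub.arm == "MSC", value].dropna()
        y = sub.loc[sub.arm == "PBS", value].dropna()
        if len(x) and len(y):
            comps.append(
                mann_whitney_u(
                    x, y, endpoint=f"{group}:{endpoint}", label_x="MSC", label_y="PBS"
                )
            )

    for g in lesion_groups:
        add("histo_cumulative", report.histo_results, "cumulative", g)
        add("percent_dhi", report.dhi_results, "percent_dhi", g)
        for mode in LOADING_MODES:
            m = report.biomech_results.loading_mode == mode
            add(f"rom:{mode}", report.biomech_results, "rom_deg", g, m)
            add(f"stiffness:{mode}", report.biomech_results, "final_stiffness", g, m)
            if mode != "axial_rotation":
                add(f"nz_width:{mode}", report.biomech_results, "nz_width_deg", g, m)
        for analyte in ("GAG", "hydroxyproline"):
            for zone in report.design.zones:
                m = (report.biochem_results.analyte == analyte) & (
                    report.biochem_results.zone == zone
                )
                add(f"{analyte}:{zone}", report.biochem_results, "ug_per_mg", g, m)
        for gene in plates.GENES:
            m = report.qpcr_results.gene == gene
            add(f"expr:{gene}", report.qpcr_results, "rel_copies_per_ug", g, m)
    return apply_bh(comps, alpha=alpha)


def _recovery_table(report: StudyReport) -> pd.DataFrame:
    rows = []
    b = report.biomech_results
    nz = b.dropna(subset=["nz_width_deg", "true_nz_width_deg"])
    rows.append(
        {
            "stage": "biomech_nz_width",
            "median_abs_error": float((nz.nz_width_deg - nz.true_nz_width_deg).abs().median()),
            "median_rel_error": float(
                ((nz.nz_width_deg - nz.true_nz_width_deg) / nz.true_nz_width_deg)
                .abs()
                .median()
            ),
        }
    )
    rows.append(
        {
            "stage": "biomech_stiffness",
            "median_abs_error": float((b.final_stiffness - b.true_final_stiffness).abs().median()),
            "median_rel_error": float(
                ((b.final_stiffness - b.true_final_stiffness) / b.true_final_stiffness)
                .abs()
                .median()
            ),
        }
    )
    d = report.dhi_results
    rows.append(
        {
            "stage": "percent_dhi",
            "median_abs_error": float((d.percent_dhi - d.true_percent_dhi).abs().median()),
            "median_rel_error": float(
                ((d.percent_dhi - d.true_percent_dhi) / d.true_percent_dhi).abs().median()
            ),
        }
    )
    c = report.biochem_results
    rows.append(
        {
            "stage": "biochem_ug_per_mg",
            "median_abs_error": float((c.ug_per_mg - c.true_ug_per_mg).abs().median()),
            "median_rel_error": float(
                ((c.ug_per_mg - c.true_ug_per_mg) / c.true_ug_per_mg).abs().median()
            ),
        }
    )
    return pd.DataFrame(rows)


def write_study(report: StudyReport, outdir) -> None:
    """Write the report as tidy CSV tables plus a JSON summary and run log."""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "biomech": report.biomech_results,
        "dhi": report.dhi_results,
        "histopathology": report.histo_results,
        "biochemistry": report.biochem_results,
        "qpcr": report.qpcr_results,
        "qpcr_folds": report.qpcr_folds,
        "comparisons": report.comparison_frame(),
        "recovery": report.recovery,
    }
    for name, df in tables.items():
        if df is not None:
            df.to_csv(out / f"{name}.csv", index=False)
    (out / "summary.json").write_text(json.dumps(report.summary(), indent=2))
    from . import __version__

    (out / "run_log.txt").write_text(
        f"ivdkit {__version__}\nseed: {report.seed}\n"
        f"cells: {report.design.cells()}\nn_sheep_per_cell: {report.design.n_sheep_per_cell}\n"
    )


def run_study(
    design: StudyDesign | None = None,
    seed: int = 0,
    alpha: float = 0.05,
    scheme: ScoringScheme | None = None,
) -> StudyReport:
    """Generate and analyse one complete synthetic study."""
    design = design or StudyDesign(seed=seed)
    scheme = scheme or ScoringScheme()
    bio, dhi, histo, chem, q = _generate_and_analyze(design, seed, scheme)
    folds = qpcr.fold_vs_noc(q, group_col="cohort", noc_label=_cell_label("NOC", "none"))
    report = StudyReport(
        design=design,
        seed=seed,
        biomech_results=bio,
        dhi_results=dhi,
        histo_results=histo,
        biochem_results=chem,
        qpcr_results=q,
        qpcr_folds=folds,
    )
    report.comparisons = _msc_vs_pbs(report, alpha)
    report.recovery = _recovery_table(report)
    return report
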
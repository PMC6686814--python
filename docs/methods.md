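# Methods

`ivdkit` reimplements the outcome-analysis layer of a large-animal
annular-lesion disc degeneration study as a tested pipeline, driven by a
synthetic-study generator whose every quantity has a closed-form ground
truth. This note records the models, the calibration, the numerical choices
and the limits of what the synthetic tests demonstrate.

## Study structure

The emulated experiment lesions ovine lumbar discs (6 × 20 mm annular
incision), lets degeneration develop (4 weeks for the early/late-acute
groups EA and LA, 12 weeks for the established group EST), injects either
mesenchymal stromal cells (MSC) or vehicle (PBS) intradiscally, and
harvests after a recovery period alongside nonoperated controls (NOC).
Each animal contributes L1L2 to histology, L3L4 to gene expression and
L5L6 to biomechanics; biochemistry and qPCR are performed on three
dissection zones (outer annulus AF1, inner annulus AF2, nucleus pulposus
NP). Default cohort size is 6 per (group, arm) cell.

## Torque-angle biomechanics

**Measurement model.** A functional spinal unit is rotated at 5 deg/s to a
torque limit of ±5 Nm for 10 cycles, sampled at 20 Hz; the final full cycle
is analysed. ROM is the angular deflection between the torque extremes.
Each loading direction's branch is fitted with a degree-7 least-squares
polynomial of torque on angle; the neutral zone (NZ) of a branch is the
maximal contiguous angular range, anchored at the branch's zero-torque
crossing, where the fitted gradient is strictly below 0.05 Nm/deg; the
final NZ is the intersection of the two branch ranges (empty or missing
ranges yield "no NZ" — the axial-rotation behaviour, which has no region of
low stiffness). Initial stiffness per branch is the fitted gradient at the
zero-torque crossing averaged over the maximal contiguous band where the
gradient deviates from the crossing value by less than 0.05 Nm/deg; final
stiffness is the arithmetic mean of the two branches.

Numerical choices: gradients are evaluated analytically from the fitted
polynomial on a fixed 0.01 deg grid (deterministic overlap computation);
ties at the threshold are excluded (strict `<`); when several sub-threshold
pockets exist the one containing, or failing that nearest to, the
zero-torque crossing is used; fits use `numpy.polynomial.Polynomial.fit`
(domain-mapped for conditioning). Whether the original procedure fitted
per direction or per loop is ambiguous; per-direction is used, since the
NZ definition references per-direction ranges.

**Synthetic loops.** The noiseless backbone has gradient
`g(θ) = k_nz + (k_el − k_nz)(θ/a)^6`, i.e. torque
`T(θ) = k_nz θ + (k_el − k_nz) θ^7 / (7 a^6)` — a smooth dual-stiffness
lazy-S with a flat lax region around neutral and progressive stiffening to
the torque limit. The scale `a` is set from `nz_half_width` so the analytic
NZ is exactly `±nz_half_width` for NZ-capable modes. This family was chosen
deliberately to lie **inside the span of the degree-7 fitting model**: with
zero noise the fit reproduces the backbone exactly, every estimand (NZ
width, ROM, stiffness) has a closed form, and estimator error under noise
is attributable to noise and sampling alone. A saturating (e.g. tanh-type)
transition was rejected because no degree-7 polynomial can track its
gradient plateau to the 0.1 deg agreement demanded of the NZ oracle; real
loops are of course not polynomial, so agreement of estimator and oracle
here validates the *procedure*, not its model error on real specimens.
Branches carry ±`hysteresis_offset` (constant torque offset by loading
direction) and i.i.d. Gaussian torque noise (`noise_sd`, default 0.05 Nm).

**Ground-truth stiffness.** The banded average that defines initial
stiffness has an irreducible positive bias relative to the plateau gradient
`k_nz` (≈ δ/7 with δ = 0.05 Nm/deg for this backbone family), so the
generator reports the analytic value of the *estimand* (the exact banded
average of the backbone gradient) as ground truth, alongside `k_nz`.
Recovery is measured against the estimand; for constant-gradient loops the
two coincide.

**Preset magnitudes.** Flexion-extension/lateral-bending presets use
plateau gradients 0.014–0.02 Nm/deg, transition-edge stiffness
0.55–0.8 Nm/deg, NZ widths 5.6–8.4 deg and ROM 12–17 deg — a lax lumbar
segment tested to ±5 Nm with posterior elements removed; established-lesion
discs are laxer than controls and MSC-treated discs sit between. Axial
rotation uses plateau gradients 1.2–1.6 Nm/deg (no sub-threshold region,
hence no NZ). Stiffness precision is information-limited by plateau length:
with 0.05 Nm noise at 20 Hz, even an ideal local slope estimator on a
4.4 deg plateau has ~30% relative error, falling below 10% only for
plateaus ≳ 6 deg; the recovery property is therefore stated at the
canonical long-plateau loop (`DEFAULT_LOOP`).

## Disc height index

Disc height is the mean of the anterior/middle/posterior disc-space
distances, each measured as the projection of the landmark-pair difference
onto the local spine axis (the line through the two vertebral-body
centroids); DHI normalises it to the mean of the adjacent vertebral-body
heights, and %DHI is the endpoint DHI as a percentage of the pre-surgery
DHI. This construction is exactly invariant under similarity transforms
(radiographic magnification, rotation, translation), which the generator
exercises by pushing every landmark set through a random similarity
transform (scale 0.85–1.25, rotation ±8 deg). Endpoint disc spaces are
scaled by a truncated-normal draw of the height ratio; vertebral bodies are
unchanged. The pre-surgery film is taken as the "pre-lesion" denominator.
Preset ratios: NOC 1.00 ± 0.015, degenerate baseline 0.88 ± 0.03,
PBS endpoint 0.80 ± 0.04 (15–25% loss), MSC endpoint 0.935 ± 0.02 (92–95%
re-attainment).

## Histopathology scoring

Six ordinal criteria — GAG staining, lesion structure, cell morphology,
vessel ingrowth, cell infiltration, special degenerative/repair features —
are summed into a cumulative score. Criterion ranges are config-driven
(default 0–5 each, scheme maximum 30, consistent with observed cumulative
means up to 22). Two blinded observers are reconciled by the per-criterion
mean rounded half-up; no reconciliation rule was published, so rounded mean
was chosen as the simplest order-preserving, idempotent rule.

**Generator and calibration.** Observer 1 draws each criterion from a
discretised, range-clipped normal; observer 2 adds ±1 ordinal jitter with
probability `jitter_p` per side. Every step of the chain is discrete, so
the exact mean and variance of the consensus cumulative score have closed
forms; presets solve (by monotone fixed-point iteration over a common mean
shift and a common criterion SD) for distributions whose exact consensus
expectation and SD equal the cohort targets: degenerate baseline 22 ± 2.2,
PBS endpoint 19 ± 2.5, MSC endpoint 4 ± 0.4, NOC 3 ± 0.8 (the NOC figures
are a design choice: "near-control" MSC outcomes sit just above them). The
*allocation* of each total across criteria a–f (e.g. 4+4+3+3+3+2 for the
PBS endpoint) is an implementer choice documented in the preset module, not
study data. `jitter_p = min(0.15, σ²)` ties inter-observer noise to cohort
dispersion, since near-deterministic cohort summaries imply near-perfect
agreement; no published agreement statistic constrains it.

## Biochemistry and qPCR

Both chromogenic assays (DMMB for sulfated GAG with a chondroitin-sulfate
standard series; the dimethylaminobenzaldehyde hydroxyproline reaction) are
modelled in their linear range: OLS calibration of signal on amount,
triplicate sample signals averaged before inversion, amounts scaled by the
digest/aliquot dilution factor and divided by wet weight (per-wet-weight
reporting is an assumption; the basis is configurable). Out-of-range
signals are flagged but quantified; negative back-calculated amounts clamp
to zero with a flag. Zonal preset contents (µg/mg wet): GAG NOC
18/28/45 (AF1/AF2/NP) depleted to 13/20/25 in lesion discs and restored to
17/27/42 by treatment; hydroxyproline 20/15/8 rising modestly with the
fibrotic lesion response.

qPCR standard curves are log-linear (Ct = intercept + slope·log10 copies,
slope −3.32 at 100% efficiency, efficiency validated in (0, 1.2]), anchored
to the top pooled-cDNA standard (relative copies = 1). Triplicates are
averaged as Ct; replicate ranges > 1 Ct are flagged. Normalisation is by
total RNA loaded — deliberately not by housekeeping genes, whose expression
shifts with disease. Cohort effects are fold changes of geometric means
over NOC. Preset multipliers give lesion discs elevated proteases (MMP2/3/
9/13 ×2.5–6, ADAMTS4/5 ×2.5–4) and depressed matrix genes (ACAN, COL2A1
×0.5), normalising to ×1.1–1.3 under treatment.

## Statistics

Group comparisons are two-sided Mann-Whitney U tests with midrank ties.
For n₁·n₂ ≤ 64 the p value is exact: the full permutation distribution of
U is enumerated over all C(n₁+n₂, n₁) allocations and the smaller
one-sided tail is doubled (capped at 1) — under ties the distribution is
asymmetric, so both tails are enumerated explicitly. Larger samples use
the tie-corrected normal approximation with continuity correction.
Families of tests are corrected by Benjamini-Hochberg step-up, study-wide
by default; the "corrected threshold" (largest rejected raw p) is reported
as a data-dependent output of each analysis. The mixed ordinal regression
screen of the original analysis is out of scope; the Mann-Whitney layer is
the implemented comparator.

## What the synthetic tests do and do not show

The generator reproduces the *statistical shape* the analyses assume —
cohort means and dispersions calibrated to published summaries, triplicate
assay structure, two-observer scoring, per-modality noise — under a single
study seed with named substreams (regenerating one table never perturbs
another; identical seeds are bit-identical). It does not emulate real
torque-angle model error (backbones are exactly degree-7), radiographic
landmarking error beyond similarity transforms, non-linear assay response,
qPCR inhibition or melt-curve failures, or inter-animal correlation across
endpoints (draws are independent across stages given the preset). Passing
tests therefore validate the estimators and their implementations under
the stated noise models, not the biology of any particular specimen.

## Problem sizes

Default analyses run at the study's own scale: 6 sheep per cell (42
total), 3 loading modes × ~1,200-sample records, 18 discs per cohort for
radiogrammetry, triplicate assays over 3 zones and 12 genes. Recovery
properties use 50 seeded replicates; the null calibration of the exact
test uses 2,000 replicates at n = 6 vs 6.
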
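"""Torque-angle analysis: cycle extraction, ROM, fits, NZ, stiffness."""

import numpy as np
import pytest
from numpy.polynomial import Polynomial

from ivdkit import biomech
from ivdkit.synth.loops import HysteresisParams, LoadingRecord, simulate_loop


def linear_record(slope=1.0, limit=5.0, n_cycles=1, noise=0.0, seed=0):
    p = HysteresisParams(
        k_nz=slope, k_el=slope, nz_half_width=0.0, torque_limit=limit,
        n_cycles=n_cycles, noise_sd=noise,
    )
    return simulate_loop(p, seed=seed)


class TestFinalCycle:
    def test_ten_cycle_record_returns_cycle_ten(self):
        rec = simulate_loop(
            HysteresisParams(k_nz=0.02, k_el=0.8, nz_half_width=2.0), seed=0
        )
        cyc = biomech.extract_final_cycle(rec)
        assert np.all(cyc.cycle == 10)
        # sample count equals the generator's per-cycle count
        assert cyc.time_s.size == np.sum(rec.cycle == 10)

    def test_single_cycle_identity(self):
        rec = linear_record(n_cycles=1)
        cyc = biomech.extract_final_cycle(rec)
        np.testing.assert_array_equal(cyc.angle_deg, rec.angle_deg)

    def test_incomplete_record_rejected(self):
        rec = linear_record(n_cycles=1)
        half = rec.direction == 1  # only the loading branch: never complete
        broken = LoadingRecord(
            specimen="S", loading_mode="flexion_extension",
            time_s=rec.time_s[half], angle_deg=rec.angle_deg[half],
            torque_nm=rec.torque_nm[half], cycle=rec.cycle[half],
            direction=rec.direction[half],
        )
        with pytest.raises(ValueError, match="incomplete"):
            biomech.extract_final_cycle(broken)


class TestRom:
    def test_linear_loop_rom_is_limit_over_slope(self):
        cyc = biomech.extract_final_cycle(linear_record(slope=1.0, limit=5.0))
        assert biomech.compute_rom(cyc) == pytest.approx(10.0, abs=0.3)

    def test_rom_matches_analytic_span_within_one_sample(self):
        rec = simulate_loop(
            HysteresisParams(k_nz=0.02, k_el=0.8, nz_half_width=2.0, hysteresis_offset=0.05),
            seed=0,
        )
        cyc = biomech.extract_final_cycle(rec)
        assert biomech.compute_rom(cyc) == pytest.approx(rec.ground_truth.rom_deg, abs=0.25)

    def test_monotone_torque_rejected(self):
        rec = linear_record()
        shifted = LoadingRecord(
            specimen="S", loading_mode="flexion_extension",
            time_s=rec.time_s, angle_deg=rec.angle_deg,
            torque_nm=rec.torque_nm + 100.0,  # all positive
            cycle=rec.cycle, direction=rec.direction,
        )
        with pytest.raises(ValueError, match="sign"):
            biomech.compute_rom(shifted)


class TestDirectionFit:
    def test_degree7_data_interpolated_exactly(self):
        rec = simulate_loop(
            HysteresisParams(k_nz=0.02, k_el=0.8, nz_half_width=2.0), seed=0
        )
        cyc = biomech.extract_final_cycle(rec)
        fit = biomech.fit_direction(cyc, +1)
        assert fit.residual_rms < 1e-9  # backbone is itself degree 7

    def test_linear_data_recovers_slope(self):
        cyc = biomech.extract_final_cycle(linear_record(slope=2.0, limit=5.0))
        fit = biomech.fit_direction(cyc, +1)
        grid = np.linspace(*fit.domain, 50)
        np.testing.assert_allclose(fit.gradient(grid), 2.0, atol=1e-8)

    def test_noisy_rms_bounded_by_noise(self):
        errs = []
        for seed in range(10):
            rec = simulate_loop(
                HysteresisParams(k_nz=0.02, k_el=0.8, nz_half_width=2.0, noise_sd=0.05),
                seed=seed,
            )
            cyc = biomech.extract_final_cycle(rec)
            errs.append(biomech.fit_direction(cyc, +1).residual_rms)
        assert max(errs) <= 2 * 0.05

    def test_too_few_samples_rejected(self):
        rec = linear_record()
        m = rec.direction == 1
        tiny = LoadingRecord(
            specimen="S", loading_mode="flexion_extension",
            time_s=rec.time_s[m][:5], angle_deg=rec.angle_deg[m][:5],
            torque_nm=rec.torque_nm[m][:5], cycle=rec.cycle[m][:5],
            direction=rec.direction[m][:5],
        )
        with pytest.raises(ValueError):
            biomech.fit_direction(tiny, +1)

    def test_evaluation_outside_domain_rejected(self):
        cyc = biomech.extract_final_cycle(linear_record())
        fit = biomech.fit_direction(cyc, +1)
        with pytest.raises(ValueError, match="domain"):
            fit(fit.domain[1] + 1.0)


def _fit_from_poly(poly: Polynomial, lo: float, hi: float, direction=1) -> biomech.DirectionFit:
    return biomech.DirectionFit(poly=poly, domain=(lo, hi), residual_rms=0.0, direction=direction)


def _plateau_poly(center: float, half_width: float, k_nz=0.01, k_el=1.0):
    """Odd degree-7 torque curve whose gradient is < 0.05 exactly on
    (center - hw, center + hw): gradient = k_nz + dk*((x-c)/a)^6."""
    a = half_width * ((k_el - k_nz) / (0.05 - k_nz)) ** (1 / 6)
    x = Polynomial([0, 1])
    return k_nz * (x - center) + (k_el - k_nz) * (x - center) ** 7 / (7 * a**6)


class TestNeutralZone:
    def test_stiff_linear_directions_have_no_nz(self):
        pos = _fit_from_poly(Polynomial([0.0, 0.2]), -10, 10)
        neg = _fit_from_poly(Polynomial([0.0, 0.2]), -10, 10, -1)
        assert biomech.neutral_zone(pos, neg) is None

    def test_symmetric_plateau_width(self):
        pos = _fit_from_poly(_plateau_poly(0.0, 3.0), -10, 10)
        neg = _fit_from_poly(_plateau_poly(0.0, 3.0), -10, 10, -1)
        lo, hi = biomech.neutral_zone(pos, neg)
        assert hi - lo == pytest.approx(6.0, abs=0.03)

    def test_overlap_is_interval_intersection(self):
        # plateaus (-3, 3) and (-1, 5) -> common overlapping range (-1, 3)
        pos = _fit_from_poly(_plateau_poly(0.0, 3.0), -10, 10)
        neg = _fit_from_poly(_plateau_poly(2.0, 3.0), -10, 10, -1)
        lo, hi = biomech.neutral_zone(pos, neg)
        assert lo == pytest.approx(-1.0, abs=0.03)
        assert hi == pytest.approx(3.0, abs=0.03)

    def test_disjoint_plateaus_yield_no_nz(self):
        pos = _fit_from_poly(_plateau_poly(-5.0, 2.0), -10, 10)
        neg = _fit_from_poly(_plateau_poly(5.0, 2.0), -10, 10, -1)
        assert biomech.neutral_zone(pos, neg) is None

    def test_disjoint_domains_rejected(self):
        pos = _fit_from_poly(Polynomial([0, 1]), -10, -5)
        neg = _fit_from_poly(Polynomial([0, 1]), 5, 10, -1)
        with pytest.raises(ValueError, match="disjoint"):
            biomech.neutral_zone(pos, neg)

    def test_raising_threshold_never_shrinks_nz(self):
        rec = simulate_loop(
            HysteresisParams(
                k_nz=0.015, k_el=0.7, nz_half_width=3.4, hysteresis_offset=0.02
            ),
            seed=0,
        )
        cyc = biomech.extract_final_cycle(rec)
        fp = biomech.fit_direction(cyc, +1)
        fn = biomech.fit_direction(cyc, -1)
        widths = []
        for thr in (0.02, 0.05, 0.1, 0.2):
            nz = biomech.neutral_zone(fp, fn, threshold=thr)
            widths.append(0.0 if nz is None else nz[1] - nz[0])
        assert widths == sorted(widths)


class TestStiffness:
    def test_constant_gradient_recovered_exactly(self):
        fit = _fit_from_poly(Polynomial([0.0, 1.7]), -5, 5)
        assert biomech.initial_stiffness(fit) == pytest.approx(1.7)

    def test_final_is_arithmetic_mean(self):
        assert biomech.final_stiffness(1.0, 3.0) == 2.0

    def test_no_zero_crossing_rejected(self):
        fit = _fit_from_poly(Polynomial([10.0, 0.1]), -5, 5)
        with pytest.raises(ValueError, match="neutral position"):
            biomech.initial_stiffness(fit)

    def test_noiseless_loop_matches_analytic_estimand(self, noiseless_loop):
        res = biomech.analyze(noiseless_loop)
        gt = noiseless_loop.ground_truth
        assert res.initial_stiffness_pos == pytest.approx(gt.initial_stiffness_pos, rel=0.01)
        assert res.initial_stiffness_neg == pytest.approx(gt.initial_stiffness_neg, rel=0.01)
        assert res.final_stiffness == pytest.approx(gt.final_stiffness, rel=0.01)
        # conservation: final is exactly the mean of the two directions
        assert res.final_stiffness == pytest.approx(
            0.5 * (res.initial_stiffness_pos + res.initial_stiffness_neg), abs=1e-12
        )

    def test_stiff_mode_recovers_plateau_stiffness(self):
        p = HysteresisParams(
            k_nz=1.6, k_el=2.2, nz_half_width=2.0, hysteresis_offset=0.3
        )
        res = biomech.analyze(simulate_loop(p, seed=0))
        assert res.nz_range is None
        # band bias is delta/7 ~ 0.007, negligible against k_nz = 1.6
        assert res.final_stiffness == pytest.approx(1.6, rel=0.02)


class TestAnalyze:
    def test_noiseless_nz_matches_ground_truth(self, noiseless_loop):
        res = biomech.analyze(noiseless_loop)
        gt = noiseless_loop.ground_truth
        assert res.nz_width_deg == pytest.approx(gt.nz_width_deg, abs=0.05)
        assert res.rom_deg == pytest.approx(gt.rom_deg, abs=0.25)
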
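"""Cumulative histopathology scoring and its synthetic score sheets."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivdkit.histopath import (
    CRITERIA,
    HistoProfile,
    ScoringScheme,
    cohort_scores,
    consensus_cumulative_scores,
    cumulative_score,
    reconcile_observers,
)
from ivdkit.synth.design import StudyDesign
from ivdkit.synth.histo import (
    consensus_moments,
    criterion_pmf,
    cumulative_moments,
    generate_histo_profiles,
)
from ivdkit.synth.presets import get_preset


def profile(scores, disc="d1", obs="obs1"):
    return HistoProfile(disc, obs, dict(zip(CRITERIA, scores)))


class TestCumulativeScore:
    def test_bounds_and_sum(self, scheme):
        assert cumulative_score(profile([0] * 6), scheme) == 0
        assert cumulative_score(profile([5] * 6), scheme) == scheme.scheme_max == 30
        assert cumulative_score(profile([4, 5, 3, 4, 3, 3]), scheme) == 22

    def test_out_of_range_rejected(self, scheme):
        with pytest.raises(ValueError, match="outside"):
            cumulative_score(profile([6, 0, 0, 0, 0, 0]), scheme)

    def test_missing_criterion_rejected(self, scheme):
        p = HistoProfile("d1", "obs1", {"a_gag_staining": 1})
        with pytest.raises(ValueError, match="missing"):
            cumulative_score(p, scheme)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 5), min_size=6, max_size=6), st.integers(0, 5))
    def test_monotone_in_every_criterion(self, scores, i):
        scheme = ScoringScheme()
        base = cumulative_score(profile(scores), scheme)
        bumped = list(scores)
        idx = i % 6
        if bumped[idx] < 5:
            bumped[idx] += 1
            assert cumulative_score(profile(bumped), scheme) == base + 1


class TestReconcile:
    def test_identical_observers(self):
        a = profile([1, 2, 3, 4, 5, 0])
        b = profile([1, 2, 3, 4, 5, 0], obs="obs2")
        consensus, dis = reconcile_observers([a, b])
        assert consensus.scores == a.scores
        assert all(v == 0 for v in dis.values())

    def test_half_up_rounding_and_disagreement(self):
        a = profile([2, 0, 0, 0, 0, 0])
        b = profile([3, 0, 0, 0, 0, 0], obs="obs2")
        consensus, dis = reconcile_observers([a, b])
        assert consensus.scores["a_gag_staining"] == 3  # 2.5 rounds up
        assert dis["a_gag_staining"] == 1

    def test_permutation_invariant_and_idempotent(self):
        a = profile([2, 1, 4, 0, 3, 5])
        b = profile([3, 1, 3, 1, 3, 5], obs="obs2")
        c1, _ = reconcile_observers([a, b])
        c2, _ = reconcile_observers([b, a])
        assert c1.scores == c2.scores
        again, _ = reconcile_observers([c1])
        assert again.scores == c1.scores

    def test_conflicting_disc_ids_rejected(self):
        with pytest.raises(ValueError, match="disc"):
            reconcile_observers([profile([0] * 6, disc="d1"), profile([0] * 6, disc="d2")])


class TestCohortScores:
    def test_constant_cohort(self):
        s = cohort_scores([4, 4, 4, 4, 4, 4])
        assert (s["mean"], s["sd"], s["q25"], s["q75"]) == (4, 0, 4, 4)

    def test_one_to_six(self):
        s = cohort_scores([1, 2, 3, 4, 5, 6])
        assert s["median"] == 3.5
        assert s["q25"] == pytest.approx(2.25)  # linear-interpolation quantiles
        assert s["q75"] == pytest.approx(4.75)

    def test_single_disc_rejected(self):
        with pytest.raises(ValueError):
            cohort_scores([4])


class TestGenerator:
    def test_zero_dispersion_integer_means_is_exact(self, scheme, small_design):
        preset = dataclasses.replace(
            get_preset("PBS-endpoint"),
            histo_criterion_means=(4, 4, 3, 3, 3, 2),
            histo_criterion_sd=0.0,
            observer_jitter_p=0.0,
        )
        df = generate_histo_profiles(preset, small_design, seed=1, scheme=scheme)
        cum = consensus_cumulative_scores(df, scheme)
        assert (cum["cumulative"] == 19).all()
        # both observers identical
        wide = df.pivot_table(
            index=["disc_id", "criterion"], columns="observer", values="score"
        )
        assert (wide["obs1"] == wide["obs2"]).all()

    def test_observer_jitter_bounded_by_one(self, scheme, small_design):
        df = generate_histo_profiles(
            get_preset("degenerate-baseline"), small_design, seed=2, scheme=scheme
        )
        wide = df.pivot_table(
            index=["disc_id", "criterion"], columns="observer", values="score"
        )
        assert (wide["obs1"] - wide["obs2"]).abs().max() <= 1

    def test_mean_outside_range_rejected(self, scheme, small_design):
        preset = dataclasses.replace(
            get_preset("NOC"), histo_criterion_means=(9, 0, 0, 0, 0, 0)
        )
        with pytest.raises(ValueError, match="outside"):
            generate_histo_profiles(preset, small_design, seed=0, scheme=scheme)

    def test_cohort_mean_within_two_se(self, scheme):
        # average of 10 seeded cohorts against the calibrated expectation
        preset = get_preset("PBS-endpoint")
        design = StudyDesign(n_sheep_per_cell=6)
        means = []
        for seed in range(10):
            df = generate_histo_profiles(preset, design, seed=seed, scheme=scheme)
            means.append(consensus_cumulative_scores(df, scheme)["cumulative"].mean())
        mean, sd = preset.histo_target
        assert np.mean(means) == pytest.approx(mean, abs=2 * sd / np.sqrt(6 * 10))


class TestExactMoments:
    """The closed-form consensus moments against Monte-Carlo simulation."""

    @pytest.mark.parametrize("mu,sigma,jp", [(3.2, 0.9, 0.15), (0.7, 0.2, 0.04)])
    def test_moments_match_simulation(self, mu, sigma, jp):
        rng = np.random.default_rng(0)
        n = 200_000
        x = np.clip(np.floor(rng.normal(mu, sigma, n) + 0.5), 0, 5).astype(int)
        j = rng.choice([-1, 0, 1], p=[jp, 1 - 2 * jp, jp], size=n)
        y = np.clip(x + j, 0, 5)
        consensus = np.floor((x + y) / 2 + 0.5).astype(int)
        e, v = consensus_moments(mu, sigma, 5, jp)
        assert consensus.mean() == pytest.approx(e, abs=4 * consensus.std() / np.sqrt(n))
        assert consensus.var() == pytest.approx(v, rel=0.02)

    def test_pmf_sums_to_one(self):
        for mu, sigma in [(0.0, 0.5), (2.5, 1.2), (5.0, 0.1), (1.0, 0.0)]:
            assert criterion_pmf(mu, sigma, 5).sum() == pytest.approx(1.0)

    def test_presets_are_calibrated_to_their_targets(self, scheme):
        for name in ("NOC", "degenerate-baseline", "PBS-endpoint", "MSC-endpoint"):
            p = get_preset(name)
            mean, sd = cumulative_moments(
                np.asarray(p.histo_criterion_means),
                p.histo_criterion_sd,
                scheme,
                p.observer_jitter_p,
            )
            assert mean == pytest.approx(p.histo_target[0], abs=1e-3)
            assert sd == pytest.approx(p.histo_target[1], abs=1e-3)
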
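"""Entropy-based information, the p-model, and the global ML fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bubblegaze import info
from bubblegaze.stimulus import Stimulus, StimulusDesign, build_stimulus_set
from bubblegaze.synth import (
    ExperimentDesign,
    generate_responses_only,
    make_bubble_pool,
    sample_ground_truth,
)

from conftest import make_bubble


def dists(n=2, c=2, seed=0):
    return np.random.default_rng(seed).dirichlet(np.ones(c), size=n)


class TestStimulusInformation:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.25, 0.25, 0.25, 0.25], 0.0),
            ([1.0, 0.0, 0.0, 0.0], 2.0),
            ([0.5, 0.5], 0.0),
            ([1.0, 0.0], 1.0),
            # direct entropy computation: 1 - H(0.75) = 0.18872...
            ([0.75, 0.25], 1.0 + 0.75 * np.log2(0.75) + 0.25 * np.log2(0.25)),
        ],
    )
    def test_examples(self, p, expected):
        assert info.stimulus_information(np.array(p)) == pytest.approx(expected)

    def test_expression_range_is_2_bit(self):
        assert info.stimulus_information(np.eye(4)[0]) == 2.0

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            info.stimulus_information(np.array([]))
        with pytest.raises(ValueError):
            info.stimulus_information(np.array([0.5, 0.4]))


class TestPModel:
    def test_flat_is_identity(self):
        d = np.array([0.7, 0.2, 0.1])
        out = info.integrate_pmodel([d, np.full(3, 1 / 3)])
        np.testing.assert_allclose(out, d)

    def test_hand_evaluated_product(self):
        # (0.8,0.2) x (0.8,0.2) -> (0.64, 0.04)/0.68
        out = info.integrate_pmodel([[0.8, 0.2], [0.8, 0.2]])
        np.testing.assert_allclose(out, [0.64 / 0.68, 0.04 / 0.68])

    def test_opposite_evidence_cancels(self):
        out = info.integrate_pmodel([[0.9, 0.1], [0.1, 0.9]])
        np.testing.assert_allclose(out, [0.5, 0.5])

    def test_zero_component_absorbing(self):
        out = info.integrate_pmodel([[0.0, 1.0], [0.5, 0.5]])
        np.testing.assert_allclose(out, [0.0, 1.0])

    def test_contradictory_deltas_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            info.integrate_pmodel([[1.0, 0.0], [0.0, 1.0]])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_commutative_and_associative(self, seed):
        a, b, c = dists(3, 3, seed)
        ab = info.integrate_pmodel([a, b])
        np.testing.assert_allclose(ab, info.integrate_pmodel([b, a]))
        np.testing.assert_allclose(
            info.integrate_pmodel([info.integrate_pmodel([a, b]), c]),
            info.integrate_pmodel([a, info.integrate_pmodel([b, c])]),
            atol=1e-12,
        )

    def test_self_integration_information_increases_to_max(self):
        d = np.array([0.8, 0.2])
        cur = d.copy()
        infos = [info.stimulus_information(cur)]
        for _ in range(20):
            cur = info.integrate_pmodel([cur, d])
            infos.append(info.stimulus_information(cur))
        assert np.all(np.diff(infos) > 0)
        assert infos[-1] == pytest.approx(1.0, abs=1e-3)


class TestMaxModel:
    def test_picks_most_informative(self):
        flat = np.array([0.5, 0.5])
        sharp = np.array([0.9, 0.1])
        np.testing.assert_allclose(info.integrate_maxmodel([flat, sharp]), sharp)

    def test_all_flat_returns_flat(self):
        flat = np.array([0.5, 0.5])
        np.testing.assert_allclose(info.integrate_maxmodel([flat, flat]), flat)

    def test_tie_broken_by_first_index(self):
        a, b = np.array([0.8, 0.2]), np.array([0.2, 0.8])
        np.testing.assert_allclose(info.integrate_maxmodel([a, b]), a)


class TestGlobalFit:
    def test_single_bubble_mle_equals_proportions(self):
        b = make_bubble("b0", 10.0, 10.0)
        s = Stimulus("s0", "gender", (b,), "same")
        resp = pd.DataFrame(
            {
                "stimulus_id": ["s0"] * 1000,
                "response": ["male"] * 750 + ["female"] * 250,
            }
        )
        fit = info.fit_bubble_distributions(resp, [s], ("male", "female"))
        np.testing.assert_allclose(fit.dist_of("b0"), [0.75, 0.25], atol=1e-4)
        assert fit.information[0] == pytest.approx(0.18872, abs=1e-3)

    def test_parameter_and_equation_counts(self):
        assert info.count_free_parameters(94, 4) == 282
        assert info.count_free_parameters(94, 2) == 94
        with pytest.raises(ValueError):
            info.count_free_parameters(10, 1)

    def test_consistency_tv_shrinks_with_more_trials(self):
        # with data generated under the p-model, estimates approach truth
        # as the trial count grows (TV roughly halves per 4x trials)
        rng = np.random.default_rng(11)
        pool = make_bubble_pool(20, "gender", seed=rng)
        truth = sample_ground_truth(
            20, 2, seed=rng, bubble_ids=[b.bubble_id for b in pool]
        )
        stimuli = build_stimulus_set(StimulusDesign(100), pool, seed=rng)
        tvs = []
        for n_pp in (40, 160):
            design = ExperimentDesign(n_participants=25, trials_per_participant=n_pp)
            resp = generate_responses_only(design, stimuli, truth, seed=5)
            fit = info.fit_bubble_distributions(
                resp, stimuli, ("male", "female"), seed=0
            )
            order = [truth.bubble_ids.index(b) for b in fit.bubble_ids]
            tv = 0.5 * np.abs(
                fit.distributions - truth.response_dists[order]
            ).sum(axis=1).mean()
            tvs.append(tv)
        assert tvs[1] < 0.7 * tvs[0]


class TestInfoVsCount:
    def test_single_draw_equals_pool_mean(self):
        pool = dists(10, 2, seed=1)
        pred = info.predict_info_vs_count(pool, [1], reps=400, seed=0)
        expect = np.mean([info.stimulus_information(p) for p in pool])
        assert pred["mean_information"].iloc[0] == pytest.approx(expect, abs=0.03)

    def test_identical_pool_matches_closed_form(self):
        pool = np.array([[0.8, 0.2]])
        pred = info.predict_info_vs_count(pool, [2], reps=5, seed=0)
        expect = info.stimulus_information(np.array([0.64 / 0.68, 0.04 / 0.68]))
        assert pred["mean_information"].iloc[0] == pytest.approx(expect)

    def test_nondecreasing_in_count_for_informative_pool(self):
        pool = np.array([[0.8, 0.2]])
        pred = info.predict_info_vs_count(pool, range(1, 6), reps=3, seed=0)
        assert pred["mean_information"].is_monotonic_increasing


class TestPredictionError:
    def test_zero_when_observed_equals_prediction(self):
        b = make_bubble("b0", 10.0, 10.0)
        s = Stimulus("s0", "gender", (b,), "same")
        resp = pd.DataFrame(
            {"stimulus_id": ["s0"] * 4, "response": ["male", "male", "female", "female"]}
        )
        fit = info.fit_bubble_distributions(resp, [s], ("male", "female"))
        err, bound = info.info_prediction_error(fit, resp, [s], reps=50, seed=0)
        assert err == pytest.approx(0.0, abs=1e-3)
        assert bound > 0.0  # finite-sample entropy fluctuation at n=4

    def test_bound_below_realized_error_in_expectation(self, small_world):
        resp = pd.DataFrame(
            {
                "stimulus_id": [t.stimulus_id for t in small_world.trials],
                "response": [t.response for t in small_world.trials],
            }
        )
        stimuli = [s for s in small_world.stimuli if not s.is_fullfield]
        fit = info.fit_bubble_distributions(resp, stimuli, ("male", "female"), seed=0)
        err, bound = info.info_prediction_error(fit, resp, stimuli, reps=30, seed=1)
        # data were generated under the p-model, so the realized error is
        # essentially all sampling noise: bound ~ err, never far above
        assert bound <= err * 1.5
        assert err < 0.2


class TestBootstrap:
    def test_zero_variance_degenerate_interval(self):
        lo, hi = info.bootstrap_ci(np.full(10, 0.3), reps=200, seed=0)
        assert lo == hi == pytest.approx(0.3)

    def test_identical_seeds_identical_intervals(self):
        x = np.random.default_rng(0).random(50)
        assert info.bootstrap_ci(x, seed=5) == info.bootstrap_ci(x, seed=5)

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            info.bootstrap_ci(np.array([1.0]))

    def test_curve_difference_rule(self):
        assert info.curves_differ(0.9, (0.1, 0.5))
        assert not info.curves_differ(0.3, (0.1, 0.5))


class TestPermutationPositionTest:
    def test_identical_sets_inside_region(self):
        a = np.array([5, 5])
        assert info.permutation_position_test([(a, a)], reps=300, seed=0) == 1.0

    def test_planted_position_effect_detected(self):
        rng = np.random.default_rng(2)
        pairs = []
        for _ in range(60):
            a = rng.multinomial(40, [0.9, 0.1])
            b = rng.multinomial(40, [0.3, 0.7])
            pairs.append((a, b))
        frac = info.permutation_position_test(pairs, reps=400, seed=0)
        assert frac < 0.5

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            info.permutation_position_test(
                [(np.array([1, 0]), np.array([0, 0]))], reps=10
            )
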
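"""Tests for Manly selectivity indices and preference summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bioticres.preference import (
    PreferenceSummary,
    ZeroConsumptionError,
    manly_alpha,
    null_expectation,
    preference_bootstrap_test,
    summarize_preferences,
    transform_alpha,
)
from bioticres.simulate import simulate_switch_trial


def switch_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "predator",
            "prop_invader",
            "n_invader_0",
            "n_native_0",
            "eaten_invader",
            "eaten_native",
            "is_control",
            "replicate_id",
        ],
    )


class TestManlyAlpha:
    def test_symmetric_kills_are_neutral(self):
        assert manly_alpha(10, 5, 10, 5) == pytest.approx(0.5)

    def test_only_invader_eaten_is_complete_preference(self):
        assert manly_alpha(10, 3, 10, 0) == pytest.approx(1.0)

    def test_rare_native_case_direct_evaluation(self):
        # ln(12/18) / (ln(12/18) + ln(1/2))
        expected = math.log(12 / 18) / (math.log(12 / 18) + math.log(1 / 2))
        assert manly_alpha(18, 6, 2, 1) == pytest.approx(expected)
        assert round(manly_alpha(18, 6, 2, 1), 3) == 0.369

    def test_complete_depletion_limits(self):
        assert manly_alpha(5, 5, 15, 3) == 1.0  # invader wiped out
        assert manly_alpha(15, 3, 5, 5) == 0.0  # native wiped out
        both = manly_alpha(10, 10, 10, 10)  # continuity correction
        assert both == pytest.approx(0.5)

    def test_zero_consumption_is_undefined(self):
        with pytest.raises(ZeroConsumptionError):
            manly_alpha(10, 0, 10, 0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            manly_alpha(10, 11, 10, 0)
        with pytest.raises(ValueError):
            manly_alpha(0, 0, 10, 2)

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(
        n_i0=st.integers(1, 20),
        n_n0=st.integers(1, 20),
        data=st.data(),
    )
    def test_two_prey_closure(self, n_i0, n_n0, data):
        r_i = data.draw(st.integers(0, n_i0))
        r_n = data.draw(st.integers(0, n_n0))
        if r_i + r_n == 0:
            return
        a_i = manly_alpha(n_i0, r_i, n_n0, r_n)
        a_n = manly_alpha(n_n0, r_n, n_i0, r_i)  # labels swapped
        assert 0.0 <= a_i <= 1.0
        assert a_i + a_n == pytest.approx(1.0, abs=1e-12)


class TestTransform:
    @pytest.mark.parametrize(
        "alpha, n, expected",
        [(1.0, 3, 5 / 6), (0.5, 7, 0.5), (0.0, 15, 0.5 / 15)],
    )
    def test_known_values(self, alpha, n, expected):
        assert transform_alpha(alpha, n) == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        a1=st.floats(0.0, 1.0),
        a2=st.floats(0.0, 1.0),
        n=st.integers(2, 50),
    )
    def test_maps_inside_unit_interval_and_preserves_order(self, a1, a2, n):
        t1, t2 = transform_alpha(a1, n), transform_alpha(a2, n)
        assert 0.0 < t1 < 1.0
        if a1 < a2:
            assert t1 < t2
        # n = 1 collapses every index to the neutral point
        assert transform_alpha(a1, 1) == 0.5

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            transform_alpha(1.2, 5)
        with pytest.raises(ValueError):
            transform_alpha(0.5, 0)


class TestNullExpectation:
    @pytest.mark.parametrize("p", [0.0, 0.75, 1.0])
    def test_identity_on_unit_interval(self, p):
        assert null_expectation(p) == p

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            null_expectation(1.5)


class TestSummaries:
    def test_single_neutral_trial(self):
        df = switch_frame([("P", 0.5, 10, 10, 5, 5, 0, 1)])
        summ = summarize_preferences(df)["P"]
        assert summ.table["mean_alpha"].iloc[0] == pytest.approx(0.5)
        assert summ.table["se_alpha"].iloc[0] == 0.0
        assert summ.overall_mean_alpha == pytest.approx(0.5)

    def test_overall_mean_is_unweighted_over_proportions(self):
        df = switch_frame(
            [
                ("P", 0.25, 5, 15, 5, 0, 0, 1),  # alpha 1.0
                ("P", 0.25, 5, 15, 5, 0, 0, 2),
                ("P", 0.50, 10, 10, 5, 5, 0, 1),  # alpha 0.5
            ]
        )
        summ = summarize_preferences(df)["P"]
        assert summ.overall_mean_alpha == pytest.approx((1.0 + 0.5) / 2)

    def test_zero_consumption_trials_excluded_and_counted(self):
        df = switch_frame(
            [
                ("P", 0.5, 10, 10, 5, 5, 0, 1),
                ("P", 0.5, 10, 10, 0, 0, 0, 2),
            ]
        )
        summ = summarize_preferences(df)["P"]
        assert summ.n_excluded == 1
        assert summ.table["n_trials"].iloc[0] == 1

    def test_controls_ignored(self):
        df = switch_frame(
            [
                ("P", 0.5, 10, 10, 6, 2, 0, 1),
                ("none", 0.5, 10, 10, 0, 0, 1, 1),
            ]
        )
        assert list(summarize_preferences(df)) == ["P"]

    def test_summary_invariant_enforced(self):
        table = pd.DataFrame(
            {"prop_invader": [0.5], "mean_alpha": [0.6], "se_alpha": [0.0], "n_trials": [1]}
        )
        with pytest.raises(ValueError):
            PreferenceSummary("P", table, overall_mean_alpha=0.9, n_excluded=0)


class TestBootstrapTest:
    def test_uniform_complete_preference_is_flagged(self):
        df = switch_frame(
            [("P", 0.5, 10, 10, 4 + i % 2, 0, 0, i) for i in range(6)]
        )
        res = preference_bootstrap_test(df, n_boot=200, seed=1)["P"]
        assert res.conclusive and res.prefers_invader
        assert res.ci[0] > 0.5

    def test_symmetric_alphas_not_flagged(self):
        df = switch_frame(
            [
                ("P", 0.5, 10, 10, 6, 2, 0, 1),
                ("P", 0.5, 10, 10, 2, 6, 0, 2),
                ("P", 0.5, 10, 10, 5, 5, 0, 3),
                ("P", 0.5, 10, 10, 5, 5, 0, 4),
            ]
        )
        res = preference_bootstrap_test(df, n_boot=200, seed=2)["P"]
        assert not res.prefers_invader

    def test_single_trial_is_inconclusive_not_error(self):
        df = switch_frame([("P", 0.5, 10, 10, 5, 5, 0, 1)])
        res = preference_bootstrap_test(df, n_boot=100, seed=3)["P"]
        assert not res.conclusive and not res.prefers_invader

    def test_detects_doubled_attack_rate_in_simulated_experiments(self):
        # invader attacked at twice the native rate: the CI should clear 0.5
        # in the majority of simulated experiments
        flagged = 0
        n_exp = 30
        master = np.random.SeedSequence(404).spawn(n_exp)
        for k, ss in enumerate(master):
            seeds = ss.spawn(15)
            rows = []
            for j, s in enumerate(seeds):
                ri, rn = simulate_switch_trial((2.0, 0.1), (1.0, 0.1), 10, 10, seed=s)
                rows.append(("P", 0.5, 10, 10, ri, rn, 0, j))
            res = preference_bootstrap_test(switch_frame(rows), n_boot=200, seed=k)["P"]
            flagged += res.prefers_invader
        assert flagged > n_exp / 2


class TestFrequencyIndependence:
    def test_fixed_parameters_show_no_availability_trend(self):
        # generator has no switching mechanism, so per-proportion mean alpha
        # should sit near a_i/(a_i+a_n) at every availability.  Counts are
        # scaled up 10x from the arena design: at small counts the
        # trial-level index is biased towards whichever type dominates the
        # arena (mass at exactly 0/1 when the rare type records no kills or
        # is wiped out), an estimator property, not switching.
        ratios = [(20, 180), (50, 150), (100, 100), (150, 50), (180, 20)]
        rows = []
        master = np.random.SeedSequence(88)
        for (ni, nn), ss in zip(ratios, master.spawn(len(ratios))):
            for j, s in enumerate(ss.spawn(150)):
                ri, rn = simulate_switch_trial((0.5, 0.0), (0.25, 0.0), ni, nn, seed=s)
                if ri + rn:
                    rows.append(("P", ni / (ni + nn), ni, nn, ri, rn, 0, j))
        summ = summarize_preferences(switch_frame(rows))["P"]
        means = summ.table.sort_values("prop_invader")["mean_alpha"].to_numpy()
        assert means.max() - means.min() < 0.05
        # preference stays on the invader side at every availability
        assert (means > 0.5).all()
        assert np.allclose(means, 0.5 / 0.75, atol=0.05)
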
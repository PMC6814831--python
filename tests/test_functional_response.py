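"""Unit and property tests for the depletion functional-response machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bioticres.functional_response import (
    AllZeroConsumptionError,
    FitError,
    RogersModel,
    ShapeRegressionResult,
    classify_fr_type,
    determine_fr_type,
    functional_response_ratio,
    logistic_shape_regression,
    max_feeding_rate,
    rogers_predict,
    rogers_root_bisect,
)

DENSITIES = (2, 4, 7, 10, 15)


def make_trials(densities, eaten_by_density, replicates=1):
    rows = []
    for d in densities:
        for r in range(replicates):
            e = eaten_by_density[d]
            rows.append({"density": d, "eaten": e[r] if isinstance(e, (list, tuple)) else e})
    return pd.DataFrame(rows)


class TestRogersPredict:
    def test_zero_prey_and_zero_attack(self):
        assert rogers_predict(2.0, 0.2, 1.0, 0) == 0.0
        assert rogers_predict(0.0, 0.2, 1.0, 12) == 0.0

    def test_no_handling_reduces_to_exponential_depletion(self):
        a, T, n0 = 1.7, 1.0, 10
        assert rogers_predict(a, 0.0, T, n0) == pytest.approx(n0 * (1 - math.exp(-a * T)), rel=1e-12)

    def test_matches_bisection_oracle_at_study_parameters(self):
        # root of the implicit equation at the strongest-attack group
        ne = rogers_predict(2.507, 0.200, 1.0, 15)
        assert ne == pytest.approx(4.3221, abs=5e-4)
        assert ne == pytest.approx(rogers_root_bisect(2.507, 0.200, 1.0, 15), abs=1e-8)

    def test_satisfies_implicit_equation(self):
        a, h, T, n0 = 1.2, 0.35, 1.0, 9
        ne = rogers_predict(a, h, T, n0)
        assert ne == pytest.approx(n0 * (1 - math.exp(a * (ne * h - T))), abs=1e-9)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            rogers_predict(-1.0, 0.2, 1.0, 5)
        with pytest.raises(ValueError):
            rogers_predict(1.0, 0.2, 0.0, 5)
        with pytest.raises(ValueError):
            rogers_predict(1.0, 0.2, 1.0, -3)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        a=st.floats(0.05, 8.0),
        h=st.floats(0.0, 1.0),
        T=st.floats(0.25, 4.0),
        n0=st.integers(0, 60),
    )
    def test_bounds_and_oracle_agreement(self, a, h, T, n0):
        ne = rogers_predict(a, h, T, n0)
        assert 0.0 <= ne <= n0
        if h > 0:
            assert ne <= T / h + 1e-9 + 0.0 or ne <= n0  # asymptotic ceiling or full depletion cap
        assert ne == pytest.approx(rogers_root_bisect(a, h, T, n0), abs=1e-8)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        a=st.floats(0.1, 5.0),
        h=st.floats(0.01, 0.8),
        T=st.floats(0.5, 2.0),
        n0=st.integers(1, 40),
    )
    def test_monotone_in_each_argument(self, a, h, T, n0):
        base = rogers_predict(a, h, T, n0)
        assert rogers_predict(a * 1.2, h, T, n0) >= base - 1e-10
        assert rogers_predict(a, h * 1.2, T, n0) <= base + 1e-10
        assert rogers_predict(a, h, T * 1.2, n0) >= base - 1e-10
        assert rogers_predict(a, h, T, n0 + 1) >= base - 1e-10


class TestDerivedMetrics:
    @pytest.mark.parametrize(
        "h, expected",
        [(0.112, 8.929), (0.204, 4.902), (1.0, 1.0)],
    )
    def test_max_feeding_rate(self, h, expected):
        assert max_feeding_rate(h) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize(
        "a, h, expected",
        [(2.507, 0.200, 12.535), (1.139, 0.204, 5.583), (1.0, 1.0, 1.0)],
    )
    def test_functional_response_ratio(self, a, h, expected):
        assert functional_response_ratio(a, h) == pytest.approx(expected, abs=5e-4)

    def test_reject_nonpositive(self):
        with pytest.raises(ValueError):
            max_feeding_rate(0.0)
        with pytest.raises(ValueError):
            functional_response_ratio(-1.0, 0.5)


class TestShapeRegression:
    def test_declining_proportions_give_negative_first_order(self):
        # noise-free saturating pattern: proportion eaten falls with density
        eaten = {2: 2, 4: 3, 7: 4, 10: 4, 15: 5}
        res = logistic_shape_regression(make_trials(DENSITIES, eaten, replicates=3), order=1)
        assert res.coef1 < 0

    def test_constant_proportions_give_null_coefficient(self):
        eaten = {2: 1, 4: 2, 10: 5}
        res = logistic_shape_regression(make_trials((2, 4, 10), eaten, replicates=4), order=1)
        assert res.coef1 == pytest.approx(0.0, abs=1e-6)
        assert res.p1 > 0.9

    def test_degenerate_consumption_raises(self):
        with pytest.raises(FitError):
            logistic_shape_regression(make_trials(DENSITIES, dict.fromkeys(DENSITIES, 0)))

    def test_too_few_densities_raises(self):
        with pytest.raises(ValueError):
            logistic_shape_regression(make_trials((5,), {5: 2}, replicates=4), order=1)
        with pytest.raises(ValueError):
            logistic_shape_regression(make_trials((2, 10), {2: 1, 10: 3}, replicates=4), order=2)


class TestClassification:
    @pytest.mark.parametrize(
        "result, expected",
        [
            (ShapeRegressionResult(1, -0.160, 1e-4), "II"),
            (ShapeRegressionResult(2, 0.3, 0.001, -0.05, 0.002), "III"),
            (ShapeRegressionResult(1, -0.1, 0.4), "inconclusive"),
            (ShapeRegressionResult(2, 0.3, 0.001, 0.05, 0.002), "inconclusive"),
        ],
    )
    def test_rule_application(self, result, expected):
        assert classify_fr_type(result, 0.05) == expected

    def test_sequenced_classification_on_simulated_depletion_data(self):
        from bioticres.simulate import FRDesign, SimParams, simulate_fr_experiment

        df = simulate_fr_experiment(
            {("P", "x"): SimParams(2.5, 0.2)}, FRDesign(control_replicates=0), seed=0
        )
        fr_type, used = determine_fr_type(df[df["is_control"] == 0])
        assert fr_type == "II"
        assert used.order == 1


class TestRogersFit:
    def test_recovers_parameters_from_noise_free_data(self):
        # noise-free in mean: integer counts allocated across replicates so
        # each density's average equals the deterministic prediction
        # (rounding every trial instead saturates the lowest density and
        # genuinely shifts the MLE)
        a, h = 2.5, 0.2
        rows = []
        for d in DENSITIES:
            pred = rogers_predict(a, h, 1.0, d)
            floor, k = int(pred), round(5 * (pred - int(pred)))
            for i in range(5):
                rows.append({"density": d, "eaten": floor + 1 if i < k else floor})
        res = RogersModel.from_dataframe(pd.DataFrame(rows)).fit()
        assert res.converged
        assert res.attack_rate == pytest.approx(a, rel=0.10)
        assert res.handling_time == pytest.approx(h, rel=0.10)

    def test_derived_fields_consistent(self):
        eaten = {2: 2, 4: 3, 7: 4, 10: 4, 15: 5}
        res = RogersModel.from_dataframe(make_trials(DENSITIES, eaten, replicates=3)).fit()
        assert res.frr * res.handling_time == pytest.approx(res.attack_rate, rel=1e-12)
        assert res.max_feeding_rate * res.handling_time == pytest.approx(1.0, rel=1e-12)
        assert res.llf == pytest.approx(res.model.loglike(np.log([res.attack_rate, res.handling_time])))

    def test_all_zero_consumption_is_boundary_error(self):
        trials = make_trials(DENSITIES, dict.fromkeys(DENSITIES, 0), replicates=2)
        with pytest.raises(AllZeroConsumptionError):
            RogersModel.from_dataframe(trials).fit()

    def test_single_density_rejected(self):
        with pytest.raises(ValueError):
            RogersModel([5, 5, 5], [1, 2, 1])

    def test_summary_mentions_estimates(self):
        eaten = {2: 2, 4: 3, 7: 4, 10: 4, 15: 5}
        res = RogersModel.from_dataframe(make_trials(DENSITIES, eaten, replicates=3)).fit()
        text = res.summary()
        assert "attack rate" in text and "FRR" in text


class TestBootstrap:
    def test_constant_strata_give_zero_width_intervals(self):
        eaten = {2: 2, 4: 3, 7: 4, 10: 4, 15: 5}
        res = RogersModel.from_dataframe(make_trials(DENSITIES, eaten, replicates=4)).fit()
        band = res.bootstrap(n_boot=50, seed=3)
        assert band.a_ci[0] == pytest.approx(band.a_ci[1], rel=1e-6)
        assert band.h_ci[0] == pytest.approx(band.h_ci[1], rel=1e-6)
        assert band.n_failed == 0

    def test_band_brackets_point_prediction(self):
        eaten = {2: [1, 2, 2], 4: [2, 3, 4], 7: [3, 4, 5], 10: [3, 4, 6], 15: [4, 5, 7]}
        res = RogersModel.from_dataframe(make_trials(DENSITIES, eaten, replicates=3)).fit()
        band = res.bootstrap(n_boot=200, seed=11)
        assert np.all(band.lower <= band.point + 1e-9)
        assert np.all(band.point <= band.upper + 1e-9)

    def test_default_settings(self):
        eaten = {2: 2, 4: 3, 7: 4, 10: 4, 15: 5}
        res = RogersModel.from_dataframe(make_trials(DENSITIES, eaten, replicates=2)).fit()
        import inspect

        sig = inspect.signature(res.bootstrap)
        assert sig.parameters["n_boot"].default == 2000
        assert sig.parameters["conf"].default == 0.95

    def test_invalid_settings_rejected(self):
        eaten = {2: 2, 4: 3, 7: 4, 10: 4, 15: 5}
        res = RogersModel.from_dataframe(make_trials(DENSITIES, eaten, replicates=2)).fit()
        with pytest.raises(ValueError):
            res.bootstrap(n_boot=0)
        with pytest.raises(ValueError):
            res.bootstrap(n_boot=10, conf=1.2)
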
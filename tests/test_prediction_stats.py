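import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ne_pipeline.errors import DomainError
from ne_pipeline.prediction_stats import (
    noblet_ne1,
    noblet_ne2,
    ols_fit,
    pearson_matrix,
    relative_error,
    stepwise_select,
)


def normal_equations(y, X):
    """Independent OLS oracle: solve (X'X) b = X'y directly."""
    X1 = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(X1.T @ X1, X1.T @ y)


class TestNobletEquations:
    @pytest.mark.parametrize(
        "de, ee, starch, cp, adf, expected",
        [
            (10.71, 2.13, 12.81, 17.32, 14.47, 6.71),  # wheat bran 1
            (13.50, 2.87, 20.81, 19.84, 9.01, 8.98),  # wheat bran 3
            (10.0, 0.0, 0.0, 0.0, 0.0, 7.00),
        ],
    )
    def test_de_based_prediction(self, de, ee, starch, cp, adf, expected):
        assert noblet_ne1(de, ee, starch, cp, adf) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize(
        "me, ee, starch, cp, adf, expected",
        [
            (9.96, 2.13, 12.81, 17.32, 14.47, 6.61),  # wheat bran 1
            (11.08, 1.97, 17.04, 18.84, 10.44, 7.58),  # wheat bran 2
            (10.0, 0.0, 0.0, 0.0, 0.0, 7.26),
        ],
    )
    def test_me_based_prediction(self, me, ee, starch, cp, adf, expected):
        assert noblet_ne2(me, ee, starch, cp, adf) == pytest.approx(expected, abs=0.005)

    @settings(deadline=None, derandomize=True)
    @given(de=st.floats(5, 20))
    def test_prediction_affine_in_energy(self, de):
        assert noblet_ne1(2 * de, 0, 0, 0, 0) == pytest.approx(
            2 * noblet_ne1(de, 0, 0, 0, 0), rel=1e-12
        )


class TestRelativeError:
    def test_wheat_shorts_underprediction(self):
        assert relative_error(12.47, 10.56, 10.35) == pytest.approx(19.3, abs=0.05)

    def test_zero_when_determined_matches_mean_prediction(self):
        assert relative_error(7.0, 6.5, 7.5) == 0.0

    def test_overprediction_is_negative(self, bran):
        r = bran.loc["wheat bran 3"]
        ne1 = noblet_ne1(r["DE"], r["EE"], r["starch"], r["CP"], r["ADF"])
        ne2 = noblet_ne2(r["ME"], r["EE"], r["starch"], r["CP"], r["ADF"])
        assert relative_error(r["NE"], ne1, ne2) == pytest.approx(-7.4, abs=0.05)

    def test_nonpositive_predictions_rejected(self):
        with pytest.raises(DomainError):
            relative_error(7.0, 1.0, -1.0)

    @settings(deadline=None, derandomize=True)
    @given(d=st.floats(1, 20), a=st.floats(1, 20), b=st.floats(1, 20), c=st.floats(0.1, 10))
    def test_invariant_to_common_rescaling(self, d, a, b, c):
        assert relative_error(c * d, c * a, c * b) == pytest.approx(
            relative_error(d, a, b), rel=1e-9
        )


class TestPearsonMatrix:
    def test_energy_chemistry_correlations_on_brans(self, bran):
        cm = pearson_matrix(bran[["CP", "NDF", "starch", "NE"]])
        assert cm.r.loc["NE", "CP"] == pytest.approx(0.92, abs=0.01)
        assert cm.r.loc["NDF", "starch"] == pytest.approx(-0.94, abs=0.01)
        assert cm.p.loc["NE", "CP"] < 0.01

    def test_diagonal_symmetry_and_bounds(self, bran):
        cm = pearson_matrix(bran[["CP", "NDF", "NE"]])
        assert (np.diag(cm.r) == 1.0).all()
        assert np.allclose(cm.r, cm.r.T)
        assert ((cm.r.to_numpy() >= -1) & (cm.r.to_numpy() <= 1)).all()

    def test_matches_covariance_oracle(self, bran):
        cm = pearson_matrix(bran[["CP", "NE"]])
        x, y = bran["CP"].to_numpy(), bran["NE"].to_numpy()
        oracle = np.cov(x, y, ddof=0)[0, 1] / (x.std() * y.std())
        assert cm.r.loc["CP", "NE"] == pytest.approx(oracle, rel=1e-12)

    def test_zero_variance_column_reported_absent(self, bran):
        t = bran[["CP", "NE"]].copy()
        t["const"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            cm = pearson_matrix(t)
        assert np.isnan(cm.r.loc["const", "CP"])
        assert cm.r.loc["CP", "NE"] == pytest.approx(0.9235, abs=1e-3)


class TestOlsFit:
    def test_crude_protein_model_matches_published(self, bran):
        m = ols_fit(bran, "NE", ["CP"])
        assert m.intercept == pytest.approx(-0.80, abs=0.01)
        assert m.coefficients["CP"] == pytest.approx(0.46, abs=0.01)
        assert m.r2 == pytest.approx(0.85, abs=0.01)
        assert m.p_value < 0.05

    def test_two_predictor_model_matches_published(self, bran):
        m = ols_fit(bran, "NE", ["GE", "CP"])
        assert m.intercept == pytest.approx(-21.65, abs=0.01)
        assert m.coefficients["GE"] == pytest.approx(1.20, abs=0.01)
        assert m.coefficients["CP"] == pytest.approx(0.35, abs=0.01)
        assert m.r2 == pytest.approx(0.94, abs=0.01)

    def test_exact_line_recovered(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "y": [1.0, 3.0, 5.0, 7.0]})
        m = ols_fit(df, "y", ["x"])
        assert m.intercept == pytest.approx(1.0)
        assert m.coefficients["x"] == pytest.approx(2.0)
        assert m.r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("predictors", [["CP"], ["NDF"], ["GE", "CP"], ["GE", "ME"]])
    def test_agrees_with_normal_equations_oracle(self, bran, predictors):
        m = ols_fit(bran, "NE", predictors)
        b = normal_equations(bran["NE"].to_numpy(), bran[predictors].to_numpy())
        assert m.intercept == pytest.approx(b[0], rel=1e-9)
        for c, exp in zip(predictors, b[1:]):
            assert m.coefficients[c] == pytest.approx(exp, rel=1e-9)

    def test_single_predictor_r2_equals_pearson_r_squared(self, bran):
        for var, printed_r in [("CP", 0.92), ("NDF", -0.84)]:
            m = ols_fit(bran, "NE", [var])
            r = pearson_matrix(bran[[var, "NE"]]).r.loc[var, "NE"]
            assert m.r2 == pytest.approx(r**2, rel=1e-12)
            assert r == pytest.approx(printed_r, abs=0.01)

    def test_rank_deficiency_names_collinear_set(self, bran):
        t = bran.copy()
        t["CP2"] = 2.0 * t["CP"]
        with pytest.raises(DomainError, match="CP2"):
            ols_fit(t, "NE", ["CP", "CP2"])

    def test_information_criteria_follow_gaussian_form(self, bran):
        m = ols_fit(bran, "NE", ["CP"])
        n, k = m.n, 2
        assert m.aic == pytest.approx(n * np.log(m.sse / n) + 2 * k)
        assert m.bic == pytest.approx(n * np.log(m.sse / n) + k * np.log(n))


class TestStepwise:
    def test_crude_protein_enters_first_from_chemistry_pool(self, bran):
        models = stepwise_select(bran, "NE", ["GE", "CP", "EE", "starch", "NDF", "ADF", "ash"])
        assert models, "no model selected"
        # the single-predictor model on the path is CP
        singles = [m for m in models if len(m.predictors) == 1]
        assert singles and singles[0].predictors == ("CP",)

    def test_energy_pool_yields_two_variable_model(self, bran):
        models = stepwise_select(bran, "NE", ["GE", "ME"])
        best = models[0]
        assert set(best.predictors) == {"GE", "ME"}
        assert best.r2 == pytest.approx(0.94, abs=0.01)

    def test_perfect_single_candidate(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 4.0]})
        df["y"] = 2 * df["x"] + 1
        models = stepwise_select(df, "y", ["x"])
        assert len(models) == 1 and models[0].r2 == pytest.approx(1.0)

    def test_deterministic(self, bran):
        a = stepwise_select(bran, "NE", ["GE", "CP", "NDF", "ADF"])
        b = stepwise_select(bran, "NE", ["GE", "CP", "NDF", "ADF"])
        assert [m.predictors for m in a] == [m.predictors for m in b]

    def test_no_entry_returns_empty_with_diagnostic(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": rng.normal(size=8), "y": rng.normal(size=8)})
        with pytest.warns(UserWarning, match="no candidate"):
            assert stepwise_select(df, "y", ["x"], entry_alpha=1e-6) == []

    def test_ranked_by_fit_quality(self, bran):
        models = stepwise_select(bran, "NE", ["GE", "CP", "EE", "starch", "NDF", "ADF", "ash"])
        r2s = [m.r2 for m in models]
        assert r2s == sorted(r2s, reverse=True)
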
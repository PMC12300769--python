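"""Equation representation and the three discovery engines."""

import inspect

import numpy as np
import pandas as pd
import pytest

from sdml.features import score_features
from sdml.symreg import (
    DictionaryOverflowError,
    Equation,
    EvaluationError,
    Factor,
    Term,
    evaluate_equation,
    fit_gp,
    fit_hsie,
    fit_mftec,
    printed_equation_demo,
)
from sdml.symreg.equation import expr_from_text, expr_to_text
from tests.conftest import make_table


class TestEquation:
    def test_term_equation_round_trips_through_json(self):
        eq = Equation(
            terms=[
                Term((Factor("MW"),), 1.38),
                Term((Factor("ExposureTime", power=2),), -1.18),
                Term((Factor("ExposureTime", transform="sqrt_abs"), Factor("MW")), 1.08),
                Term((Factor("pKa", power=-1), Factor("TPSA")), 0.2),
            ],
            intercept=-2.5,
            fit_r2=0.776,
            method="hsie",
        )
        back = Equation.from_json(eq.to_json())
        assert back == eq
        df = pd.DataFrame({"MW": [400.0, 600.0], "ExposureTime": [10.0, 30.0],
                           "pKa": [2.0, -0.5], "TPSA": [40.0, 10.0]})
        np.testing.assert_allclose(back.predict(df), eq.predict(df))

    def test_expression_equation_round_trips(self):
        text = "(add (mul 2.0 x1) (sin x2))"
        eq = Equation(method="gp", expression=text)
        back = Equation.from_json(eq.to_json())
        df = pd.DataFrame({"x1": [0.5, -1.0], "x2": [0.0, 3.1]})
        np.testing.assert_allclose(back.predict(df), 2 * df["x1"] + np.sin(df["x2"]))
        assert expr_to_text(expr_from_text(text)) == text

    def test_protected_operators_keep_demo_equations_finite(self):
        df = pd.DataFrame({"MW": [500.0], "logKow": [0.0], "pKa": [0.0]})
        for which in (3, 4):
            eq = printed_equation_demo(which)
            assert np.isfinite(eq.predict(df)).all()

    def test_missing_feature_named_in_error(self):
        eq = Equation(terms=[Term((Factor("MW"),), 1.0)])
        with pytest.raises(EvaluationError, match="MW"):
            eq.predict(pd.DataFrame({"pKa": [1.0]}))

    def test_intercept_only_equation_is_constant(self):
        eq = Equation(terms=[], intercept=3.25)
        preds, _ = evaluate_equation(eq, pd.DataFrame({"x": [1.0, 2.0, 9.0]}))
        np.testing.assert_allclose(preds, 3.25)


class TestGP:
    def test_planted_sum_recovered_in_most_seeds(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 2))
        t = make_table(X, X[:, 0] + X[:, 1])
        hits = 0
        for seed in range(10):
            eq = fit_gp(t, pop=500, gens=20, seed=seed)
            pred, _ = evaluate_equation(eq, t)
            hits += np.sqrt(np.mean((pred - t.y.to_numpy()) ** 2)) < 1e-6
        assert hits >= 8

    def test_zero_generations_returns_finite_incumbent(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        t = make_table(X, X[:, 0])
        eq = fit_gp(t, pop=50, gens=0, seed=0)
        pred, _ = evaluate_equation(eq, t)
        assert np.isfinite(pred).all()

    def test_default_budget_matches_reference_protocol(self):
        sig = inspect.signature(fit_gp)
        assert sig.parameters["pop"].default == 2000
        assert sig.parameters["gens"].default == 100

    def test_flattenable_result_serializes_to_terms(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 2))
        t = make_table(X, 2.0 * X[:, 0])
        eq = fit_gp(t, pop=300, gens=10, seed=1)
        back = Equation.from_json(eq.to_json())
        pred_a, _ = evaluate_equation(eq, t)
        pred_b, _ = evaluate_equation(back, t)
        np.testing.assert_allclose(pred_a, pred_b)


class TestMFTEC:
    def _scores(self, t, seed=0):
        return score_features(t, n_bootstrap=0, seed=seed)

    def test_planted_sqrt_transform_dominates(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3))
        y = 2 * np.sqrt(np.abs(X[:, 0])) + rng.normal(0, 0.05, 200)
        t = make_table(X, y)
        eq = fit_mftec(t, self._scores(t), m=3, seed=0)
        # dominant term by standardized magnitude |coef| * sd(column)
        mags = {
            term.label(): abs(term.coefficient) * np.std(term.evaluate(t.data) / term.coefficient)
            for term in eq.terms
        }
        assert max(mags, key=mags.get) == "sqrt_abs(x1)"
        assert eq.fit_r2 > 0.9

    def test_constant_target_collapses_to_intercept(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 3))
        t = make_table(X, np.full(100, 1.5))
        eq = fit_mftec(t, self._scores(t), m=3, seed=0)
        assert eq.intercept == pytest.approx(1.5)
        assert all(abs(term.coefficient) < 1e-6 for term in eq.terms)

    def test_flattened_equation_equals_stacked_pipeline(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(150, 4))
        y = X[:, 0] + 0.5 * X[:, 1] * X[:, 2] + rng.normal(0, 0.1, 150)
        t = make_table(X, y)
        eq, stacked = fit_mftec(t, self._scores(t), m=4, seed=0, return_details=True)
        pred, _ = evaluate_equation(eq, t)
        np.testing.assert_allclose(pred, stacked, atol=1e-8)

    def test_nonpositive_m_rejected(self):
        t = make_table(np.zeros((30, 2)), np.zeros(30))
        with pytest.raises(ValueError):
            fit_mftec(t, [], m=0)


class TestHSIE:
    def test_pure_cube_recovered_exactly(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 3))
        t = make_table(X, X[:, 0] ** 3)
        eq = fit_hsie(t, max_order=3, seed=0)
        assert [term.label() for term in eq.terms] == ["x1^3"]
        assert eq.terms[0].coefficient == pytest.approx(1.0, rel=0.01)

    def test_linear_truth_with_order_one_equals_ols(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 3))
        beta = np.array([1.5, -2.0, 0.5])
        y = X @ beta + 0.7
        t = make_table(X, y)
        eq = fit_hsie(t, max_order=1, seed=0)
        coefs = {term.label(): term.coefficient for term in eq.terms}
        ols = np.linalg.lstsq(np.column_stack([np.ones(100), X]), y, rcond=None)[0]
        assert eq.intercept == pytest.approx(ols[0], abs=1e-6)
        for j, name in enumerate(["x1", "x2", "x3"]):
            assert coefs[name] == pytest.approx(ols[j + 1], abs=1e-6)

    def test_sparse_support_recovery(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(500, 4))
            y = 2 * X[:, 0] - 1.5 * X[:, 1] * X[:, 2] + rng.normal(0, 0.1, 500)
            t = make_table(X, y)
            eq = fit_hsie(t, max_order=3, seed=seed)
            labels = {term.label(): term.coefficient for term in eq.terms}
            ok = "x1" in labels and "x2 * x3" in labels
            ok = ok and all(abs(c) <= 0.2 for l, c in labels.items()
                            if l not in ("x1", "x2 * x3"))
            hits += ok
        assert hits >= 4

    def test_fit_r2_is_self_consistent(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(120, 3))
        y = X[:, 0] - X[:, 1] ** 2 + rng.normal(0, 0.2, 120)
        t = make_table(X, y)
        eq = fit_hsie(t, seed=0)
        _, r2 = evaluate_equation(eq, t)
        assert r2 == pytest.approx(eq.fit_r2, abs=1e-10)

    def test_dictionary_overflow_guard(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(45, 50))
        t = make_table(X, rng.normal(size=45))
        with pytest.raises(DictionaryOverflowError):
            fit_hsie(t, max_order=3, seed=0)
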
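"""Standardisation, collinearity, chi-square, R^2, model selection, GLMMs.

Oracles: closed forms for z-scores/VIF/R^2, the textbook O/E formula for
the chi-square, statsmodels' variance_inflation_factor as a cross-check,
and R lme4::glmer as the independent Poisson-GLMM reference.
"""

from __future__ import annotations

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest

from migtrack.glmm import fit_poisson_glmm
from migtrack.stats import (
    ModelResult,
    ModelSpec,
    chi_square_schedule,
    enumerate_candidates,
    fit_candidates,
    r2_mixed,
    select_model,
    vif,
    zscore,
)

warnings.filterwarnings("ignore", module="statsmodels")


class TestZscore:
    def test_closed_form(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1], atol=1e-12)

    def test_idempotence(self):
        x = zscore(np.random.default_rng(0).normal(3, 7, 50))
        np.testing.assert_allclose(zscore(x), x, atol=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            zscore([2.0, 2.0, 2.0])


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        X = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
        np.testing.assert_allclose(vif(X), [1.0, 1.0], atol=1e-12)

    def test_correlation_0_6_closed_form(self):
        rng = np.random.default_rng(4)
        a = zscore(rng.normal(0, 1, 500))
        c = rng.normal(0, 1, 500)
        c = c - a * (a @ c) / (a @ a)  # exactly orthogonal to a
        c = zscore(c)
        b = 0.6 * a + np.sqrt(1 - 0.36) * c
        got = vif(np.column_stack([a, b]))
        np.testing.assert_allclose(got, [1.5625, 1.5625], atol=1e-9)

    def test_duplicated_column_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            vif(np.column_stack([x, x]))

    def test_matches_statsmodels_cross_check(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(8)
        X = rng.standard_normal((300, 3))
        X[:, 2] += 0.5 * X[:, 0]
        Xc = X - X.mean(axis=0)
        expected = [variance_inflation_factor(Xc, j) for j in range(3)]
        np.testing.assert_allclose(vif(X), expected, rtol=1e-8)


class TestChiSquare:
    def test_hand_oracle_table(self):
        stat, dof = chi_square_schedule([[30, 10], [10, 30]])
        assert stat == pytest.approx(20.0, abs=1e-12)
        assert dof == 1

    def test_independent_table_zero(self):
        stat, dof = chi_square_schedule([[5, 5], [5, 5]])
        assert stat == 0.0 and dof == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_schedule([[0, 0], [5, 5]])

    def test_matches_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            k = int(rng.integers(2, 6))
            t = rng.integers(1, 200, size=(2, k)).astype(float)
            stat, dof = chi_square_schedule(t)
            # direct O/E computation
            total = t.sum()
            e = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
            expected = ((t - e) ** 2 / e).sum()
            assert stat == pytest.approx(expected, abs=1e-9)
            assert dof == k - 1


class TestR2Mixed:
    def test_closed_form(self):
        assert r2_mixed(1, 1, 2) == (0.25, 0.5)

    def test_no_random_variance_marginal_equals_conditional(self):
        m, c = r2_mixed(2.0, 0.0, 3.0)
        assert m == c

    def test_no_fixed_variance_zero_marginal(self):
        m, c = r2_mixed(0.0, 1.0, 1.0)
        assert m == 0.0 and c == 0.5

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            r2_mixed(0, 0, 0)


def _result(terms, aic, n_params):
    spec = ModelSpec("y", terms, "bird")
    return ModelResult(spec, aic, n_params, 0.0, {}, 1.0, 1.0, 1.0)


class TestSelectModel:
    def test_most_parsimonious_within_2_aic(self):
        a = _result(("a", "b", "c"), 100.0, 3)
        b = _result(("a", "b"), 101.5, 2)
        c = _result(("a",), 103.0, 1)
        assert select_model([a, b, c]) is b

    def test_single_candidate(self):
        a = _result(("a",), 50.0, 2)
        assert select_model([a]) is a

    def test_tie_on_params_breaks_by_aic(self):
        a = _result(("a",), 100.0, 2)
        b = _result(("b",), 101.0, 2)
        assert select_model([a, b]) is a

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        results = [
            _result((f"t{i}",), 100 + float(rng.uniform(0, 4)), int(rng.integers(1, 5)))
            for i in range(8)
        ]
        chosen = select_model(results)
        for _ in range(10):
            shuffled = list(rng.permutation(len(results)))
            assert select_model([results[i] for i in shuffled]) is chosen

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_model([])


class TestEnumerate:
    def test_two_main_effects_four_subsets(self):
        assert len(enumerate_candidates(("a", "b"))) == 4

    def test_marginality_with_interaction(self):
        subsets = enumerate_candidates(("season", "sex", "season:sex"))
        assert len(subsets) == 5
        assert ("season", "sex", "season:sex") in subsets
        assert all(
            "season:sex" not in s or ("season" in s and "sex" in s) for s in subsets
        )


class TestMixedModels:
    def test_gaussian_slope_recovery_and_selection(self):
        rng = np.random.default_rng(17)
        n, n_birds = 5000, 40
        g = rng.integers(0, n_birds, n)
        tw = rng.normal(0, 1, n)
        cw = rng.normal(0, 1, n)
        b = rng.normal(0, 0.5, n_birds)
        y = 30 + 1.0 * tw + b[g] + rng.normal(0, 2, n)
        df = pd.DataFrame(
            {"speed": y, "tailwind": tw, "crosswind": cw, "bird": g}
        )
        res = fit_candidates(
            df,
            ModelSpec("speed", ("tailwind", "crosswind"), "bird"),
            continuous=["tailwind", "crosswind"],
        )
        sel = select_model(res)
        assert "tailwind" in sel.terms
        est, se = sel.coefficients["tailwind"]
        assert est == pytest.approx(1.0, abs=0.1)
        r2m, r2c = sel.r2()
        assert 0 < r2m < r2c <= 1

    def test_correlated_predictors_screened(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 200)
        df = pd.DataFrame(
            {"y": x, "a": x, "b": 0.9 * x + 0.1 * rng.normal(0, 1, 200), "g": 0}
        )
        with pytest.raises(ValueError, match="correlated"):
            fit_candidates(df, ModelSpec("y", ("a", "b"), "g"), continuous=["a", "b"])

    def test_poisson_glmm_matches_lme4_glmer(self, tmp_path):
        rng = np.random.default_rng(9)
        n, n_birds = 400, 20
        g = rng.integers(0, n_birds, n)
        x = rng.normal(0, 1, n)
        b = rng.normal(0, 0.4, n_birds)
        y = rng.poisson(np.exp(0.8 + 0.3 * x + b[g]))
        fit = fit_poisson_glmm(y, np.column_stack([np.ones(n), x]), g, ["Intercept", "x"])
        csv = tmp_path / "d.csv"
        pd.DataFrame({"y": y, "x": x, "g": g}).to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}'); d$g <- factor(d$g)\n"
            "m <- glmer(y ~ x + (1|g), data=d, family=poisson)\n"
            "cat(fixef(m), sqrt(unlist(VarCorr(m))), AIC(m), sep=',')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        b0, b1, sigma, aic = (float(v) for v in out.stdout.strip().split(","))
        assert fit.fe_params[0] == pytest.approx(b0, abs=0.02)
        assert fit.fe_params[1] == pytest.approx(b1, abs=0.02)
        assert fit.sigma_re == pytest.approx(sigma, abs=0.05)
        # glmer uses a Laplace approximation; AICs agree to ~1 unit
        assert fit.aic == pytest.approx(aic, abs=1.5)
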
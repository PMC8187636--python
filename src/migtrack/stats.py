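"""Feature standardisation, collinearity screens, mixed-model fitting,
parsimony model selection, and schedule chi-square tests.

Continuous responses and predictors are z-scored so coefficients are
comparable in SD units. Candidate models are all fixed-effect subsets of
the full model that respect marginality (an interaction enters only with
both main effects), ranked by ML AIC; among candidates within 2 AIC
units of the best, the most parsimonious (fewest parameters) is
retained. Variance explained follows the Nakagawa-Schielzeth marginal /
conditional R^2 decomposition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .glmm import fit_poisson_glmm

logger = logging.getLogger(__name__)

CORRELATION_SCREEN_R = 0.60
VIF_MAX = 10.0


def zscore(values) -> np.ndarray:
    """Standardise to mean 0, sample SD 1 (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("zscore needs a 1-D vector of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


def vif(design) -> np.ndarray:
    """Variance inflation factor per column: VIF_j = 1 / (1 - R^2_j).

    R^2_j comes from regressing column j (with intercept) on the others.
    Rank-deficient designs have infinite VIF and raise.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("vif needs >= 2 predictor columns")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient (infinite VIF)")
    out = np.empty(p)
    ones = np.ones((n, 1))
    for j in range(p):
        yj = X[:, j]
        Xo = np.hstack([ones, np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ beta
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
        out[j] = 1.0 / (1.0 - r2)
    return out


def chi_square_schedule(table) -> tuple[float, int]:
    """Pearson chi-square (no continuity correction) on a 2 x k count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    res = chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof)


def r2_mixed(var_fixed: float, var_random: float, var_resid: float) -> tuple[float, float]:
    """Marginal and conditional R^2 from variance components.

    R2_marginal = fixed / total; R2_conditional = (fixed + random) / total.
    """
    for v in (var_fixed, var_random, var_resid):
        if v < 0:
            raise ValueError("variance components must be non-negative")
    total = var_fixed + var_random + var_resid
    if total == 0:
        raise ValueError("all variance components are zero")
    return var_fixed / total, (var_fixed + var_random) / total


@dataclass(frozen=True)
class ModelSpec:
    """One mixed model: response, fixed terms, grouping column, family."""

    response: str
    fixed_terms: tuple[str, ...]
    group: str
    family: str = "gaussian"  # or "poisson"

    def __post_init__(self):
        if self.family not in ("gaussian", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class ModelResult:
    """A fitted candidate: AIC, parameter count, coefficients, variances."""

    spec: ModelSpec
    aic: float
    n_params: int
    llf: float
    coefficients: dict[str, tuple[float, float]]  # name -> (estimate, SE)
    var_fixed: float
    var_random: float
    var_resid: float
    converged: bool = True
    extra: dict = field(default_factory=dict)

    @property
    def terms(self) -> tuple[str, ...]:
        return self.spec.fixed_terms

    def r2(self) -> tuple[float, float]:
        return r2_mixed(self.var_fixed, self.var_random, self.var_resid)


def enumerate_candidates(terms: tuple[str, ...]) -> list[tuple[str, ...]]:
    """All subsets of ``terms`` respecting marginality.

    Interactions are written "a:b" and require both main effects in the
    subset. The empty (intercept-only) subset is included. Term order
    within a subset follows the full model's order.
    """
    terms = tuple(terms)
    subsets = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            ok = True
            for t in combo:
                if ":" in t:
                    a, b = t.split(":", 1)
                    if a not in combo or b not in combo:
                        ok = False
                        break
            if ok:
                subsets.append(combo)
    return subsets


def correlation_screen(data: pd.DataFrame, columns: list[str], r_max: float = CORRELATION_SCREEN_R):
    """Raise when any pair of continuous predictors has |r| >= r_max."""
    if len(columns) < 2:
        return
    corr = data[columns].corr().to_numpy()
    for i in range(len(columns)):
        for j in range(i + 1, len(columns)):
            if abs(corr[i, j]) >= r_max:
                raise ValueError(
                    f"predictors {columns[i]!r} and {columns[j]!r} are highly "
                    f"correlated (|r| = {abs(corr[i, j]):.2f} >= {r_max})"
                )


def _design_matrix(data: pd.DataFrame, terms: tuple[str, ...]):
    """Intercept + treatment-coded design matrix for the given terms."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["Intercept"]

    def main_effect(t: str):
        col = data[t]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(col.astype(str)))
            out = []
            for lev in levels[1:]:  # treatment coding, first level reference
                out.append(((col.astype(str) == lev).to_numpy(float), f"{t}[{lev}]"))
            return out
        return [(col.to_numpy(float), t)]

    for t in terms:
        if ":" in t:
            a, b = t.split(":", 1)
            for ca, na in main_effect(a):
                for cb, nb in main_effect(b):
                    cols.append(ca * cb)
                    names.append(f"{na}:{nb}")
        else:
            for c, nm in main_effect(t):
                cols.append(c)
                names.append(nm)
    return np.column_stack(cols), names


def _fit_one(data: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    import statsmodels.api as sm

    X, names = _design_matrix(data, spec.fixed_terms)
    y = data[spec.response].to_numpy(float)
    groups = data[spec.group].to_numpy()
    eta_cols = slice(0, X.shape[1])
    if spec.family == "gaussian":
        model = sm.MixedLM(y, X, groups=groups)
        fit = model.fit(reml=False)
        if not np.isfinite(fit.llf):
            raise RuntimeError("MixedLM likelihood did not converge")
        beta = np.asarray(fit.fe_params)
        var_random = float(np.asarray(fit.cov_re)[0, 0])
        var_resid = float(fit.scale)
        k = X.shape[1] + 2  # fixed effects + random-intercept var + residual var
        llf = float(fit.llf)
        coef = {
            nm: (float(b), float(se))
            for nm, b, se in zip(names, beta, np.asarray(fit.bse_fe))
        }
    else:
        fit = fit_poisson_glmm(y, X, groups, exog_names=names)
        beta = fit.fe_params
        var_random = fit.sigma_re**2
        # lognormal approximation to the Poisson observation-level variance
        lam = float(np.exp(X @ beta).mean())
        var_resid = float(np.log1p(1.0 / lam)) if lam > 0 else np.inf
        k = fit.n_params
        llf = fit.llf
        coef = {
            nm: (float(b), float(se))
            for nm, b, se in zip(names, beta, fit.se[: len(beta)])
        }
    var_fixed = float(np.var(X @ beta))
    return ModelResult(
        spec=spec,
        aic=2.0 * k - 2.0 * llf,
        n_params=k,
        llf=llf,
        coefficients=coef,
        var_fixed=var_fixed,
        var_random=var_random,
        var_resid=var_resid,
    )


def fit_candidates(
    data: pd.DataFrame,
    spec: ModelSpec,
    continuous: list[str] | None = None,
) -> list[ModelResult]:
    """Fit every marginality-respecting fixed-effect subset of ``spec``.

    ``continuous`` names the continuous predictors, which must already be
    z-scored; they are screened for pairwise |r| >= 0.60 and VIF >= 10 in
    the full model. Candidates that fail to converge are dropped with a
    warning.
    """
    if continuous:
        correlation_screen(data, continuous)
        if len(continuous) >= 2:
            v = vif(data[continuous].to_numpy(float))
            bad = [c for c, vj in zip(continuous, v) if vj >= VIF_MAX]
            if bad:
                raise ValueError(f"predictors {bad} exceed VIF {VIF_MAX}")
    results = []
    for subset in enumerate_candidates(spec.fixed_terms):
        sub = ModelSpec(spec.response, subset, spec.group, spec.family)
        try:
            results.append(_fit_one(data, sub))
        except Exception as exc:  # noqa: BLE001 - optimizer failures vary
            logger.warning("candidate %s dropped: %s", subset, exc)
    if not results:
        raise RuntimeError("no candidate model converged")
    return results


def select_model(results: list[ModelResult]) -> ModelResult:
    """Most parsimonious model within 2 AIC units of the best.

    Ties on parameter count break by lower AIC, then by lexicographic
    term order, so the choice is invariant to candidate-list order.
    """
    if not results:
        raise ValueError("empty candidate list")
    best_aic = min(r.aic for r in results)
    eligible = [r for r in results if r.aic <= best_aic + 2.0]
    return min(eligible, key=lambda r: (r.n_params, r.aic, r.terms))


def selection_table(results: list[ModelResult]) -> pd.DataFrame:
    """One row per candidate: terms, AIC, dAIC, n_params, selected flag."""
    chosen = select_model(results)
    best_aic = min(r.aic for r in results)
    rows = [
        {
            "terms": " + ".join(r.terms) if r.terms else "(intercept)",
            "aic": r.aic,
            "delta_aic": r.aic - best_aic,
            "n_params": r.n_params,
            "selected": r is chosen,
        }
        for r in sorted(results, key=lambda r: r.aic)
    ]
    return pd.DataFrame(rows)
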
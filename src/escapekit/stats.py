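"""Factorial mixed-effects analysis: EMMs, contrasts, Holm correction.

Continuous responses use a linear mixed model with a subject random
intercept; binary responses use a Laplace-approximate (MAP) logistic mixed
model, falling back to variational inference and finally to a plain GLM
without random effects when optimization fails.  Contrast tests are Wald
tests with a normal reference distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FactorialFit",
    "EMMTable",
    "ContrastTable",
    "RankDeficientDesignError",
    "fit_factorial_mixed",
    "estimated_marginal_means",
    "contrast",
    "contrast_table",
    "cell_weights",
    "holm_bonferroni",
    "questionnaire_select",
    "between_person_variance_explained",
]

FACTORS = ("threat", "tti", "behavior")


class RankDeficientDesignError(ValueError):
    pass


@dataclass
class FactorialFit:
    """Fixed-effects view of a fitted factorial mixed model."""

    family: str  # continuous | binary
    fe_params: np.ndarray
    cov_fe: np.ndarray
    design_info: object
    levels: dict
    converged: bool
    method: str  # which optimizer / fallback produced the fit
    random_intercept_sd: float
    result: object = None  # the underlying statsmodels results object


def _check_cells(data: pd.DataFrame, factors: Sequence[str]) -> dict:
    levels = {f: sorted(data[f].astype(str).unique()) for f in factors}
    counts = data.groupby([data[f].astype(str) for f in factors]).size()
    empty = []
    from itertools import product

    for combo in product(*(levels[f] for f in factors)):
        key = combo if len(combo) > 1 else combo[0]
        if key not in counts.index:
            empty.append(combo)
    if empty:
        raise RankDeficientDesignError(
            "design cells without observations: "
            + ", ".join("/".join(c) for c in empty)
        )
    return levels


def fit_factorial_mixed(
    data: pd.DataFrame,
    response: str,
    family: str = "continuous",
    factors: Sequence[str] = FACTORS,
    subject: str = "subject",
) -> FactorialFit:
    """Fit ``response ~ f1 * f2 * ... + (1 | subject)``.

    Factors with a single observed level are dropped from the fixed-effects
    formula (sub-designs are allowed).  Rows with a missing response are
    dropped listwise.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    if family not in ("continuous", "binary"):
        raise ValueError(f"unknown family {family!r}")
    df = data.dropna(subset=[response]).copy()
    if df[subject].nunique() < 2:
        raise ValueError("need at least two subjects")
    used = [f for f in factors if df[f].nunique() > 1]
    if not used:
        raise ValueError("no factor varies in the data")
    levels = _check_cells(df, used)
    if family == "binary" and not set(df[response].unique()) <= {0, 1, 0.0, 1.0}:
        raise ValueError("binary responses must lie in {0, 1}")

    rhs = " * ".join(f"C({f})" for f in used)
    formula = f"{response} ~ {rhs}"

    if family == "continuous":
        model = smf.mixedlm(formula, df, groups=df[subject])
        fit = None
        method_used = None
        for method in ("lbfgs", "bfgs", "cg", "powell", "nm"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cand = model.fit(reml=True, method=method, maxiter=500)
                if np.all(np.isfinite(cand.fe_params)):
                    fit = cand
                    method_used = method
                    if getattr(cand, "converged", True):
                        break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if fit is None:
            raise RuntimeError("all mixed-model optimizers failed")
        k = len(fit.fe_params)
        return FactorialFit(
            family="continuous",
            fe_params=np.asarray(fit.fe_params),
            cov_fe=np.asarray(fit.cov_params())[:k, :k],
            design_info=model.data.design_info,
            levels=levels,
            converged=bool(getattr(fit, "converged", True)),
            method=method_used,
            random_intercept_sd=float(np.sqrt(max(fit.cov_re.values[0, 0], 0.0))),
            result=fit,
        )

    # binary: Laplace-approximate (MAP) logistic mixed model, then
    # variational fallback, then a GLM without the random intercept
    vc = {"subject_re": f"0 + C({subject})"}
    model = BinomialBayesMixedGLM.from_formula(formula, vc, df)
    for method in ("map", "vb"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                # the optimizer draws random starting values from the global
                # RNG; pin it so identical inputs give identical fits
                state = np.random.get_state()
                np.random.seed(20231018)
                try:
                    res = model.fit_map() if method == "map" else model.fit_vb()
                finally:
                    np.random.set_state(state)
            k = model.k_fep
            params = np.asarray(res.params[:k])
            if method == "map":
                cov = np.asarray(res.cov_params())[:k, :k]
            else:  # VB gives a diagonal posterior approximation
                cov = np.diag(np.asarray(res.fe_sd) ** 2)
            if np.all(np.isfinite(params)) and np.all(np.isfinite(cov)):
                sd = float(np.exp(res.params[k])) if len(res.params) > k else 0.0
                return FactorialFit(
                    family="binary",
                    fe_params=params,
                    cov_fe=cov,
                    design_info=model.data.design_info,
                    levels=levels,
                    converged=True,
                    method=method,
                    random_intercept_sd=sd,
                    result=res,
                )
        except (np.linalg.LinAlgError, ValueError):
            continue
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = smf.glm(formula, df, family=sm.families.Binomial()).fit()
    return FactorialFit(
        family="binary",
        fe_params=np.asarray(glm.params),
        cov_fe=np.asarray(glm.cov_params()),
        design_info=glm.model.data.design_info,
        levels=levels,
        converged=bool(glm.converged),
        method="glm_no_re",
        random_intercept_sd=0.0,
        result=glm,
    )


@dataclass
class EMMTable:
    """Estimated marginal means: one row per design cell, equal cell weights."""

    cells: pd.DataFrame  # factor columns + emm (+ emm_response for binary)
    X: np.ndarray  # cell design matrix (cells x fixed effects)
    fe_params: np.ndarray
    cov_fe: np.ndarray
    family: str


def estimated_marginal_means(fit: FactorialFit) -> EMMTable:
    """Model-predicted cell means with random effects at zero.

    Binary fits report both the link (log-odds) and response (probability)
    scales; contrasts operate on the link scale.
    """
    from itertools import product
    from patsy import build_design_matrices

    factors = list(fit.levels)
    grid = pd.DataFrame(
        list(product(*(fit.levels[f] for f in factors))), columns=factors
    )
    (X,) = build_design_matrices([fit.design_info], grid)
    X = np.asarray(X)
    emm = X @ fit.fe_params
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov_fe, X))
    out = grid.copy()
    out["emm"] = emm
    out["se"] = se
    if fit.family == "binary":
        out["emm_response"] = 1.0 / (1.0 + np.exp(-emm))
    return EMMTable(cells=out, X=X, fe_params=fit.fe_params, cov_fe=fit.cov_fe, family=fit.family)


def contrast(emms: EMMTable, weights: Sequence[float]) -> tuple[float, float, float]:
    """Wald test of a linear combination of EMMs: (estimate, SE, p)."""
    w = np.asarray(weights, dtype=float)
    if len(w) != len(emms.cells):
        raise ValueError(
            f"weight vector has length {len(w)}, expected {len(emms.cells)} cells"
        )
    xw = w @ emms.X
    est = float(xw @ emms.fe_params)
    se = float(np.sqrt(xw @ emms.cov_fe @ xw))
    if se == 0:
        p = 1.0 if est == 0 else 0.0
    else:
        p = float(2.0 * sps.norm.sf(abs(est) / se))
    return est, se, p


def cell_weights(
    cells: pd.DataFrame, plus: dict, minus: Optional[dict] = None
) -> np.ndarray:
    """Averaging difference weights: +1/n over cells matching ``plus``,
    -1/m over cells matching ``minus``."""

    def mask(sel: dict) -> np.ndarray:
        m = np.ones(len(cells), dtype=bool)
        for key, val in sel.items():
            vals = val if isinstance(val, (list, tuple, set)) else [val]
            m &= cells[key].astype(str).isin([str(v) for v in vals]).to_numpy()
        return m

    w = np.zeros(len(cells))
    mp = mask(plus)
    if not mp.any():
        raise ValueError(f"no cells match {plus}")
    w[mp] = 1.0 / mp.sum()
    if minus is not None:
        mm = mask(minus)
        if not mm.any():
            raise ValueError(f"no cells match {minus}")
        w[mm] -= 1.0 / mm.sum()
    return w


@dataclass
class ContrastTable:
    """EMM contrasts with raw and Holm-adjusted p-values."""

    table: pd.DataFrame  # label, estimate, se, z, p, p_holm

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def contrast_table(emms: EMMTable, named_weights: dict) -> ContrastTable:
    """Evaluate a family of contrasts and Holm-adjust their p-values jointly."""
    rows = []
    for label, w in named_weights.items():
        est, se, p = contrast(emms, w)
        z = est / se if se > 0 else np.nan
        rows.append({"label": label, "estimate": est, "se": se, "z": z, "p": p})
    df = pd.DataFrame(rows)
    df["p_holm"] = holm_bonferroni(df["p"].to_numpy())
    return ContrastTable(df)


def holm_bonferroni(p_values) -> np.ndarray:
    """Step-down Holm adjustment, returned in input order.

    Sorted ascending, p(i) is multiplied by (m - i), a running maximum is
    enforced, and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running = max(running, val)
        adj[idx] = running
    return adj


def questionnaire_select(
    scores: pd.DataFrame,
    outcome: pd.Series,
    r2_threshold: float = 0.10,
    max_vars: int = 3,
    sex_column: str = "sex",
) -> list:
    """Screen questionnaire scores by bivariate r^2 against a subject-level outcome.

    Retains scores with r^2 strictly above the threshold, keeps at most the
    ``max_vars`` highest, and always appends the sex column.  Constant
    columns are excluded with a warning.
    """
    candidates = [c for c in scores.columns if c != sex_column]
    r2 = {}
    y = np.asarray(outcome, dtype=float)
    for c in candidates:
        x = np.asarray(scores[c], dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            warnings.warn(f"constant column {c!r} excluded from screening")
            continue
        r = np.corrcoef(x[ok], y[ok])[0, 1]
        r2[c] = r * r
    passed = sorted(
        (c for c in r2 if r2[c] > r2_threshold), key=lambda c: r2[c], reverse=True
    )
    return passed[:max_vars] + [sex_column]


def between_person_variance_explained(
    predictors: pd.DataFrame, outcome: pd.Series
) -> float:
    """Multiple-regression R^2 on subject-level (one row per subject) data."""
    import statsmodels.api as sm

    X = np.asarray(predictors, dtype=float)
    y = np.asarray(outcome, dtype=float)
    ok = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    X, y = X[ok], y[ok]
    if len(y) <= X.shape[1] + 1:
        raise ValueError("not enough subjects for the number of predictors")
    res = sm.OLS(y, sm.add_constant(X)).fit()
    return float(res.rsquared)
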
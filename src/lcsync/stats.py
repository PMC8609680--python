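"""Inferential layer: partial correlations, group tests, stepwise regression.

Partial correlation is computed by double residualization — both variables
are regressed on an intercept plus the covariates and the Pearson correlation
of the residuals is taken, with the two-sided p value from
t = r sqrt(df / (1 - r^2)) on df = n - 2 - n_covariates.  The residual route
is preferred over precision-matrix inversion because the residuals themselves
are the quantities plotted in covariate-adjusted scatter diagrams.

Stepwise multiple linear regression uses forward selection with backward
elimination on partial-F p values (entry p <= 0.05, removal p > 0.10 by
default), reporting standardized coefficients.  ``run_cohort_analysis``
assembles the full result surface for a labeled cohort: group comparisons,
the covariate-adjusted correlation set, and the stepwise model of the
UPDRS-III response rate.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import PartialCorrResult, StepwiseResult
from .response import add_response_columns, split_by_response

__all__ = [
    "partial_correlation",
    "two_sample_t",
    "chi_square_2x2",
    "stepwise_regression",
    "run_cohort_analysis",
]


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | pd.DataFrame | None = None,
    covariate_names: list[str] | None = None,
) -> PartialCorrResult:
    """Partial correlation of x and y controlling for covariates.

    With an empty covariate set this reduces to the plain Pearson
    correlation.  Collinear covariate columns are dropped with a warning; the
    result is invariant under invertible affine transforms of the covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    n = x.size

    if covariates is None:
        cov = np.empty((n, 0))
        names: list[str] = []
    elif isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        cov = covariates.to_numpy(dtype=float)
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        names = covariate_names or [f"c{i}" for i in range(cov.shape[1])]
    if cov.shape[0] != n:
        raise ValueError("covariate rows must match x and y")

    # drop linearly dependent covariate columns (rank via pivoted QR diag)
    design = np.column_stack([np.ones(n), cov])
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = max(design.shape) * np.finfo(float).eps * diag.max()
    keep = diag > tol
    if not np.all(keep[1:]):
        dropped = [names[i] for i in range(len(names)) if not keep[i + 1]]
        warnings.warn(f"dropped collinear covariate column(s): {dropped}", stacklevel=2)
        names = [nm for nm, k in zip(names, keep[1:]) if k]
    qk = q[:, keep]

    rx = x - qk @ (qk.T @ x)
    ry = y - qk @ (qk.T @ y)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("constant residuals; partial correlation undefined")

    n_cov = len(names)
    df = n - 2 - n_cov
    if df < 1:
        raise ValueError("not enough observations for the covariate count")
    r_val = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    r_val = float(np.clip(r_val, -1.0, 1.0))
    if abs(r_val) == 1.0:
        p_val = 0.0
    else:
        t_stat = r_val * np.sqrt(df / (1.0 - r_val**2))
        p_val = float(2.0 * scipy.stats.t.sf(abs(t_stat), df))
    return PartialCorrResult(r=r_val, p=p_val, df=df, covariates=names)


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Pooled-variance two-sided two-sample t test; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 count table, df = 1, no continuity
    correction; returns (statistic, p)."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero marginal; chi-squared undefined")
    stat, p, _, _ = scipy.stats.chi2_contingency(tab, correction=False)
    return float(stat), float(p)


def _ols_pvalues(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS with intercept on standardized data; returns (betas, p values) for
    the non-intercept columns (coefficient t tests = partial F at 1 df)."""
    n = y.size
    design = np.column_stack([np.ones(n), x])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = n - design.shape[1]
    if dof <= 0:
        raise ValueError("not enough observations for the model size")
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.inf)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), dof)
    return coef[1:], p[1:]


def stepwise_regression(
    y: Sequence[float],
    candidates: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseResult:
    """Forward-selection / backward-elimination multiple linear regression.

    Variables (response and candidates) are standardized to unit variance, so
    reported betas are standardized coefficients.  At each step the candidate
    with the smallest partial-F p value enters if p <= p_enter; retained
    predictors with p > p_remove are then removed, worst first.  Terminates
    at a fixed point; a cycle or more than 2x the candidate count of
    iterations raises.
    """
    y = np.asarray(y, dtype=float)
    names = list(candidates.columns)
    if y.size <= len(names) + 2:
        raise ValueError("need n > candidate count + 2")
    ys = (y - y.mean()) / y.std(ddof=0)
    xs = {
        nm: (candidates[nm].to_numpy(dtype=float) - candidates[nm].mean())
        / candidates[nm].std(ddof=0)
        for nm in names
    }

    selected: list[str] = []
    steps: list[tuple[str, str, float]] = []
    seen_models = {frozenset()}
    max_iter = 2 * len(names)

    for _ in range(max_iter + 1):
        changed = False
        # forward step: best candidate by partial-F p value
        remaining = [nm for nm in names if nm not in selected]
        if remaining:
            best_name, best_p = None, np.inf
            for nm in remaining:
                trial = np.column_stack([xs[s] for s in selected + [nm]])
                _, pvals = _ols_pvalues(ys, trial)
                if pvals[-1] < best_p:
                    best_name, best_p = nm, pvals[-1]
            if best_name is not None and best_p <= p_enter:
                selected.append(best_name)
                steps.append(("enter", best_name, float(best_p)))
                changed = True
        # backward step: drop retained predictors above the removal threshold
        while selected:
            design = np.column_stack([xs[s] for s in selected])
            _, pvals = _ols_pvalues(ys, design)
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                steps.append(("remove", selected[worst], float(pvals[worst])))
                del selected[worst]
                changed = True
            else:
                break
        if not changed:
            break
        model = frozenset(selected)
        if model in seen_models and changed:
            raise RuntimeError("stepwise selection cycled without converging")
        seen_models.add(model)
    else:
        raise RuntimeError("stepwise selection did not converge")

    if selected:
        design = np.column_stack([xs[s] for s in selected])
        betas, pvals = _ols_pvalues(ys, design)
        beta_map = dict(zip(selected, map(float, betas)))
        p_map = dict(zip(selected, map(float, pvals)))
    else:
        beta_map, p_map = {}, {}
    return StepwiseResult(selected=list(selected), betas=beta_map, p_values=p_map, steps=steps)


#: covariate-adjusted correlation analyses of the cohort result surface:
#: (x, y, covariates)
COHORT_CORRELATIONS: list[tuple[str, str, tuple[str, ...]]] = [
    ("cnr_lc", "updrs3_off", ("age",)),
    ("cnr_lc", "updrs3_on", ("age",)),
    ("cnr_sn", "updrs3_off", ("age",)),
    ("cnr_sn", "updrs3_on", ("age",)),
    ("cnr_lc", "rate_updrs", ("age", "duration_med", "ledd")),
    ("cnr_sn", "rate_updrs", ("age", "duration_med", "ledd")),
    ("cnr_lc", "rate_sync", ("age", "duration_med", "ledd")),
    ("rate_updrs", "rate_sync", ("age", "duration_med", "ledd")),
]

#: continuous variables compared between response and resistance groups
GROUP_COMPARE_VARS = (
    "age",
    "duration_med",
    "ledd",
    "updrs3_off",
    "cnr_lc",
    "cnr_sn",
)

STEPWISE_CANDIDATES = ("cnr_lc", "cnr_sn", "age", "duration_med", "ledd")


def run_cohort_analysis(
    cohort: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> dict:
    """Full inferential report for a cohort table.

    Computes response rates and the median group split, compares groups
    (two-sample t per continuous variable, chi-squared for sex), runs the
    covariate-adjusted correlation set (CNR vs OFF/ON scores with age as
    covariate; CNR and rates of change with age, medication duration and
    LEDD as covariates), and the stepwise regression of the UPDRS-III rate
    on CNR_LC, CNR_SN, age, duration and LEDD.  No multiple-testing
    correction is applied; the report records the number of tests run.
    """
    required = {
        "age",
        "sex",
        "duration_med",
        "ledd",
        "cnr_lc",
        "cnr_sn",
        "updrs3_off",
        "updrs3_on",
        "sync_off",
        "sync_on",
    }
    missing = sorted(required - set(cohort.columns))
    if missing:
        raise ValueError(f"cohort is missing columns: {missing}")

    df = split_by_response(add_response_columns(cohort))
    resp = df[df["group"] == "response"]
    resist = df[df["group"] == "resistance"]

    group_comparison: dict[str, dict] = {}
    for var in GROUP_COMPARE_VARS:
        t, p = two_sample_t(resp[var], resist[var])
        group_comparison[var] = {"test": "t", "statistic": t, "p": p}
    sex_table = np.array(
        [
            [(resp["sex"] == 0).sum(), (resp["sex"] == 1).sum()],
            [(resist["sex"] == 0).sum(), (resist["sex"] == 1).sum()],
        ]
    )
    stat, p = chi_square_2x2(sex_table)
    group_comparison["sex"] = {"test": "chi2", "statistic": stat, "p": p}

    correlations = {}
    for x, y, covs in COHORT_CORRELATIONS:
        res = partial_correlation(df[x], df[y], df[list(covs)])
        correlations[f"{x}~{y}"] = {
            "r": res.r,
            "p": res.p,
            "df": res.df,
            "covariates": res.covariates,
        }

    sw = stepwise_regression(
        df["rate_updrs"], df[list(STEPWISE_CANDIDATES)], p_enter=p_enter, p_remove=p_remove
    )

    return {
        "n_subjects": int(len(df)),
        "group_sizes": {
            "response": int(len(resp)),
            "resistance": int(len(resist)),
        },
        "group_comparison": group_comparison,
        "correlations": correlations,
        "stepwise": {
            "selected": sw.selected,
            "betas": sw.betas,
            "p_values": sw.p_values,
            "steps": sw.steps,
        },
        "n_tests": len(group_comparison) + len(correlations),
    }
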
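"""Logistic-regression comparison arm: multiplicative interaction models,
separation and collinearity screening, and Firth bias-reduced fitting.

Each candidate interaction is assessed with the standard epidemiological
model — outcome on continuous age, the main effects of every component
variable, all lower-order products, and the highest-order product term:

    pairwise:   y ~ age + v1 + v2 + v1:v2
    three-way:  y ~ age + v1 + v2 + v3 + v1:v2 + v1:v3 + v2:v3 + v1:v2:v3

Ordinary maximum likelihood diverges under complete or quasi-complete
separation, which is common when interaction cells are sparse; designs
are therefore screened with a linear-programming separation check, and
sparse or separated models are fitted by Firth's bias-reduced logistic
regression (Jeffreys-prior penalised likelihood), whose estimates are
always finite.  Firth p-values are penalised likelihood-ratio tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import linprog
from scipy.special import expit
from scipy.stats import chi2

from .cohort import DiscreteCohort

__all__ = [
    "RegressionFit", "SeparationError", "build_design", "detect_separation",
    "collinearity_diagnostics", "fit_logistic", "firth_fit", "benchmark_models",
]

#: interaction cells with fewer observations than this trigger Firth fitting
SPARSE_CELL = 5
#: flag levels for collinearity diagnostics (annotations, never auto-drops)
VIF_FLAG = 10.0
CONDITION_FLAG = 30.0


class SeparationError(RuntimeError):
    """MLE requested on a separated design (estimates would diverge)."""


@dataclass
class RegressionFit:
    terms: list[str]
    coef: pd.Series
    odds_ratios: pd.Series
    pvalues: pd.Series
    method: str  # "MLE" | "Firth"
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(cohort: DiscreteCohort, model: Sequence[str],
                 adjust_age: bool = True) -> tuple[pd.DataFrame, dict]:
    """Design matrix for a multiplicative interaction model.

    Columns: intercept, (continuous) age, each main effect, every product
    of 2..k component variables.  Also reports the cell counts of the
    cross-classification of the component variables — the "bin sizes" that
    decide Firth dispatch.
    """
    model = list(model)
    if len(set(model)) != len(model):
        raise ValueError("duplicate variables in interaction model")
    df = cohort.data
    X = pd.DataFrame({"const": np.ones(len(df))})
    if adjust_age:
        if "age_years" not in df.columns:
            raise ValueError("cohort has no age_years column to adjust for")
        X["age_years"] = df["age_years"].to_numpy(dtype=float)
    for v in model:
        X[v] = df[v].to_numpy(dtype=float)
    for r in range(2, len(model) + 1):
        for combo in combinations(model, r):
            X[":".join(combo)] = np.prod([df[v].to_numpy(dtype=float) for v in combo], axis=0)
    codes = np.zeros(len(df), dtype=np.int64)
    for v in model:
        codes = codes * 2 + df[v].to_numpy(dtype=np.int64)
    cells = np.bincount(codes, minlength=2 ** len(model))
    diag = {"model": model,
            "interaction_term": ":".join(model),
            "cell_counts": {format(i, f"0{len(model)}b"): int(c) for i, c in enumerate(cells)},
            "min_cell": int(cells.min())}
    return X, diag


# ---------------------------------------------------------------------------
# screening diagnostics
# ---------------------------------------------------------------------------

def detect_separation(X: pd.DataFrame | np.ndarray, y: Sequence[int],
                      tol: float = 1e-9) -> str:
    """Classify a design as 'none', 'quasi' or 'complete' separation.

    Solves two small linear programmes over coefficient vectors ``b`` with
    ``|b_j| <= 1``: complete separation exists iff the worst-case margin
    ``min_i s_i x_i'b`` (``s_i = 2y_i - 1``) can be made strictly positive;
    quasi-separation iff margins can be nonnegative with positive sum.
    """
    A = np.asarray(X, dtype=float)
    s = 2.0 * np.asarray(y, dtype=float) - 1.0
    M = A * s[:, None]  # rows: s_i * x_i
    n, p = M.shape
    # --- complete: maximise t s.t. M b >= t, |b| <= 1, 0 <= t <= 1
    c_obj = np.zeros(p + 1)
    c_obj[-1] = -1.0
    A_ub = np.hstack([-M, np.ones((n, 1))])
    b_ub = np.zeros(n)
    bounds = [(-1.0, 1.0)] * p + [(0.0, 1.0)]
    res = linprog(c_obj, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if res.status == 0 and -res.fun > tol:
        return "complete"
    # --- quasi: maximise sum(M b) s.t. M b >= 0, |b| <= 1
    res = linprog(-M.sum(axis=0), A_ub=-M, b_ub=np.zeros(n),
                  bounds=[(-1.0, 1.0)] * p, method="highs")
    if res.status == 0 and -res.fun > tol:
        return "quasi"
    return "none"


def collinearity_diagnostics(X: pd.DataFrame) -> dict:
    """Per-column VIFs and the condition number of the non-constant block.

    Exactly collinear columns yield an infinite VIF, reported as a flag
    rather than an exception.
    """
    cols = [c for c in X.columns if c != "const"]
    if len(cols) < 2:
        raise ValueError("need at least 2 non-intercept columns")
    A = X[cols].to_numpy(dtype=float)
    vifs: dict[str, float] = {}
    for j, name in enumerate(cols):
        target = A[:, j]
        others = np.column_stack([np.ones(len(A)), np.delete(A, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        ss_tot = ((target - target.mean()) ** 2).sum()
        ss_res = (resid ** 2).sum()
        if ss_tot <= 0 or ss_res / max(ss_tot, 1e-300) < 1e-12:
            vifs[name] = float("inf")
        else:
            vifs[name] = float(1.0 / (ss_res / ss_tot))
    std = A.std(axis=0)
    std[std == 0] = 1.0
    cond = float(np.linalg.cond(np.column_stack([np.ones(len(A)), (A - A.mean(0)) / std])))
    max_vif = max(vifs.values())
    return {"vif": vifs, "max_vif": max_vif, "condition_number": cond,
            "collinearity_flag": (not np.isfinite(max_vif)) or max_vif > VIF_FLAG
                                 or cond > CONDITION_FLAG}


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = expit(eta)
    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_fit(X: pd.DataFrame | np.ndarray, y: Sequence[int],
              fixed_zero: Sequence[int] = (), max_iter: int = 50,
              tol: float = 1e-8) -> tuple[np.ndarray, float, bool]:
    """Firth bias-reduced logistic fit by Newton iteration with step-halving.

    The score is modified by the Jeffreys-prior term,
    ``U*(b) = X'(y - p + h (1/2 - p))`` with ``h`` the hat diagonal of the
    weighted design; coefficients listed in ``fixed_zero`` are constrained
    to 0 (used for penalised likelihood-ratio tests).  Returns
    ``(beta, penalised log-likelihood, converged)``.
    """
    A = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = A.shape
    free = np.array([j for j in range(p) if j not in set(fixed_zero)])
    beta = np.zeros(p)
    ll_old = _penalized_loglik(A, y, beta)
    converged = False
    for _ in range(max_iter):
        prob = expit(A @ beta)
        w = prob * (1.0 - prob)
        info = A.T @ (A * w[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", A, info_inv, A) * w
        score = A.T @ (y - prob + h * (0.5 - prob))
        sub_info = info[np.ix_(free, free)]
        try:
            step_free = np.linalg.solve(sub_info, score[free])
        except np.linalg.LinAlgError:
            step_free = np.linalg.lstsq(sub_info, score[free], rcond=None)[0]
        step = np.zeros(p)
        step[free] = step_free
        # step-halving on the penalised likelihood
        factor = 1.0
        for _half in range(25):
            cand = beta + factor * step
            ll_new = _penalized_loglik(A, y, cand)
            if ll_new >= ll_old - 1e-12:
                break
            factor *= 0.5
        beta = beta + factor * step
        improve = ll_new - ll_old
        ll_old = ll_new
        if np.max(np.abs(factor * step)) < tol and abs(improve) < tol:
            converged = True
            break
    return beta, ll_old, converged


def _firth_lrt_pvalues(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                       ll_full: float) -> np.ndarray:
    """Penalised likelihood-ratio p per coefficient (profile at beta_j = 0)."""
    pvals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        _, ll0, _ = firth_fit(X, y, fixed_zero=(j,))
        stat = max(2.0 * (ll_full - ll0), 0.0)
        pvals[j] = chi2.sf(stat, df=1)
    return pvals


def fit_logistic(X: pd.DataFrame, y: Sequence[int], method: str = "auto",
                 design_diag: Optional[dict] = None) -> RegressionFit:
    """Fit a logistic model by MLE or Firth penalised likelihood.

    ``auto`` dispatches to Firth when any interaction cell count is below
    5 (requires ``design_diag`` from :func:`build_design`) or when the
    design is separated; MLE on a separated design raises
    :class:`SeparationError` (such models are reported as not assessable).
    """
    if method not in ("MLE", "Firth", "auto"):
        raise ValueError("method must be 'MLE', 'Firth' or 'auto'")
    y = np.asarray(y, dtype=float)
    sep = detect_separation(X, y)
    diagnostics = {"separation": sep}
    if design_diag:
        diagnostics.update(design_diag)
    if X.shape[1] > 2:
        diagnostics.update(collinearity_diagnostics(X))
    if method == "auto":
        sparse = bool(design_diag and design_diag.get("min_cell", SPARSE_CELL) < SPARSE_CELL)
        method = "Firth" if (sparse or sep != "none") else "MLE"
    terms = list(X.columns)
    if method == "MLE":
        if sep != "none":
            raise SeparationError(
                f"{sep} separation detected; maximum-likelihood estimates diverge")
        res = sm.Logit(y, X.astype(float)).fit(disp=0, maxiter=200)
        coef = pd.Series(res.params, index=terms)
        pvals = pd.Series(res.pvalues, index=terms)
        converged = bool(res.mle_retvals.get("converged", False))
        diagnostics["inference"] = "Wald"
    else:
        A = X.to_numpy(dtype=float)
        beta, ll_full, converged = firth_fit(A, y)
        coef = pd.Series(beta, index=terms)
        pvals = pd.Series(_firth_lrt_pvalues(A, y, beta, ll_full), index=terms)
        diagnostics["inference"] = "penalized-LRT"
    return RegressionFit(terms=terms, coef=coef, odds_ratios=np.exp(coef),
                         pvalues=pvals, method=method, diagnostics=diagnostics,
                         converged=converged)


# ---------------------------------------------------------------------------
# benchmark against the entropy screen
# ---------------------------------------------------------------------------

def benchmark_models(cohort: DiscreteCohort, models: Sequence[Sequence[str]],
                     adjust_age: bool = True) -> pd.DataFrame:
    """Regression assessment of screen-selected interaction models.

    For each model the highest-order product term's odds ratio and p-value
    are reported together with the fit method.  Models whose design is
    separated or exactly collinear are reported as not assessable with the
    reason, mirroring the "---" entries of printed comparison tables;
    otherwise sparse interaction cells (< 5) dispatch to Firth.
    """
    if len(models) == 0:
        raise ValueError("no models to benchmark")
    y = cohort.outcome
    rows = []
    for model in models:
        model = list(model)
        X, diag = build_design(cohort, model, adjust_age=adjust_age)
        term = diag["interaction_term"]
        sep = detect_separation(X, y)
        coll = collinearity_diagnostics(X)
        row = {"variables": " x ".join(model), "order": len(model),
               "interaction_term": term, "min_cell": diag["min_cell"],
               "separation": sep,
               "collinearity_flag": bool(coll["collinearity_flag"])}
        exact_collinear = not np.isfinite(coll["max_vif"])
        if sep != "none" or exact_collinear:
            reasons = [r for r, hit in (("separation", sep != "none"),
                                        ("collinearity", exact_collinear)) if hit]
            row.update({"odds_ratio": np.nan, "p_value": np.nan, "method": "",
                        "assessable": False, "reason": "/".join(reasons)})
        else:
            method = "Firth" if diag["min_cell"] < SPARSE_CELL else "MLE"
            fit = fit_logistic(X, y, method=method, design_diag=diag)
            row.update({"odds_ratio": float(fit.odds_ratios[term]),
                        "p_value": float(fit.pvalues[term]),
                        "method": fit.method,
                        "assessable": bool(fit.converged),
                        "reason": "" if fit.converged else "non-convergence"})
        rows.append(row)
    return pd.DataFrame(rows)
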
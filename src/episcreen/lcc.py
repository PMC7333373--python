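"""Local case-control (LCC) subsampling for confounder adjustment.

A pilot logistic model of the outcome on the confounders alone (here,
age) is fitted by maximum likelihood; each observation is then kept
independently with probability ``|y - p_tilde|``, the absolute difference
between its outcome and the pilot's fitted probability.  Rows the pilot
predicts well are rarely kept, so the confounder's effect on the outcome
is cancelled in the subsample, which can then be analysed by methods that
cannot adjust for covariates directly.  One Bernoulli draw is made per
run; the subsample size is a random variable with expectation
``sum |y_i - p_tilde_i|``, not a target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import DiscreteCohort

__all__ = ["SubsampleDraw", "fit_pilot", "lcc_subsample", "check_balance"]

#: subsamples smaller than this raise a reliability flag in diagnostics
SMALL_SUBSAMPLE = 20


@dataclass
class SubsampleDraw:
    """One LCC acceptance draw and its diagnostics."""

    pilot_coef: dict[str, float]
    accept_prob: np.ndarray
    kept_index: np.ndarray
    seed: int
    cohort: DiscreteCohort
    balance: dict = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return len(self.kept_index)

    def report(self) -> dict:
        return {"pilot_coef": self.pilot_coef, "seed": self.seed,
                "n_input": len(self.accept_prob), "n_kept": self.n_kept,
                "expected_kept": float(self.accept_prob.sum()),
                "balance": self.balance}


def _design(confounders: pd.DataFrame) -> pd.DataFrame:
    X = sm.add_constant(confounders.astype(float), has_constant="add")
    return X


def fit_pilot(outcome: Sequence[int], confounders: pd.DataFrame) -> dict[str, float]:
    """Maximum-likelihood logistic fit of the outcome on confounders only.

    Returns named coefficients (log-odds); raises on a constant outcome or
    non-convergence.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; pilot model cannot be fitted")
    X = _design(confounders)
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(f"pilot logistic fit did not converge: {res.mle_retvals}")
    return {name: float(v) for name, v in res.params.items()}


def _pilot_probs(pilot: dict[str, float], confounders: pd.DataFrame) -> np.ndarray:
    X = _design(confounders)
    beta = np.array([pilot[c] for c in X.columns])
    from scipy.special import expit
    return expit(X.to_numpy() @ beta)


def lcc_subsample(cohort: DiscreteCohort, pilot: Optional[dict[str, float]] = None,
                  confounders: Sequence[str] = ("age_years",), seed: int = 0,
                  ) -> SubsampleDraw:
    """Draw an LCC subsample keeping each row with probability ``|y - p~|``.

    ``pilot`` defaults to a fresh fit on the cohort itself.  The returned
    draw carries the subsample as a new cohort plus a balance diagnostic
    (post-subsample confounder slope, its SE and Wald p).
    """
    conf = cohort.data[list(confounders)]
    y = cohort.outcome.astype(float)
    if pilot is None:
        pilot = fit_pilot(y, conf)
    p_tilde = _pilot_probs(pilot, conf)
    accept = np.abs(y - p_tilde)
    assert (accept >= 0).all() and (accept <= 1).all()
    rng = np.random.default_rng(seed)
    kept = np.flatnonzero(rng.random(len(accept)) < accept)
    sub = cohort.subset(kept, lcc_seed=seed)
    draw = SubsampleDraw(pilot_coef=pilot, accept_prob=accept, kept_index=kept,
                         seed=seed, cohort=sub)
    if len(kept) > 0:
        try:
            draw.balance = check_balance(sub, confounders)
        except (RuntimeError, ValueError) as exc:  # e.g. constant outcome in subsample
            draw.balance = {"error": str(exc)}
    return draw


def check_balance(subsample: DiscreteCohort, confounders: Sequence[str] = ("age_years",),
                  ) -> dict:
    """Refit outcome ~ confounders on the subsample and report the slopes.

    After a successful LCC draw the confounder coefficients should be
    statistically indistinguishable from zero.  Subsamples smaller than
    ``SMALL_SUBSAMPLE`` are flagged as unreliable.
    """
    if len(subsample) == 0:
        raise ValueError("subsample is empty; no balance diagnostic possible")
    conf = subsample.data[list(confounders)]
    y = subsample.outcome.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("subsample outcome is constant")
    X = _design(conf)
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    out = {"slopes": {}, "small_subsample": len(subsample) < SMALL_SUBSAMPLE,
           "n": len(subsample)}
    for name in conf.columns:
        out["slopes"][name] = {"estimate": float(res.params[name]),
                               "se": float(res.bse[name]),
                               "wald_p": float(res.pvalues[name])}
    return out
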
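"""Permutation null distributions, p-values and Bonferroni verdicts.

Inference is one-sided on the synergy direction: the permutation p-value
counts null statistics at least as large as the observed one, using the
add-one estimator ``(1 + #{null >= obs}) / (B + 1)`` so the smallest
attainable p at B = 1000 is 1/1001 (reported in tables as 0.001).
One shared permutation set (a fixed reshuffling of the outcome vector)
is used for every model within a testing family, which removes
between-model Monte-Carlo noise from the ranking.

Main effects (8 models), pairwise interactions (28) and three-way
interactions (56) form three separate Bonferroni families; with 8
predictors the familywise 0.05/0.10 critical values round to the printed
thresholds 0.006, 0.002/0.004 and 0.0009/0.002 respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import DiscreteCohort
from .entropy import _entropy_rows

_LN2 = float(np.log(2.0))

__all__ = [
    "PermutationNull", "SignificanceVerdict", "enumerate_models",
    "permute_outcomes", "permutation_pvalue", "bonferroni_class",
    "printed_threshold", "run_screen",
]


@dataclass
class PermutationNull:
    """Null statistic values for one model under outcome reshuffling."""

    model: tuple[str, ...]
    basis: str
    B: int
    values: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.B:
            raise ValueError("null must contain exactly B values")


@dataclass(frozen=True)
class SignificanceVerdict:
    p: float
    m: int
    label: str  # "significant" | "suggestive" | "null"
    threshold_significant: float
    threshold_suggestive: float
    printed_significant: float
    printed_suggestive: float


def enumerate_models(variables: Sequence[str], order: int) -> list[tuple[str, ...]]:
    """All unordered predictor subsets of the given order (2 or 3)."""
    if order not in (2, 3):
        raise ValueError("interaction order must be 2 or 3")
    if len(variables) < order:
        raise ValueError("need at least `order` variables")
    return list(combinations(variables, order))


def permute_outcomes(c: Sequence[int], B: int, seed: int) -> np.ndarray:
    """B independent uniform reshufflings of the outcome vector, as a
    (B, n) array.  Reproducible under ``seed``; the same set is reused for
    every model in a family."""
    if B < 1:
        raise ValueError("need at least one permutation")
    c = np.asarray(c, dtype=np.int64)
    rng = np.random.default_rng(seed)
    perms = np.empty((B, len(c)), dtype=np.int64)
    for b in range(B):
        perms[b] = rng.permutation(c)
    return perms


def permutation_pvalue(observed: float, null_values: Sequence[float]) -> float:
    """Add-one one-sided permutation p: ``(1 + #{null >= obs}) / (B + 1)``."""
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("empty permutation null")
    return float((1 + (null >= observed).sum()) / (null.size + 1))


def printed_threshold(x: float) -> float:
    """Round a Bonferroni critical value to one significant figure, the
    convention used when quoting thresholds such as 0.002 or 0.0009."""
    if x <= 0:
        return 0.0
    exp = int(np.floor(np.log10(abs(x))))
    return float(round(x, -exp))


def bonferroni_class(p: float, m: int, fwer_sig: float = 0.05,
                     fwer_sug: float = 0.1) -> SignificanceVerdict:
    """Classify an unadjusted permutation p against Bonferroni critical
    values ``fwer/m`` for significant and suggestive association."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    t_sig, t_sug = fwer_sig / m, fwer_sug / m
    if p <= t_sig:
        label = "significant"
    elif p <= t_sug:
        label = "suggestive"
    else:
        label = "null"
    return SignificanceVerdict(p=p, m=m, label=label,
                               threshold_significant=t_sig, threshold_suggestive=t_sug,
                               printed_significant=printed_threshold(t_sig),
                               printed_suggestive=printed_threshold(t_sug))


# ---------------------------------------------------------------------------
# vectorised screening engine
# ---------------------------------------------------------------------------

def _perm_joint_entropy(codes: np.ndarray, n_cells: int, perms: np.ndarray) -> np.ndarray:
    """H(cell, class) under each permuted outcome; shape (B,).

    ``codes`` maps each row to a cell 0..n_cells-1; counts are accumulated
    for all permutations at once with a single bincount.
    """
    B = perms.shape[0]
    width = 2 * n_cells
    flat = codes[None, :] * 2 + perms + (np.arange(B)[:, None] * width)
    counts = np.bincount(flat.ravel(), minlength=B * width).reshape(B, width)
    return _entropy_rows(counts)


def _observed_joint_entropy(codes: np.ndarray, n_cells: int, c: np.ndarray) -> float:
    counts = np.bincount(codes * 2 + c, minlength=2 * n_cells)
    return float(_entropy_rows(counts[None, :])[0])


def _cell_entropy(codes: np.ndarray, n_cells: int) -> float:
    return float(_entropy_rows(np.bincount(codes, minlength=n_cells)[None, :])[0])


class _ScreenEngine:
    """Shared computation of MI / IG2 / IG3 statistics and their nulls."""

    def __init__(self, X: np.ndarray, names: Sequence[str], c: np.ndarray,
                 perms: np.ndarray, clamp_synergy: bool = True):
        self.X, self.names, self.c, self.perms = X, list(names), c, perms
        self.clamp = clamp_synergy
        self.h_class = _cell_entropy(c, 2)
        self._codes: dict[tuple[str, ...], tuple[np.ndarray, int]] = {}
        self._mi_obs: dict[tuple[str, ...], float] = {}
        self._mi_null: dict[tuple[str, ...], np.ndarray] = {}

    def codes_for(self, model: tuple[str, ...]) -> tuple[np.ndarray, int]:
        if model not in self._codes:
            idx = [self.names.index(v) for v in model]
            codes = np.zeros(self.X.shape[0], dtype=np.int64)
            for j in idx:
                codes = codes * 2 + self.X[:, j]
            self._codes[model] = (codes, 2 ** len(model))
        return self._codes[model]

    def mi(self, model: tuple[str, ...]) -> tuple[float, np.ndarray]:
        """Joint MI of a variable subset with the class: observed + null."""
        if model not in self._mi_obs:
            codes, k = self.codes_for(model)
            h_cells = _cell_entropy(codes, k)
            self._mi_obs[model] = h_cells + self.h_class - \
                _observed_joint_entropy(codes, k, self.c)
            self._mi_null[model] = h_cells + self.h_class - \
                _perm_joint_entropy(codes, k, self.perms)
        return self._mi_obs[model], self._mi_null[model]

    def ig2(self, pair: tuple[str, str]) -> tuple[float, np.ndarray]:
        mi12, mi12_null = self.mi(pair)
        out_obs, out_null = mi12, mi12_null.copy()
        for v in pair:
            mi, mi_null = self.mi((v,))
            out_obs -= mi
            out_null -= mi_null
        return out_obs, out_null

    def ig3(self, triple: tuple[str, str, str]) -> tuple[float, np.ndarray]:
        mi123, mi123_null = self.mi(triple)
        out_obs, out_null = mi123, mi123_null.copy()
        for pair in combinations(triple, 2):
            ig, ig_null = self.ig2(pair)
            if self.clamp:
                ig, ig_null = max(ig, 0.0), np.maximum(ig_null, 0.0)
            out_obs -= ig
            out_null -= ig_null
        for v in triple:
            mi, mi_null = self.mi((v,))
            out_obs -= mi
            out_null -= mi_null
        return out_obs, out_null


def pairwise_ig_test(x1: Sequence[int], x2: Sequence[int], c: Sequence[int],
                     B: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Permutation test of a single pairwise interaction.

    Returns ``(IG in bits, one-sided permutation p)``; a convenience for
    single-model designs such as calibration and power studies.
    """
    X = np.column_stack([np.asarray(x1, dtype=np.int64), np.asarray(x2, dtype=np.int64)])
    c = np.asarray(c, dtype=np.int64)
    perms = permute_outcomes(c, B, seed)
    engine = _ScreenEngine(X, ["x1", "x2"], c, perms)
    obs, null = engine.ig2(("x1", "x2"))
    return float(obs), permutation_pvalue(obs, null)


def run_screen(cohort: DiscreteCohort, order: int, B: int = 1000, seed: int = 0,
               fwer_sig: float = 0.05, fwer_sug: float = 0.1,
               clamp_synergy: bool = True,
               predictors: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Screen every model of the given order (1 = main-effect MI,
    2 = pairwise IG, 3 = three-way IG) with shared-permutation inference.

    Returns a tidy table with one row per model: variables, order, the
    statistic in bits and as % of class entropy, the unadjusted permutation
    p-value, the family size m, the Bonferroni verdict and its critical
    values, plus B, seed and n for reproducibility.  Constant predictors
    are excluded with a warning; a constant outcome is an error.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    names = [p for p in (predictors or cohort.predictors)]
    degenerate = [p for p in names if cohort.data[p].nunique() < 2]
    if degenerate:
        warnings.warn(f"excluding constant predictors from screen: {degenerate}")
        names = [p for p in names if p not in degenerate]
    c = cohort.outcome
    if len(np.unique(c)) < 2:
        raise ValueError("outcome is constant; screening is undefined")
    X = cohort.predictor_matrix(names)
    perms = permute_outcomes(c, B, seed)
    engine = _ScreenEngine(X, names, c, perms, clamp_synergy=clamp_synergy)

    if order == 1:
        models = [(v,) for v in names]
        stats = [engine.mi(m) for m in models]
        basis = "MI"
    elif order == 2:
        models = enumerate_models(names, 2)
        stats = [engine.ig2(m) for m in models]
        basis = "IG2"
    else:
        models = enumerate_models(names, 3)
        stats = [engine.ig3(m) for m in models]
        basis = "IG3"

    m_tests = len(models)
    rows = []
    for model, (obs, null) in zip(models, stats):
        p = permutation_pvalue(obs, null)
        verdict = bonferroni_class(p, m_tests, fwer_sig, fwer_sug)
        rows.append({
            "variables": " x ".join(model),
            "order": order,
            "basis": basis,
            "bits": obs,
            "pct": 100.0 * obs / engine.h_class,
            "p_value": p,
            "m": m_tests,
            "significance": verdict.label,
            "threshold_significant": verdict.threshold_significant,
            "threshold_suggestive": verdict.threshold_suggestive,
            "B": B,
            "seed": seed,
            "n": len(c),
        })
    df = pd.DataFrame(rows)
    return df.sort_values(["p_value", "bits"], ascending=[True, False],
                          kind="mergesort").reset_index(drop=True)
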
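"""Shannon entropy, mutual information, and information-gain interaction statistics.

All quantities are measured in bits (log base 2) so that, for a binary
class variable ``C``, main-effect mutual information lies in ``[0, H(C)]``
and pairwise/three-way information gain lies in ``[-H(C), H(C)]`` with
``H(C) <= 1``.  Positive information gain indicates synergy (the variables
jointly carry information about the class beyond their lower-order
contributions); negative values indicate redundancy.

Estimation is plug-in (maximum likelihood) from observed cell frequencies;
no small-sample bias correction is applied because downstream inference is
by permutation, which places the same estimator bias in the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.special import xlogy

_LN2 = float(np.log(2.0))

__all__ = [
    "InformationValue",
    "entropy",
    "mutual_information",
    "joint_mutual_information",
    "information_gain_pairwise",
    "information_gain_threeway",
    "to_percent",
    "ig_pairwise_from_table",
    "ig_threeway_from_table",
]


@dataclass(frozen=True)
class InformationValue:
    """An information statistic for a set of predictors against the class.

    ``pct`` is the statistic normalised by the class entropy,
    ``100 * bits / H(C)`` ("% of class entropy explained"); it is ``None``
    when the class is degenerate (``H(C) = 0``).  Raw bits are always
    carried alongside because the percent normalisation is a reporting
    convention, not part of the statistic.
    """

    bits: float
    pct: Optional[float]
    basis: str  # "MI" | "IG2" | "IG3"
    variables: tuple[str, ...]
    n: int


# ---------------------------------------------------------------------------
# entropy primitives
# ---------------------------------------------------------------------------

def entropy(counts: Sequence[float]) -> float:
    """Shannon entropy, in bits, of a discrete distribution given by counts.

    ``0 * log 0`` is taken as 0.  Raises on an empty/all-zero table.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or np.any(c < 0):
        raise ValueError("counts must be a nonempty array of nonnegative numbers")
    total = c.sum()
    if total <= 0:
        raise ValueError("cannot compute entropy of an all-zero count table")
    p = c / total
    return float(-xlogy(p, p).sum() / _LN2)


def _entropy_rows(counts: np.ndarray) -> np.ndarray:
    """Entropy in bits of each row of a 2-D count array (0 for empty rows)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, counts / np.where(total > 0, total, 1.0), 0.0)
    return -xlogy(p, p).sum(axis=-1) / _LN2


# ---------------------------------------------------------------------------
# table-based interaction statistics (vectorised over leading batch axes)
# ---------------------------------------------------------------------------

def _mi_table(table: np.ndarray) -> np.ndarray:
    """MI between the first grouped axis (-2) and the last axis of a joint
    count table of shape ``batch + (K, L)``."""
    t = np.asarray(table, dtype=float)
    batch = t.shape[:-2]
    h_joint = _entropy_rows(t.reshape(batch + (-1,)))
    h_x = _entropy_rows(t.sum(axis=-1))
    h_c = _entropy_rows(t.sum(axis=-2))
    return h_x + h_c - h_joint


def ig_pairwise_from_table(table: np.ndarray) -> np.ndarray:
    """Pairwise information gain from a joint count table shaped
    ``batch + (2, 2, 2)`` with axes (x1, x2, class).

    ``IG2 = MI({x1,x2}; C) - MI(x1; C) - MI(x2; C)``.
    """
    t = np.asarray(table, dtype=float)
    batch = t.shape[:-3]
    mi_joint = _mi_table(t.reshape(batch + (4, 2)))
    mi1 = _mi_table(t.sum(axis=-2))
    mi2 = _mi_table(t.sum(axis=-3))
    return mi_joint - mi1 - mi2


def ig_threeway_from_table(table: np.ndarray, clamp_synergy: bool = True) -> np.ndarray:
    """Three-way information gain from a table shaped ``batch + (2, 2, 2, 2)``
    with axes (x1, x2, x3, class).

    ``IG3 = MI({x1,x2,x3}; C) - sum_pairs f(IG2) - sum_i MI(xi; C)`` where
    ``f`` is ``max(., 0)`` under the synergy-only subtraction rule
    (``clamp_synergy=True``, the default) or the identity otherwise.
    """
    t = np.asarray(table, dtype=float)
    batch = t.shape[:-4]
    mi_joint = _mi_table(t.reshape(batch + (8, 2)))
    # single-variable marginal tables: sum out the other two predictor axes
    mis = [
        _mi_table(t.sum(axis=(-3, -2))),  # x1
        _mi_table(t.sum(axis=(-4, -2))),  # x2
        _mi_table(t.sum(axis=(-4, -3))),  # x3
    ]
    pair_tables = [t.sum(axis=-2), t.sum(axis=-3), t.sum(axis=-4)]  # (1,2),(1,3),(2,3)
    igs = [ig_pairwise_from_table(pt) for pt in pair_tables]
    if clamp_synergy:
        igs = [np.maximum(ig, 0.0) for ig in igs]
    return mi_joint - sum(igs) - sum(mis)


# ---------------------------------------------------------------------------
# sequence-based public API
# ---------------------------------------------------------------------------

def _as_codes(x: Sequence[int]) -> tuple[np.ndarray, int]:
    """Encode a discrete sequence as integer codes 0..K-1."""
    arr = np.asarray(x)
    codes, inv = np.unique(arr, return_inverse=True)
    return inv.astype(np.int64), len(codes)


def _check_lengths(*seqs: Sequence[int]) -> int:
    lengths = {len(np.asarray(s)) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have mismatched lengths: {sorted(lengths)}")
    (n,) = lengths
    if n == 0:
        raise ValueError("sequences are empty")
    return n


def _joint_table(vars_codes: list[tuple[np.ndarray, int]], c: np.ndarray) -> np.ndarray:
    """Joint count table over (var cells ..., class)."""
    dims = [k for _, k in vars_codes] + [2]
    flat = np.zeros(1, dtype=np.int64)
    for codes, k in vars_codes:
        flat = flat * k + codes
    flat = flat * 2 + c
    return np.bincount(flat, minlength=int(np.prod(dims))).reshape(dims).astype(float)


def _class_codes(c: Sequence[int]) -> np.ndarray:
    arr = np.asarray(c)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("class sequence must be binary (0/1)")
    return arr.astype(np.int64)


def mutual_information(x: Sequence[int], c: Sequence[int],
                       variables: tuple[str, ...] = ("x",)) -> InformationValue:
    """Plug-in mutual information MI(X; C) in bits.

    Symmetric in its arguments; nonnegative up to float round-off.
    """
    n = _check_lengths(x, c)
    xc, kx = _as_codes(x)
    cc, kc = _as_codes(c)
    table = np.bincount(xc * kc + cc, minlength=kx * kc).reshape(kx, kc).astype(float)
    bits = float(_mi_table(table))
    h_c = entropy(table.sum(axis=0))
    pct = to_percent(bits, h_c) if h_c > 0 else None
    return InformationValue(bits=bits, pct=pct, basis="MI", variables=tuple(variables), n=n)


def joint_mutual_information(variables: Sequence[Sequence[int]], c: Sequence[int]) -> float:
    """MI of the Cartesian product of 1-3 discrete variables with ``c``, in bits."""
    if not 1 <= len(variables) <= 3:
        raise ValueError("joint MI supports 1 to 3 variables")
    n = _check_lengths(*variables, c)
    cc = _class_codes(c)
    codes = [_as_codes(v) for v in variables]
    table = _joint_table(codes, cc)
    return float(_mi_table(table.reshape(-1, 2)))


def information_gain_pairwise(x1: Sequence[int], x2: Sequence[int], c: Sequence[int],
                              variables: tuple[str, str] = ("x1", "x2")) -> InformationValue:
    """Pairwise information gain IG(x1; x2; C) in bits (synergy > 0)."""
    n = _check_lengths(x1, x2, c)
    cc = _class_codes(c)
    h_c = _entropy_rows(np.bincount(cc, minlength=2)[None, :])[0]
    if h_c <= 0:
        raise ValueError("class is constant: H(C) = 0, information gain undefined")
    table = _binary_joint(x1, x2, c=cc)
    bits = float(ig_pairwise_from_table(table))
    return InformationValue(bits=bits, pct=to_percent(bits, h_c), basis="IG2",
                            variables=tuple(variables), n=n)


def information_gain_threeway(x1: Sequence[int], x2: Sequence[int], x3: Sequence[int],
                              c: Sequence[int], clamp_synergy: bool = True,
                              variables: tuple[str, str, str] = ("x1", "x2", "x3"),
                              ) -> InformationValue:
    """Three-way information gain with synergy-only subtraction of pairwise terms.

    With ``clamp_synergy=False`` all pairwise IG terms are subtracted as-is
    (including redundant, negative ones).  The default removes only positive
    (synergistic) pairwise terms, which keeps the statistic meaningful when
    predictors are strongly correlated with one another.
    """
    n = _check_lengths(x1, x2, x3, c)
    cc = _class_codes(c)
    h_c = _entropy_rows(np.bincount(cc, minlength=2)[None, :])[0]
    if h_c <= 0:
        raise ValueError("class is constant: H(C) = 0, information gain undefined")
    table = _binary_joint(x1, x2, x3, c=cc)
    bits = float(ig_threeway_from_table(table, clamp_synergy=clamp_synergy))
    return InformationValue(bits=bits, pct=to_percent(bits, h_c), basis="IG3",
                            variables=tuple(variables), n=n)


def _binary_joint(*xs: Sequence[int], c: np.ndarray) -> np.ndarray:
    """Joint count table over binary predictors and the binary class."""
    codes = []
    for x in xs:
        arr = np.asarray(x)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("predictor sequences must be binary (0/1)")
        codes.append(arr.astype(np.int64))
    flat = np.zeros(len(c), dtype=np.int64)
    for code in codes:
        flat = flat * 2 + code
    flat = flat * 2 + c
    k = 2 ** (len(codes) + 1)
    return np.bincount(flat, minlength=k).reshape((2,) * (len(codes) + 1)).astype(float)


def to_percent(bits: float, class_entropy: float) -> float:
    """Express an information statistic as a percentage of the class entropy."""
    if class_entropy <= 0:
        raise ValueError("class entropy must be positive to form a percentage")
    return 100.0 * bits / class_entropy


def pairwise_subsets(names: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered predictor pairs, in lexicographic input order."""
    return list(combinations(names, 2))
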
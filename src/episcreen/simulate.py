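"""Synthetic case-control cohorts with embeddable pure epistasis.

The generator emulates the statistical structure the screening pipeline
assumes: eight binary predictors at the study's marginal frequencies, a
continuous age confounder acting on the outcome, and penetrance-table
interactions among 2-3 predictors whose marginal effects can be made
exactly zero ("pure" epistasis).  Defaults reproduce the study conditions:
n = 617 before confounder adjustment, predictor prevalences taken from the
post-adjustment demographic table (n = 233), age truncated-normal
(mean 14, SD 3) on [8, 21] years, and an age -> outcome coefficient of
0.45 log-odds/yr calibrated so that local case-control subsampling
contracts n = 617 to approximately 233.

:func:`population_ig` computes information gain analytically from the
exact joint distribution and serves as the brute-force oracle for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .cohort import PREDICTORS, BDR_RESPONDER_THRESHOLD, DiscreteCohort
from .entropy import ig_pairwise_from_table, ig_threeway_from_table

#: marginal predictor frequencies of the adjusted study sample (n = 233)
TABLE1_PREVALENCES: dict[str, float] = {
    "sex": 97 / 233,        # female
    "age_hi": 0.5,          # median split
    "afr_hi": 149 / 233,
    "bmi_obese": 86 / 233,
    "eod_any": 114 / 233,
    "pse": 40 / 233,
    "ses_low": 79 / 233,
    "no2_hi": 116 / 233,
}

#: responder fraction of the adjusted study sample (118 / 233)
BASELINE_PREVALENCE = 118 / 233


@dataclass(frozen=True)
class PenetranceSpec:
    """P(outcome = 1) for every combination of a 2-3 predictor subset."""

    predictors: tuple[str, ...]
    table: Mapping[tuple[int, ...], float]

    def __post_init__(self) -> None:
        k = len(self.predictors)
        if k not in (2, 3):
            raise ValueError("penetrance specs cover 2 or 3 predictors")
        expected = set(product((0, 1), repeat=k))
        if set(self.table) != expected:
            raise ValueError(f"penetrance table must cover all {2**k} combinations")
        if any(not 0.0 <= p <= 1.0 for p in self.table.values()):
            raise ValueError("penetrance probabilities must lie in [0, 1]")

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        """Penetrance per row of a (n, k) 0/1 code matrix."""
        key = np.zeros(len(codes), dtype=np.int64)
        for j in range(codes.shape[1]):
            key = key * 2 + codes[:, j]
        flat = np.array([self.table[combo] for combo in
                         sorted(self.table, reverse=False)])
        # sorted() on tuples of 0/1 yields binary order 00,01,10,11,...
        return flat[key]


def xor_penetrance(predictors: tuple[str, str] = ("pse", "ses_low"),
                   delta: float = 0.1, base: float = 0.5) -> PenetranceSpec:
    """A pure pairwise interaction: P(outcome) = base + delta when the two
    codes differ, base - delta when they agree.  With balanced predictor
    prevalences the marginal effect of each predictor is exactly zero."""
    table = {(a, b): base + delta if a != b else base - delta
             for a in (0, 1) for b in (0, 1)}
    return PenetranceSpec(predictors, table)


def parity_penetrance(predictors: tuple[str, str, str] = ("eod_any", "pse", "ses_low"),
                      delta: float = 0.1, base: float = 0.5) -> PenetranceSpec:
    """A pure three-way interaction keyed to the parity of the three codes;
    all main effects and pairwise interactions vanish at balanced
    prevalences."""
    table = {(a, b, c): base + delta if (a + b + c) % 2 else base - delta
             for a in (0, 1) for b in (0, 1) for c in (0, 1)}
    return PenetranceSpec(predictors, table)


def pure_interaction_penetrance(predictors: Sequence[str],
                                prevalences: Mapping[str, float],
                                strength: float,
                                base: float = BASELINE_PREVALENCE) -> PenetranceSpec:
    """A pure interaction at arbitrary marginal frequencies.

    The table is ``base + strength * prod_j (x_j - q_j)`` with ``q_j`` the
    predictor prevalences, so every lower-order conditional mean of the
    penetrance equals ``base`` exactly: main effects (and, for three
    predictors, pairwise effects) vanish at those prevalences, unlike the
    balanced XOR/parity tables which are pure only at 50% prevalence.
    Raises if the requested strength pushes any cell outside [0, 1].
    """
    preds = tuple(predictors)
    q = [prevalences[p] for p in preds]
    table = {}
    for combo in product((0, 1), repeat=len(preds)):
        dev = strength
        for v, qj in zip(combo, q):
            dev *= (v - qj)
        table[combo] = base + dev
    return PenetranceSpec(preds, table)


def calibrate_pure_strength(target_ig_bits: float, predictors: Sequence[str],
                            prevalences: Mapping[str, float],
                            base: float = BASELINE_PREVALENCE,
                            upper: float = 1.5) -> float:
    """Strength for :func:`pure_interaction_penetrance` whose exact
    population information gain equals ``target_ig_bits`` (bisection on the
    enumeration oracle)."""
    from scipy.optimize import brentq

    def gap(d: float) -> float:
        pen = pure_interaction_penetrance(predictors, prevalences, d, base)
        return population_ig(pen, prevalences) - target_ig_bits

    hi = upper
    while hi > 1e-6:
        try:
            pure_interaction_penetrance(predictors, prevalences, hi, base)
            break
        except ValueError:
            hi *= 0.95
    return float(brentq(gap, 1e-9, hi))


@dataclass
class CohortSpec:
    """Generative description of a synthetic cohort."""

    n: int = 617
    prevalences: dict[str, float] = field(default_factory=lambda: dict(TABLE1_PREVALENCES))
    baseline: float = BASELINE_PREVALENCE
    age_mean: float = 14.0
    age_sd: float = 3.0
    age_range: tuple[float, float] = (8.0, 21.0)
    beta_age: float = 0.45  # log-odds per year of age on the outcome
    penetrance: list[PenetranceSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        for name, p in self.prevalences.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence of {name!r} must lie strictly in (0, 1)")
        if not 0.0 < self.baseline < 1.0:
            raise ValueError("baseline prevalence must lie strictly in (0, 1)")
        seen: set[str] = set()
        for spec in self.penetrance:
            overlap = seen & set(spec.predictors)
            if overlap:
                raise ValueError(
                    f"penetrance specs overlap on predictors {sorted(overlap)}: "
                    "the generative model would be ambiguous")
            seen |= set(spec.predictors)
            unknown = set(spec.predictors) - set(self.prevalences)
            if unknown:
                raise ValueError(f"penetrance spec references unknown predictors {sorted(unknown)}")


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_predictors(spec: CohortSpec, seed: Optional[int] = None) -> pd.DataFrame:
    """Independent Bernoulli predictor draws at the spec prevalences."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cols = {name: (rng.random(spec.n) < p).astype(np.int8)
            for name, p in spec.prevalences.items()}
    return pd.DataFrame(cols)


def sample_age(spec: CohortSpec, seed: Optional[int] = None) -> np.ndarray:
    """Truncated-normal ages on ``spec.age_range`` in years."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    lo, hi = spec.age_range
    a, b = (lo - spec.age_mean) / spec.age_sd, (hi - spec.age_mean) / spec.age_sd
    return truncnorm.rvs(a, b, loc=spec.age_mean, scale=spec.age_sd,
                         size=spec.n, random_state=rng)


def outcome_probability(predictors: pd.DataFrame, age: np.ndarray,
                        spec: CohortSpec) -> np.ndarray:
    """P(outcome = 1 | row) on the logit-additive scale.

    Each penetrance spec contributes ``logit(penetrance) - logit(baseline)``
    for the row's predictor combination; age contributes
    ``beta_age * (age - age_mean)``.  With a single spec and ``beta_age=0``
    the cell probabilities equal the penetrance table exactly.
    """
    eta = np.full(len(predictors), logit(spec.baseline))
    for pen in spec.penetrance:
        codes = predictors[list(pen.predictors)].to_numpy(dtype=np.int64)
        eta = eta + (logit(pen.lookup(codes)) - logit(spec.baseline))
    eta = eta + spec.beta_age * (np.asarray(age) - spec.age_mean)
    return expit(eta)


def sample_outcome(predictors: pd.DataFrame, age: np.ndarray, spec: CohortSpec,
                   seed: Optional[int] = None) -> np.ndarray:
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    p = outcome_probability(predictors, age, spec)
    return (rng.random(len(p)) < p).astype(np.int8)


def _sample_bdr(outcome: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Continuous percent-FEV1-change values consistent with responder status.

    Responders sit above the 12% threshold with an exponential tail
    (scale 8%); non-responders below it (scale 6%, so values may be
    negative, as observed for paradoxical responses).  This is a synthetic
    marginal shape for plotting/summary code, not a spirometry model.
    """
    bdr = np.empty(len(outcome))
    resp = outcome == 1
    bdr[resp] = BDR_RESPONDER_THRESHOLD + rng.exponential(8.0, resp.sum())
    bdr[~resp] = BDR_RESPONDER_THRESHOLD - 1e-9 - rng.exponential(6.0, (~resp).sum())
    return bdr


def generate_cohort(spec: CohortSpec) -> DiscreteCohort:
    """Assemble a full synthetic cohort (reproducible under ``spec.seed``)."""
    ss = np.random.SeedSequence(spec.seed)
    s_pred, s_age, s_out, s_bdr = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]
    predictors = sample_predictors(spec, seed=s_pred)
    age = sample_age(spec, seed=s_age)
    outcome = sample_outcome(predictors, age, spec, seed=s_out)
    bdr = _sample_bdr(outcome, np.random.default_rng(s_bdr))
    df = pd.DataFrame({"participant_id": [f"S{i:06d}" for i in range(spec.n)],
                       "outcome": outcome.astype(np.int64)})
    for name in PREDICTORS:
        if name in predictors:
            df[name] = predictors[name].astype(np.int64)
    df["age_years"] = age
    df["bdr_pct"] = bdr
    names = tuple(p for p in PREDICTORS if p in predictors.columns)
    meta = {"generator": "episcreen.simulate.generate_cohort",
            "seed": spec.seed, "n": spec.n, "beta_age": spec.beta_age,
            "baseline": spec.baseline,
            "penetrance": [{"predictors": list(p.predictors),
                            "table": {"".join(map(str, k)): v for k, v in p.table.items()}}
                           for p in spec.penetrance]}
    return DiscreteCohort(df, predictors=names, meta=meta)


# ---------------------------------------------------------------------------
# exact population information gain (enumeration oracle)
# ---------------------------------------------------------------------------

def population_ig(pen: PenetranceSpec, prevalences: Mapping[str, float],
                  clamp_synergy: bool = True) -> float:
    """Exact information gain, in bits, implied by a penetrance spec.

    Enumerates the joint distribution of the spec's predictors (independent
    Bernoulli at ``prevalences``) and the outcome, then evaluates the
    pairwise or three-way information-gain statistic on the exact
    probability table.  Assumes no confounder (the oracle for the
    ``beta_age = 0`` generative case).
    """
    k = len(pen.predictors)
    shape = (2,) * k + (2,)
    table = np.zeros(shape)
    for combo in product((0, 1), repeat=k):
        p_cell = 1.0
        for name, v in zip(pen.predictors, combo):
            pv = prevalences[name]
            p_cell *= pv if v == 1 else 1.0 - pv
        p_out = pen.table[combo]
        table[combo + (1,)] = p_cell * p_out
        table[combo + (0,)] = p_cell * (1.0 - p_out)
    if k == 2:
        return float(ig_pairwise_from_table(table))
    return float(ig_threeway_from_table(table, clamp_synergy=clamp_synergy))
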
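"""Cohort data model: bronchodilator response, dichotomization rules, I/O.

The analysis operates on a complete-case table of one binary outcome
(bronchodilator responder status: percent change in FEV1 after albuterol
at or above the 12% clinical threshold) and eight binary predictors:

======================  =============================================
column                  code 1 means
======================  =============================================
``sex``                 female
``age_hi``              age at or above the sample median
``afr_hi``              global African ancestry >= 80%
``bmi_obese``           BMI percentile >= 95 (obese)
``eod_any``             affirmative answer to any discrimination item
``pse``                 mother smoked during pregnancy
``ses_low``             low composite socioeconomic status
``no2_hi``              first-year NO2 exposure >= the sample median
======================  =============================================

Every dichotomization is represented by a :class:`DichotomizationRule`
whose resolved threshold is stored so re-applying the rule to the same raw
values reproduces identical codes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical predictor order used throughout the pipeline
PREDICTORS = ("sex", "age_hi", "afr_hi", "bmi_obese", "eod_any", "pse", "ses_low", "no2_hi")

#: clinical threshold (percent change in FEV1) separating responders
BDR_RESPONDER_THRESHOLD = 12.0


class SchemaError(ValueError):
    """Raised when an input table violates the cohort schema."""


@dataclass(frozen=True)
class DichotomizationRule:
    """A reproducible recipe turning a raw variable into a 0/1 code."""

    variable: str
    kind: str  # median_split | fixed_threshold | any_affirmative | composite_ses
    threshold: Optional[float] = None
    direction: str = "ge->1"  # "ge->1" (>= threshold codes 1) or "lt->1"

    def apply(self, values: Sequence[float]) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.kind in ("median_split", "fixed_threshold"):
            if self.threshold is None or not np.isfinite(self.threshold):
                raise ValueError(f"rule for {self.variable!r} has no resolved threshold")
            hit = v >= self.threshold if self.direction == "ge->1" else v < self.threshold
            return hit.astype(np.int8)
        raise ValueError(f"rule kind {self.kind!r} is not applied to a single vector")


@dataclass
class DiscreteCohort:
    """A complete-case case-control cohort of binary predictors.

    ``data`` holds one row per participant with columns ``participant_id``,
    ``outcome`` (1 = responder), every predictor in ``predictors``, and the
    optional continuous companions ``age_years`` and ``bdr_pct``.
    """

    data: pd.DataFrame
    predictors: tuple[str, ...] = PREDICTORS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.predictors = tuple(self.predictors)
        required = ["participant_id", "outcome", *self.predictors]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort table is missing columns: {missing}")
        coded = ["outcome", *self.predictors]
        block = self.data[coded]
        if block.isna().any().any():
            raise SchemaError("outcome/predictor columns contain missing values")
        bad = [c for c in coded if not np.isin(block[c].to_numpy(), (0, 1)).all()]
        if bad:
            raise SchemaError(f"non-binary codes in columns: {bad}")
        if "age_years" in self.data.columns and (self.data["age_years"] < 0).any():
            raise SchemaError("age_years must be nonnegative")
        if "bdr_pct" in self.data.columns:
            implied = (self.data["bdr_pct"] >= BDR_RESPONDER_THRESHOLD).astype(int)
            if not (implied.to_numpy() == self.data["outcome"].to_numpy()).all():
                raise SchemaError("outcome disagrees with bdr_pct at the 12% threshold")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def outcome(self) -> np.ndarray:
        return self.data["outcome"].to_numpy(dtype=np.int64)

    def predictor_matrix(self, names: Optional[Sequence[str]] = None) -> np.ndarray:
        names = list(names) if names is not None else list(self.predictors)
        return self.data[names].to_numpy(dtype=np.int64)

    def degenerate_predictors(self) -> list[str]:
        """Predictors constant across the cohort (uninformative, excluded
        from screens with a warning)."""
        return [p for p in self.predictors if self.data[p].nunique() < 2]

    def subset(self, index: Sequence[int], **meta) -> "DiscreteCohort":
        sub = self.data.iloc[np.asarray(index)].reset_index(drop=True)
        return DiscreteCohort(sub, predictors=self.predictors, meta={**self.meta, **meta})

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# bronchodilator drug response
# ---------------------------------------------------------------------------

def compute_bdr(pre_fev1: float, post_fev1_values: Sequence[float]) -> float:
    """Percent change in FEV1, using the post-albuterol measure with the
    maximal change: ``max_j ((post_j - pre) / pre) * 100``."""
    if not np.isfinite(pre_fev1) or pre_fev1 <= 0:
        raise ValueError("pre-bronchodilator FEV1 must be a positive volume")
    posts = np.asarray(post_fev1_values, dtype=float)
    if posts.size == 0 or not np.isfinite(posts).all():
        raise ValueError("need at least one finite post-bronchodilator FEV1")
    return float(((posts - pre_fev1) / pre_fev1).max() * 100.0)


def classify_responder(bdr_pct: float) -> int:
    """1 if the percent FEV1 change meets the 12% clinical threshold."""
    if not np.isfinite(bdr_pct):
        raise ValueError("BDR percent must be finite")
    return int(bdr_pct >= BDR_RESPONDER_THRESHOLD)


def exclude_bdr_outliers(bdr_values: Sequence[float], k: float = 4.0
                         ) -> tuple[np.ndarray, list[dict]]:
    """Indices surviving a mean +/- k*SD fence on raw BDR values.

    Returns ``(kept_indices, exclusion_log)``; the log records each removed
    index, its value and the fence.  ``k=inf`` keeps everything.
    """
    v = np.asarray(bdr_values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values to judge outliers")
    mean, sd = v.mean(), v.std(ddof=1)
    lo, hi = mean - k * sd, mean + k * sd
    keep = (v >= lo) & (v <= hi)
    log = [{"index": int(i), "value": float(v[i]), "fence": (float(lo), float(hi))}
           for i in np.flatnonzero(~keep)]
    for entry in log:
        logger.info("excluding BDR outlier %s", entry)
    return np.flatnonzero(keep), log


# ---------------------------------------------------------------------------
# dichotomization
# ---------------------------------------------------------------------------

def dichotomize_median(values: Sequence[float], variable: str = "x"
                       ) -> tuple[np.ndarray, DichotomizationRule]:
    """Median split: code 1 at and above the sample median.

    Ties at the median code 1, so an all-equal column becomes constant 1
    (degenerate; flagged downstream).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("median split needs at least 2 values")
    threshold = float(np.median(v))
    rule = DichotomizationRule(variable, "median_split", threshold, "ge->1")
    return rule.apply(v), rule


def dichotomize_threshold(values: Sequence[float], cutoff: float,
                          direction: str = "ge->1", variable: str = "x") -> np.ndarray:
    """Fixed-threshold coding, e.g. ancestry >= 0.80 or BMI percentile >= 95."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    rule = DichotomizationRule(variable, "fixed_threshold", float(cutoff), direction)
    return rule.apply(values)


def eod_any(answers: Sequence[int]) -> int:
    """Any-affirmative coding of the four discrimination questionnaire items."""
    a = np.asarray(answers)
    if a.shape != (4,):
        raise ValueError("expected exactly 4 questionnaire responses")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("responses must be 0/1 (complete-case: no missing answers)")
    return int(a.any())


def ses_composite(mother_edu: int, insurance: int, income: int,
                  low_cutoff: int = 1) -> int:
    """Composite socioeconomic code from three 0/1/2 indicators.

    The three components (maternal education, insurance status, household
    income, each scored low=0 / medium=1 / high=2) are summed to a 0-6
    composite; a composite at or below ``low_cutoff`` is classed low (0),
    otherwise medium/high (1).  The aggregation is a package convention —
    only the component scoring and the low vs medium/high split are fixed
    by the study design — so the cutoff is configurable and recorded in
    the codebook.
    """
    comps = (mother_edu, insurance, income)
    if any(c not in (0, 1, 2) for c in comps):
        raise ValueError("each SES component must be scored 0, 1 or 2")
    return int(sum(comps) > low_cutoff)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_cohort(path: str | Path, predictors: Sequence[str] = PREDICTORS,
                sep: str = ",") -> DiscreteCohort:
    """Load a delimited cohort table, dropping incomplete rows (logged).

    Raises :class:`SchemaError` on unknown/missing columns or non-binary
    codes in coded columns.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"participant_id", "outcome", *predictors}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"input is missing required columns: {missing}")
    known = required | {"age_years", "bdr_pct"}
    unknown = sorted(set(df.columns) - known)
    if unknown:
        raise SchemaError(f"unknown columns in input: {unknown}")
    n_raw = len(df)
    df = df.dropna().reset_index(drop=True)
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.info("dropped %d incomplete rows (complete-case analysis)", n_dropped)
    cohort = DiscreteCohort(df, predictors=tuple(predictors),
                            meta={"source": str(path), "rows_dropped": n_dropped})
    return cohort


def write_codebook(rules: Iterable[DichotomizationRule], path: str | Path,
                   extra: Optional[dict] = None) -> None:
    """Serialize dichotomization rules (with resolved thresholds) as JSON."""
    payload = {"rules": [asdict(r) for r in rules], **(extra or {})}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_codebook(path: str | Path) -> list[DichotomizationRule]:
    payload = json.loads(Path(path).read_text())
    return [DichotomizationRule(**r) for r in payload["rules"]]
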
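"""Phenotype model: BDR arithmetic, dichotomization rules, cohort I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import episcreen as ep
from episcreen.cohort import DichotomizationRule


@pytest.mark.parametrize("pre,posts,expected", [
    (2.0, [2.3], 15.0),
    (2.0, [2.1, 2.4], 20.0),   # maximal-change rule
    (2.5, [2.5], 0.0),
])
def test_compute_bdr(pre, posts, expected):
    assert ep.compute_bdr(pre, posts) == pytest.approx(expected)


def test_compute_bdr_rejects_nonpositive_pre():
    with pytest.raises(ValueError):
        ep.compute_bdr(0.0, [2.0])
    with pytest.raises(ValueError):
        ep.compute_bdr(2.0, [])


@pytest.mark.parametrize("bdr,expected", [(12.0, 1), (11.999, 0), (-5.0, 0), (40.0, 1)])
def test_classify_responder_threshold(bdr, expected):
    assert ep.classify_responder(bdr) == expected


def test_classify_responder_rejects_nonfinite():
    with pytest.raises(ValueError):
        ep.classify_responder(float("nan"))


def test_responder_monotone_in_post_fev1():
    """Raising any post-FEV1 value never demotes a responder."""
    pre = 2.0
    posts = [2.1, 2.2]
    base = ep.classify_responder(ep.compute_bdr(pre, posts))
    for bump in (0.05, 0.2, 1.0):
        bumped = ep.classify_responder(ep.compute_bdr(pre, [posts[0], posts[1] + bump]))
        assert bumped >= base
        base = bumped


@pytest.mark.parametrize("values,codes,threshold", [
    ([1, 2, 3, 4], [0, 0, 1, 1], 2.5),
    ([10, 20, 30], [0, 1, 1], 20.0),     # median 20, >= rule
    ([7, 7, 7], [1, 1, 1], 7.0),         # all-equal: every value >= median
])
def test_dichotomize_median(values, codes, threshold):
    got, rule = ep.dichotomize_median(values)
    assert got.tolist() == codes
    assert rule.threshold == pytest.approx(threshold)


@given(st.lists(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
                min_size=2, max_size=40))
@settings(derandomize=True, max_examples=100)
def test_stored_rule_reproduces_codes(values):
    codes, rule = ep.dichotomize_median(values)
    replay = DichotomizationRule(**{**rule.__dict__}).apply(values)
    assert np.array_equal(codes, replay)


@pytest.mark.parametrize("value,cutoff,expected", [
    (0.80, 0.80, 1),    # ancestry at the national-average cutoff
    (0.799, 0.80, 0),
    (95.0, 95.0, 1),    # BMI percentile at the obese classification
    (94.9, 95.0, 0),
])
def test_dichotomize_threshold_boundaries(value, cutoff, expected):
    assert ep.dichotomize_threshold([value], cutoff)[0] == expected


@pytest.mark.parametrize("answers,expected", [
    ((0, 0, 0, 0), 0), ((0, 1, 0, 0), 1), ((1, 1, 1, 1), 1),
])
def test_eod_any(answers, expected):
    assert ep.eod_any(answers) == expected


def test_eod_any_requires_four_complete_answers():
    with pytest.raises(ValueError):
        ep.eod_any((0, 1, 0))
    with pytest.raises(ValueError):
        ep.eod_any((0, 1, 0, 2))


@pytest.mark.parametrize("components,cutoff,expected", [
    ((0, 0, 0), 1, 0),
    ((2, 2, 2), 1, 1),
    ((1, 0, 0), 1, 0),   # composite 1 <= default cutoff -> low
    ((1, 1, 0), 1, 1),
    ((1, 0, 0), 0, 1),   # cutoff dependence
])
def test_ses_composite(components, cutoff, expected):
    assert ep.ses_composite(*components, low_cutoff=cutoff) == expected


def test_ses_composite_rejects_bad_score():
    with pytest.raises(ValueError):
        ep.ses_composite(3, 0, 0)


def test_exclude_bdr_outliers():
    kept, log = ep.exclude_bdr_outliers([10, 11, 12, 13], k=4)
    assert kept.tolist() == [0, 1, 2, 3] and log == []
    kept, log = ep.exclude_bdr_outliers([10, 11, 12, 500], k=1)
    assert kept.tolist() == [0, 1, 2] and log[0]["index"] == 3
    kept, _ = ep.exclude_bdr_outliers([1, 2, 3, 1000], k=np.inf)
    assert kept.tolist() == [0, 1, 2, 3]


def _write_cohort_csv(path, rows):
    cols = ["participant_id", "outcome", *ep.PREDICTORS]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def test_load_cohort_roundtrip(tmp_path):
    path = tmp_path / "c.csv"
    _write_cohort_csv(path, [["a", 1, 0, 1, 1, 0, 1, 0, 1, 0],
                             ["b", 0, 1, 0, 0, 1, 0, 1, 0, 1],
                             ["c", 1, 0, 0, 1, 1, 0, 0, 1, 1]])
    cohort = ep.load_cohort(path)
    assert len(cohort) == 3
    assert cohort.outcome.tolist() == [1, 0, 1]


def test_load_cohort_drops_incomplete_rows(tmp_path):
    path = tmp_path / "c.csv"
    rows = [["a", 1, 0, 1, 1, 0, 1, 0, 1, 0],
            ["b", 0, 1, 0, 0, 1, None, 1, 0, 1],
            ["c", 1, 0, 0, 1, 1, 0, 0, 1, 1]]
    _write_cohort_csv(path, rows)
    cohort = ep.load_cohort(path)
    assert len(cohort) == 2
    assert cohort.meta["rows_dropped"] == 1


def test_load_cohort_rejects_nonbinary_codes(tmp_path):
    path = tmp_path / "c.csv"
    _write_cohort_csv(path, [["a", 1, 0, 1, 1, 0, 2, 0, 1, 0],
                             ["b", 0, 1, 0, 0, 1, 0, 1, 0, 1]])
    with pytest.raises(ep.SchemaError):
        ep.load_cohort(path)


def test_load_cohort_rejects_unknown_column(tmp_path):
    path = tmp_path / "c.csv"
    df = pd.DataFrame({"participant_id": ["a"], "outcome": [1], "mystery": [3],
                       **{p: [0] for p in ep.PREDICTORS}})
    df.to_csv(path, index=False)
    with pytest.raises(ep.SchemaError):
        ep.load_cohort(path)


def test_cohort_outcome_must_match_bdr():
    df = pd.DataFrame({"participant_id": ["a"], "outcome": [0],
                       **{p: [0] for p in ep.PREDICTORS}, "bdr_pct": [15.0]})
    with pytest.raises(ep.SchemaError):
        ep.DiscreteCohort(df)
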
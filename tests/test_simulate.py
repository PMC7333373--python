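"""Synthetic-cohort generator: reproducibility, penetrance semantics,
exact-IG oracle and parameter recovery."""

from itertools import product

import numpy as np
import pytest

import episcreen as ep


def test_sample_predictors_reproducible_and_concentrated():
    spec = ep.CohortSpec(n=100_000, seed=1)
    a = ep.sample_predictors(spec)
    b = ep.sample_predictors(spec)
    assert a.equals(b)
    for name, p in ep.TABLE1_PREVALENCES.items():
        assert abs(a[name].mean() - p) < 0.01


def test_prevalence_bounds_enforced():
    with pytest.raises(ValueError):
        ep.CohortSpec(prevalences={**ep.TABLE1_PREVALENCES, "pse": 1.0})


def test_overlapping_penetrance_specs_rejected():
    with pytest.raises(ValueError):
        ep.CohortSpec(penetrance=[ep.xor_penetrance(("pse", "ses_low"), 0.3),
                                  ep.xor_penetrance(("pse", "no2_hi"), 0.3)])


def test_penetrance_table_must_be_complete():
    with pytest.raises(ValueError):
        ep.PenetranceSpec(("a", "b"), {(0, 0): 0.5, (0, 1): 0.5, (1, 0): 0.5})


def test_outcome_cell_frequencies_match_penetrance():
    prev = dict(ep.TABLE1_PREVALENCES)
    prev["pse"] = prev["ses_low"] = 0.5
    pen = ep.PenetranceSpec(("pse", "ses_low"),
                            {(0, 0): 0.1, (0, 1): 0.9, (1, 0): 0.9, (1, 1): 0.1})
    spec = ep.CohortSpec(n=10_000, beta_age=0.0, prevalences=prev, penetrance=[pen], seed=2)
    cohort = ep.generate_cohort(spec)
    d = cohort.data
    for (a, b), target in pen.table.items():
        cell = d[(d.pse == a) & (d.ses_low == b)]
        assert abs(cell.outcome.mean() - target) < 0.02


def test_constant_penetrance_gives_independence():
    pen = ep.PenetranceSpec(("pse", "ses_low"), {k: 0.5 for k in product((0, 1), repeat=2)})
    spec = ep.CohortSpec(n=50_000, beta_age=0.0, penetrance=[pen], seed=3)
    cohort = ep.generate_cohort(spec)
    d = cohort.data
    assert abs(ep.mutual_information(d.pse, d.outcome).bits) < 1e-3
    assert abs(ep.information_gain_pairwise(d.pse, d.ses_low, d.outcome).bits) < 1e-3


def test_age_confounding_sign():
    spec = ep.CohortSpec(n=10_000, beta_age=0.45, seed=4)
    cohort = ep.generate_cohort(spec)
    d = cohort.data
    assert np.corrcoef(d.age_years, d.outcome)[0, 1] > 0.05


def _enumeration_ig2(pen, prev):
    """Independent 8-cell enumeration of pairwise IG (test-local oracle)."""
    joint = {}
    for (a, b), p_out in pen.table.items():
        w = (prev[pen.predictors[0]] if a else 1 - prev[pen.predictors[0]]) * \
            (prev[pen.predictors[1]] if b else 1 - prev[pen.predictors[1]])
        joint[(a, b, 1)] = w * p_out
        joint[(a, b, 0)] = w * (1 - p_out)

    def H(keys):
        agg = {}
        for k, v in joint.items():
            kk = tuple(k[i] for i in keys)
            agg[kk] = agg.get(kk, 0.0) + v
        return -sum(v * np.log2(v) for v in agg.values() if v > 0)

    mi12 = H([0, 1]) + H([2]) - H([0, 1, 2])
    mi1 = H([0]) + H([2]) - H([0, 2])
    mi2 = H([1]) + H([2]) - H([1, 2])
    return mi12 - mi1 - mi2


def test_population_ig_truth_tables():
    prev = {"pse": 0.5, "ses_low": 0.5, "eod_any": 0.5}
    fair = ep.xor_penetrance(delta=0.5)
    assert ep.population_ig(fair, prev) == pytest.approx(1.0)
    flat = ep.PenetranceSpec(("pse", "ses_low"), {k: 0.3 for k in product((0, 1), repeat=2)})
    assert ep.population_ig(flat, prev) == pytest.approx(0.0, abs=1e-15)
    parity = ep.parity_penetrance(delta=0.5)
    assert ep.population_ig(parity, prev) == pytest.approx(1.0)


def test_population_ig_matches_enumeration_oracle():
    prev = {"pse": 0.35, "ses_low": 0.6}
    pen = ep.PenetranceSpec(("pse", "ses_low"),
                            {(0, 0): 0.1, (0, 1): 0.9, (1, 0): 0.9, (1, 1): 0.1})
    assert ep.population_ig(pen, prev) == pytest.approx(_enumeration_ig2(pen, prev),
                                                        abs=1e-12)


def test_sample_ig_recovers_population_ig():
    """Monte-Carlo consistency: empirical IG at n=1e5 within 0.01 bits."""
    prev = dict(ep.TABLE1_PREVALENCES)
    prev["pse"] = 0.4
    prev["ses_low"] = 0.55
    pen = ep.xor_penetrance(delta=0.25)
    spec = ep.CohortSpec(n=100_000, beta_age=0.0, prevalences=prev,
                         penetrance=[pen], seed=6)
    cohort = ep.generate_cohort(spec)
    d = cohort.data
    sample = ep.information_gain_pairwise(d.pse, d.ses_low, d.outcome).bits
    exact = ep.population_ig(pen, prev)
    assert sample == pytest.approx(exact, abs=0.01)


def test_pure_interaction_has_zero_marginal_effects():
    """Centered-product penetrance: conditional penetrance means equal the
    baseline at the stated prevalences, for pairs and triples."""
    prev = {"pse": 40 / 233, "ses_low": 79 / 233, "eod_any": 114 / 233}
    pen2 = ep.pure_interaction_penetrance(("pse", "ses_low"), prev, 0.5)
    q1, q2 = prev["pse"], prev["ses_low"]
    for a in (0, 1):  # E[pen | x1=a] over x2 ~ Bern(q2)
        cond = (1 - q2) * pen2.table[(a, 0)] + q2 * pen2.table[(a, 1)]
        assert cond == pytest.approx(ep.BASELINE_PREVALENCE, abs=1e-12)
    pen3 = ep.pure_interaction_penetrance(("pse", "ses_low", "eod_any"), prev, 1.0)
    assert ep.population_ig(pen3, prev) > 0
    # pairwise margin of the 3-way table is flat -> pairwise IG is zero
    sub = {}
    q3 = prev["eod_any"]
    for (a, b) in product((0, 1), repeat=2):
        sub[(a, b)] = (1 - q3) * pen3.table[(a, b, 0)] + q3 * pen3.table[(a, b, 1)]
        assert sub[(a, b)] == pytest.approx(ep.BASELINE_PREVALENCE, abs=1e-12)


def test_calibrate_pure_strength_hits_target():
    prev = {"pse": 40 / 233, "ses_low": 79 / 233}
    d = ep.calibrate_pure_strength(0.0278, ("pse", "ses_low"), prev)
    pen = ep.pure_interaction_penetrance(("pse", "ses_low"), prev, d)
    assert ep.population_ig(pen, prev) == pytest.approx(0.0278, abs=1e-9)


def test_generate_cohort_defaults_and_reproducibility():
    cohort = ep.generate_cohort(ep.CohortSpec(seed=0))
    assert len(cohort) == 617
    assert abs(cohort.data.pse.mean() - 40 / 233) < 0.05
    again = ep.generate_cohort(ep.CohortSpec(seed=0))
    assert cohort.data.equals(again.data)
    other = ep.generate_cohort(ep.CohortSpec(seed=1))
    assert not cohort.data.outcome.equals(other.data.outcome)
    assert cohort.meta["seed"] == 0


def test_generate_cohort_single_row():
    assert len(ep.generate_cohort(ep.CohortSpec(n=1, seed=9))) == 1
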
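"""Entropy engine: MI, pairwise/three-way IG, truth-table oracles."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

import episcreen as ep
from episcreen.entropy import ig_pairwise_from_table, ig_threeway_from_table


@pytest.mark.parametrize("counts,expected", [
    ([50, 50], 1.0),
    ([100, 0], 0.0),
    ([75, 25], 0.8113),
])
def test_entropy_values(counts, expected):
    assert ep.entropy(counts) == pytest.approx(expected, abs=1e-4)


def test_entropy_rejects_empty():
    with pytest.raises(ValueError):
        ep.entropy([0, 0])
    with pytest.raises(ValueError):
        ep.entropy([])


def test_mi_identical_and_independent():
    c = [0, 1] * 20
    assert ep.mutual_information(c, c).bits == pytest.approx(1.0)
    x = [0, 0, 1, 1]
    cc = [0, 1, 0, 1]
    assert ep.mutual_information(x, cc).bits == pytest.approx(0.0, abs=1e-12)


def test_mi_matches_g_statistic():
    """Plug-in MI equals G/(2N ln2) with G the likelihood-ratio statistic."""
    table = np.array([[30, 10], [20, 40]])
    x = np.repeat([0, 0, 1, 1], table.ravel())
    c = np.repeat([0, 1, 0, 1], table.ravel())
    g = chi2_contingency(table, lambda_="log-likelihood", correction=False).statistic
    assert ep.mutual_information(x, c).bits == pytest.approx(
        g / (2 * table.sum() * np.log(2)), abs=1e-12)


def test_mi_length_mismatch():
    with pytest.raises(ValueError):
        ep.mutual_information([0, 1], [0, 1, 1])


def test_joint_mi_degenerate_and_duplicate():
    x = [0, 1, 0, 1, 1, 0]
    c = [0, 1, 1, 1, 0, 0]
    single = ep.mutual_information(x, c).bits
    assert ep.joint_mutual_information([x], c) == pytest.approx(single)
    assert ep.joint_mutual_information([x, x], c) == pytest.approx(single)
    with pytest.raises(ValueError):
        ep.joint_mutual_information([x, x, x, x], c)


def test_joint_mi_xor_truth_table():
    assert ep.joint_mutual_information([[0, 0, 1, 1], [0, 1, 0, 1]],
                                       [0, 1, 1, 0]) == pytest.approx(1.0)


def test_ig2_xor_pure_synergy():
    iv = ep.information_gain_pairwise([0, 0, 1, 1], [0, 1, 0, 1], [0, 1, 1, 0])
    assert iv.bits == pytest.approx(1.0)
    assert iv.pct == pytest.approx(100.0)


def test_ig2_duplicate_pure_redundancy():
    x = [0, 0, 1, 1]
    iv = ep.information_gain_pairwise(x, x, x)
    assert iv.bits == pytest.approx(-1.0)


def test_ig2_independent_null():
    rows = list(product((0, 1), repeat=3))
    x1, x2, c = ([r[i] for r in rows] for i in range(3))
    assert ep.information_gain_pairwise(x1, x2, c).bits == pytest.approx(0.0, abs=1e-12)


def test_ig2_constant_class_error():
    with pytest.raises(ValueError):
        ep.information_gain_pairwise([0, 1, 0, 1], [0, 0, 1, 1], [1, 1, 1, 1])


def test_ig3_parity_pure_three_way():
    """Exhaustive parity table: all MIs and pairwise IGs vanish, IG3 = 1 bit."""
    rows = list(product((0, 1), repeat=3))
    x1, x2, x3 = ([r[i] for r in rows] for i in range(3))
    c = [(a + b + d) % 2 for a, b, d in rows]
    for x in (x1, x2, x3):
        assert ep.mutual_information(x, c).bits == pytest.approx(0.0, abs=1e-12)
    for a, b in ((x1, x2), (x1, x3), (x2, x3)):
        assert ep.information_gain_pairwise(a, b, c).bits == pytest.approx(0.0, abs=1e-12)
    assert ep.information_gain_threeway(x1, x2, x3, c).bits == pytest.approx(1.0)


def test_ig3_main_effect_only_absorbed():
    rows = list(product((0, 1), repeat=3))
    x1, x2, x3 = ([r[i] for r in rows] for i in range(3))
    assert ep.information_gain_threeway(x1, x2, x3, x1).bits == pytest.approx(0.0, abs=1e-12)


def test_ig3_independent_null():
    rows = list(product((0, 1), repeat=4))
    x1, x2, x3, c = ([r[i] for r in rows] for i in range(4))
    assert ep.information_gain_threeway(x1, x2, x3, c).bits == pytest.approx(0.0, abs=1e-12)


def test_ig3_clamp_flag_controls_redundancy_subtraction():
    """With the synergy-only rule off, negative pairwise IG is subtracted too."""
    rng = np.random.default_rng(5)
    x1 = rng.integers(0, 2, 200)
    x2 = x1.copy()                      # maximally redundant pair
    x3 = rng.integers(0, 2, 200)
    c = x1 ^ (rng.random(200) < 0.1).astype(int)
    on = ep.information_gain_threeway(x1, x2, x3, c, clamp_synergy=True).bits
    off = ep.information_gain_threeway(x1, x2, x3, c, clamp_synergy=False).bits
    neg_sum = sum(min(ep.information_gain_pairwise(a, b, c).bits, 0.0)
                  for a, b in ((x1, x2), (x1, x3), (x2, x3)))
    assert off == pytest.approx(on - neg_sum, abs=1e-12)
    assert off > on  # redundant pair present, so the raw rule adds back


def test_to_percent():
    assert ep.to_percent(1.0, 1.0) == 100.0
    assert ep.to_percent(0.0278, 1.0) == pytest.approx(2.78)
    with pytest.raises(ValueError):
        ep.to_percent(0.1, 0.0)


binary_arrays = st.integers(min_value=8, max_value=64).flatmap(
    lambda n: st.tuples(*(st.lists(st.integers(0, 1), min_size=n, max_size=n)
                          for _ in range(3))))


@given(binary_arrays)
@settings(derandomize=True, max_examples=150)
def test_information_inequalities(seqs):
    """MI symmetry/nonnegativity, joint monotonicity, and the H(C) bound."""
    x1, x2, c = (np.array(s) for s in seqs)
    if c.min() == c.max():
        return
    mi_xc = ep.mutual_information(x1, c).bits
    assert mi_xc >= -1e-12
    assert mi_xc == pytest.approx(ep.mutual_information(c, x1).bits, abs=1e-12)
    mi1 = ep.mutual_information(x1, c).bits
    mi2 = ep.mutual_information(x2, c).bits
    joint = ep.joint_mutual_information([x1, x2], c)
    assert joint >= max(mi1, mi2) - 1e-12
    h_c = ep.entropy(np.bincount(c, minlength=2))
    iv = ep.information_gain_pairwise(x1, x2, c)
    assert abs(iv.bits) <= h_c + 1e-12


@given(st.integers(min_value=0, max_value=2**32 - 1))
@settings(derandomize=True, max_examples=25)
def test_ig3_bounded_by_class_entropy(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 80))
    x = rng.integers(0, 2, (n, 3))
    c = rng.integers(0, 2, n)
    if c.min() == c.max():
        return
    h_c = ep.entropy(np.bincount(c, minlength=2))
    iv = ep.information_gain_threeway(x[:, 0], x[:, 1], x[:, 2], c)
    assert abs(iv.bits) <= h_c + 1e-12


def test_additive_logistic_model_has_vanishing_ig2():
    """Main-effects-only logistic data: IG2 ~ 0 at large n (no synergy)."""
    rng = np.random.default_rng(11)
    n = 100_000
    x1 = rng.integers(0, 2, n)
    x2 = rng.integers(0, 2, n)
    from scipy.special import expit
    p = expit(0.1 + 0.5 * x1 - 0.3 * x2)
    c = (rng.random(n) < p).astype(int)
    assert abs(ep.information_gain_pairwise(x1, x2, c).bits) < 0.005


def test_table_and_sequence_paths_agree():
    rng = np.random.default_rng(2)
    x1, x2, x3 = rng.integers(0, 2, (3, 150))
    c = rng.integers(0, 2, 150)
    t = np.zeros((2, 2, 2, 2))
    np.add.at(t, (x1, x2, x3, c), 1)
    assert ig_pairwise_from_table(t.sum(axis=2)) == pytest.approx(
        ep.information_gain_pairwise(x1, x2, c).bits, abs=1e-12)
    assert ig_threeway_from_table(t) == pytest.approx(
        ep.information_gain_threeway(x1, x2, x3, c).bits, abs=1e-12)
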
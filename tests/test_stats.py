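"""Hamming distances, trend test, PIC, spurious expectation, group tests."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dartsex import (
    MISSING,
    catt,
    compare_criterion_groups,
    distance_summary,
    expected_spurious,
    hamming_matrix,
    pic,
    pic_per_locus,
)
from dartsex.stats import catt_per_locus

from conftest import make_pa, make_registry, make_snp, random_calls
from oracles import (
    brute_hamming,
    catt_chi2_direct,
    pearson_chi2,
    permutation_catt_p,
)


# --- Hamming ----------------------------------------------------------------

def test_hamming_half_different():
    pa = make_pa(np.array([[1, 1], [1, 0], [0, 0], [0, 1]]))
    d = hamming_matrix(pa)
    assert d.iloc[0, 1] == pytest.approx(0.5)
    assert d.iloc[0, 0] == 0.0


def test_hamming_pairwise_deletion():
    pa = make_pa(np.array([[1, 1], [MISSING, 0], [0, 0]]))
    d = hamming_matrix(pa)
    # locus 2 missing in A: only 2 shared loci, both equal
    assert d.iloc[0, 1] == pytest.approx(0.0)


def test_hamming_missing_as_mismatch_mode():
    pa = make_pa(np.array([[1, 1], [MISSING, 0], [0, 0]]))
    d = hamming_matrix(pa, missing_as_mismatch=True)
    assert d.iloc[0, 1] == pytest.approx(1 / 3)


def test_hamming_empty_locus_set_errors():
    pa = make_pa([[1, 0]])
    with pytest.raises(ValueError, match="empty locus"):
        hamming_matrix(pa, loci=[])


def test_hamming_disjoint_pair_is_nan():
    pa = make_pa(np.array([[1, MISSING], [MISSING, 0]]))
    d = hamming_matrix(pa)
    assert math.isnan(d.iloc[0, 1])
    assert d.iloc[0, 0] == 0.0  # diagonal stays defined


def test_hamming_agrees_with_brute_force_and_is_symmetric():
    rng = np.random.default_rng(10)
    for _ in range(30):
        calls = random_calls(rng, int(rng.integers(1, 20)), 6, "SNP",
                             missing_rate=0.3)
        m = make_snp(calls)
        d = hamming_matrix(m).to_numpy()
        ref = brute_hamming(calls)
        assert np.allclose(d, ref, equal_nan=True)
        assert np.allclose(d, d.T, equal_nan=True)
        finite = d[~np.isnan(d)]
        assert ((finite >= 0) & (finite <= 1)).all()


def test_hamming_permutation_consistency():
    rng = np.random.default_rng(11)
    calls = random_calls(rng, 12, 6, "PA")
    m = make_pa(calls)
    d = hamming_matrix(m)
    perm = list(np.array(m.individual_ids)[[3, 1, 5, 0, 2, 4]])
    m2 = make_pa(calls[:, [3, 1, 5, 0, 2, 4]], individuals=perm)
    d2 = hamming_matrix(m2)
    assert np.allclose(d.loc[perm, perm].to_numpy(), d2.to_numpy(),
                       equal_nan=True)


# --- distance_summary -------------------------------------------------------

def test_distance_summary_block_structure():
    # 2M/2F: within-sex pairs 0, between pairs 1
    ids = ["M01", "M02", "F01", "F02"]
    d = pd.DataFrame(
        [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]],
        index=ids, columns=ids, dtype=float,
    )
    s = distance_summary(d, make_registry(2, 2))
    assert (s.mean_within_male, s.mean_within_female, s.mean_between) == (0, 0, 1)
    assert (s.n_pairs_within_male, s.n_pairs_within_female, s.n_pairs_between) \
        == (1, 1, 4)


def test_distance_summary_single_male_stratum_undefined():
    ids = ["M01", "F01", "F02"]
    d = pd.DataFrame(np.zeros((3, 3)), index=ids, columns=ids)
    s = distance_summary(d, make_registry(1, 2))
    assert math.isnan(s.mean_within_male)
    assert "within_male" in s.undefined_strata
    assert s.mean_within_female == 0.0


def test_distance_summary_matches_enumeration_and_pair_counts():
    rng = np.random.default_rng(12)
    ids = ["M01", "M02", "M03", "F01", "F02", "F03"]
    sym = rng.random((6, 6))
    sym = (sym + sym.T) / 2
    np.fill_diagonal(sym, 0.0)
    d = pd.DataFrame(sym, index=ids, columns=ids)
    reg = make_registry(3, 3)
    s = distance_summary(d, reg, "SEM")
    wm = [sym[a, b] for a, b in [(0, 1), (0, 2), (1, 2)]]
    bt = [sym[a, b] for a in range(3) for b in range(3, 6)]
    assert s.mean_within_male == pytest.approx(np.mean(wm))
    assert s.mean_between == pytest.approx(np.mean(bt))
    assert s.dispersion_between == pytest.approx(
        np.std(bt, ddof=1) / math.sqrt(len(bt)))
    # n_pairs: C(3,2), C(3,2), 3*3
    assert (s.n_pairs_within_male, s.n_pairs_between) == (3, 9)


# --- CATT -------------------------------------------------------------------

def test_catt_no_trend_is_zero():
    res = catt([[5, 5, 5], [5, 5, 5]], weights=(0, 1, 2))
    assert res.chi2 == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_catt_pa_example_10_8():
    """Males 3 absent / 12 present vs females 12 absent / 3 present."""
    res = catt([[3, 12], [12, 3]], weights=(0, 1))
    assert res.chi2 == pytest.approx(10.8)


def test_catt_perfect_separation_equals_n():
    res = catt([[0, 15], [15, 0]], weights=(0, 1))
    assert res.chi2 == pytest.approx(30.0)


def test_catt_zero_variance_flagged_not_raised():
    res = catt([[0, 15], [0, 15]], weights=(0, 1))
    assert not res.defined and math.isnan(res.chi2)


def test_catt_invalid_tables():
    with pytest.raises(ValueError):
        catt([[1, 2]])
    with pytest.raises(ValueError):
        catt([[1, 2], [3, 4]], weights=(0, 1, 2))
    with pytest.raises(ValueError):
        catt([[0, 0], [3, 4]])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**32 - 1))
def test_catt_row_swap_with_reflected_weights_invariant(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 4))
    table = rng.integers(0, 10, size=(2, k)) + 1
    w = np.sort(rng.random(k))
    a = catt(table, w)
    b = catt(table[::-1], w)               # swap groups
    c = catt(table, tuple(w.max() + w.min() - x for x in w))  # reflect weights
    assert a.chi2 >= 0
    assert a.chi2 == pytest.approx(b.chi2)
    assert a.chi2 == pytest.approx(c.chi2)


def test_catt_matches_n_r_squared_identity():
    """Closed form equals N times the squared correlation between group
    and weighted state over expanded individuals."""
    rng = np.random.default_rng(13)
    for _ in range(50):
        k = int(rng.integers(2, 4))
        table = rng.integers(0, 12, size=(2, k)) + 1
        w = (0.0, 1.0, 2.0)[:k]
        mine = catt(table, w)
        if not mine.defined:
            continue
        assert mine.chi2 == pytest.approx(catt_chi2_direct(table, w), rel=1e-9)


def test_catt_per_locus_counts_and_missing_exclusion():
    pa = make_pa(
        [[1, 1, MISSING, 0, 0, 0]],
        individuals=["M01", "M02", "M03", "F01", "F02", "F03"],
    )
    out = catt_per_locus(pa, make_registry(3, 3))
    assert out.loc["L001", "n_called_m"] == 2
    assert out.loc["L001", "n_called_f"] == 3
    ref = catt([[0, 2], [3, 0]], weights=(0, 1))
    assert out.loc["L001", "chi2"] == pytest.approx(ref.chi2)


# --- PIC --------------------------------------------------------------------

@pytest.mark.parametrize("p,expected", [(0.5, 0.5), (1.0, 0.0), (0.0, 0.0),
                                        (0.25, 0.375)])
def test_pic_values(p, expected):
    assert pic(p) == pytest.approx(expected)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(p=st.floats(0, 1))
def test_pic_symmetric_and_bounded(p):
    assert pic(p) == pytest.approx(pic(1 - p))
    assert 0 <= pic(p) <= 0.5
    assert pic(p) <= pic(0.5)


def test_pic_out_of_range_errors():
    with pytest.raises(ValueError):
        pic(1.2)


def test_pic_per_locus_gene_counting():
    # 2 snp-hom + 1 het + 1 ref-hom: p = (2*2+1)/8 = 0.625
    snp = make_snp([[1, 1, 2, 0]])
    out = pic_per_locus(snp)
    assert out.loc["L001", "p"] == pytest.approx(0.625)
    assert out.loc["L001", "pic"] == pytest.approx(2 * 0.625 * 0.375)


def test_pic_per_locus_pa_presence_frequency():
    pa = make_pa([[1, 1, 1, 0]])
    out = pic_per_locus(pa)
    assert out.loc["L001", "p"] == pytest.approx(0.75)


# --- spurious expectation ---------------------------------------------------

def test_expected_spurious_printed_values():
    est = expected_spurious(30, 160870)
    assert est.display() == {"p_single": "9.31e-10", "expected_count": "1.5e-04"}


def test_expected_spurious_trivial_case():
    est = expected_spurious(1, 1)
    assert (est.p_single, est.expected_count) == (0.5, 0.5)


def test_expected_spurious_halves_per_individual():
    values = [expected_spurious(n, 1).p_single for n in range(1, 40)]
    assert all(b == pytest.approx(a / 2) for a, b in zip(values, values[1:]))
    assert all(a > b for a, b in zip(values, values[1:]))  # strictly decreasing


# --- group comparisons ------------------------------------------------------

def test_chi2_identical_proportions_zero():
    res = compare_criterion_groups(
        {"a": (10, 30), "b": (20, 60)}, mode="chi2_pa")
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_chi2_agrees_with_textbook_pearson():
    rng = np.random.default_rng(14)
    for _ in range(25):
        groups = {f"g{i}": tuple(rng.integers(1, 40, 2)) for i in range(3)}
        res = compare_criterion_groups(groups, mode="chi2_pa")
        table = np.array([groups[g] for g in res.group_names], dtype=float)
        assert res.statistic == pytest.approx(pearson_chi2(table), rel=1e-9)


def test_chi2_empty_group_flagged():
    res = compare_criterion_groups({"a": (0, 0), "b": (5, 5)}, mode="chi2_pa")
    assert not res.defined


def test_kruskal_identical_vectors_h_zero():
    v = [0.4, 0.5, 0.45]
    res = compare_criterion_groups({"a": v, "b": v, "c": v}, mode="kruskal_snp")
    assert res.statistic == pytest.approx(0.0)


def test_kruskal_separated_groups_rejects_with_nemenyi():
    rng = np.random.default_rng(15)
    groups = {
        "lo": rng.normal(0.1, 0.01, 20),
        "mid": rng.normal(0.3, 0.01, 20),
        "hi": rng.normal(0.49, 0.005, 20),
    }
    res = compare_criterion_groups(groups, mode="kruskal_snp")
    assert res.p_value < 0.001
    assert res.posthoc is not None
    assert res.posthoc.loc["lo", "hi"] < 0.01
    assert res.posthoc.loc["lo", "lo"] == pytest.approx(1.0)


def test_kruskal_empty_group_flagged():
    res = compare_criterion_groups({"a": [], "b": [0.2]}, mode="kruskal_snp")
    assert not res.defined


# --- permutation cross-check for CATT p-values ------------------------------

def test_catt_p_matches_permutation_oracle():
    """Closed-form p agrees with a 10,000-draw Monte-Carlo permutation
    p-value within 3 sigma on random study-scale 2x2 and 2x3 tables.

    The permutation null is a lattice distribution, so its p-value is only
    defined up to the tie mass at the observed statistic; the closed-form
    (continuous) p must lie inside the [P(>obs), P(>=obs)] bracket up to
    Monte-Carlo noise.
    """
    rng = np.random.default_rng(16)
    checked = 0
    while checked < 12:
        k = 2 if checked % 2 == 0 else 3
        table = np.vstack([
            rng.multinomial(15, np.ones(k) / k),
            rng.multinomial(15, rng.dirichlet(np.ones(k))),
        ])
        if (table.sum(axis=0) == 0).any():
            continue
        w = tuple(range(k))
        res = catt(table, w)
        if not res.defined:
            continue
        p_gt, p_geq, sigma = permutation_catt_p(table, w, 10_000, rng)
        assert p_gt - 3 * sigma <= res.p_value <= p_geq + 3 * sigma
        checked += 1
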
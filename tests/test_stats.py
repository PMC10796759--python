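"""Spearman/Pearson correlation, classification and grouped tabulation."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from drillct.core import AlignedPair, SpecimenMeta
from drillct.stats import (
    classify_r,
    correlate_pair,
    count_by_class,
    grouped_correlations,
    pearson,
    spearman,
)
from drillct.studies import (
    published_class_counts,
    published_results,
    spearman_p_agreement,
    tabulate_pair_counts,
)


# ---------------------------------------------------------------------------
# spearman


def test_spearman_perfect_and_reversed():
    assert spearman([1, 2, 3], [10, 20, 30])[0] == 1.0
    x = np.array([0.3, 1.7, 2.2, 9.0])
    assert spearman(x, x[::-1])[0] == -1.0


def test_spearman_known_rank_displacement():
    # sum d^2 = 2 -> r = 1 - 6*2/(4*15) = 0.8
    r, p = spearman([1, 2, 3, 4], [1, 3, 2, 4])
    assert np.isclose(r, 0.8)
    # independent brute-force permutation p for comparison
    y = np.array([1, 3, 2, 4], dtype=float)
    rs = []
    for perm in itertools.permutations(range(4)):
        rs.append(sps.pearsonr(np.arange(4), y[list(perm)]).statistic)
    p_brute = np.mean(np.abs(rs) >= 0.8 - 1e-12)
    assert np.isclose(p, p_brute)


def test_spearman_matches_scipy_at_large_n():
    rng = np.random.default_rng(0)
    for _ in range(10):
        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(size=60)
        r, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert np.isclose(r, ref.statistic, atol=1e-12)
        assert np.isclose(p, ref.pvalue, atol=1e-10)


def test_spearman_handles_ties_via_average_ranks():
    x = [1, 2, 2, 3]
    y = [10, 20, 20, 30]
    r, _ = spearman(x, y)
    assert r == 1.0


def test_spearman_constant_input_errors():
    with pytest.raises(ValueError, match="constant"):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])


def test_spearman_invariant_under_monotone_transforms():
    rng = np.random.default_rng(1)
    x = rng.normal(size=50)
    y = rng.normal(size=50)
    r_ref = spearman(x, y)[0]
    for f in (np.exp, lambda v: v**3, lambda v: 1026.0 + 2.0 * v):
        assert np.isclose(spearman(f(x), y)[0], r_ref, atol=1e-12)
        assert np.isclose(spearman(x, f(y))[0], r_ref, atol=1e-12)


def test_spearman_t_approximation_agrees_with_exact_permutation():
    res = spearman_p_agreement(n_inputs=50, seed=0, sizes=(8, 9))
    assert res["max_abs_p_difference"] <= 0.02


# ---------------------------------------------------------------------------
# pearson


def test_pearson_closed_form_line():
    r, R2, slope, intercept = pearson([0, 1, 2, 3], [1, 3, 5, 7])
    assert np.isclose(r, 1.0) and np.isclose(R2, 1.0)
    assert np.isclose(slope, 2.0) and np.isclose(intercept, 1.0)


def test_pearson_zero_sample_covariance():
    x = np.array([-1.0, 0.0, 1.0])
    y = np.array([1.0, -2.0, 1.0])  # orthogonal to x by construction
    r, R2, _, _ = pearson(x, y)
    assert abs(r) < 1e-12 and R2 < 1e-12


def test_pearson_constant_input_errors():
    with pytest.raises(ValueError, match="constant"):
        pearson([1.0, 1.0, 1.0], [1, 2, 3])


# ---------------------------------------------------------------------------
# classify_r


@pytest.mark.parametrize(
    "r,expected",
    [
        (0.107, "poor"),              # published L1 row of donor A
        (0.299, "poor"),
        (0.3, "fair"),                # left-closed band boundary
        (0.524, "fair"),
        (0.6, "moderately_strong"),
        (0.721, "moderately_strong"),  # published T11 row of donor A
        (0.8, "very_strong"),
        (1.0, "very_strong"),
        (-0.75, "moderately_strong"),  # classification on |r|
    ],
)
def test_classification_bands(r, expected):
    assert classify_r(r) == expected


def test_classify_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify_r(1.5)


# ---------------------------------------------------------------------------
# published-table tabulations


def test_pair_count_tabulation_matches_published_totals():
    counts = tabulate_pair_counts()
    assert counts["total"] == 4818
    assert counts["region_T"] == 904
    assert counts["region_L"] == 3914
    assert counts["individual_A"] == 2620
    assert counts["individual_B"] == 2198
    assert counts["B_T"] == 309


def test_class_counts_at_study_significance():
    counts = published_class_counts(0.01)
    assert counts == {
        "poor": 2,
        "fair": 5,
        "moderately_strong": 5,
        "very_strong": 0,
    }
    assert sum(1 for r in published_results() if r.significant) == 12


def test_class_counts_without_filter_reinclude_nonsignificant():
    counts = published_class_counts(1.0)
    assert counts["poor"] == 3  # the non-significant poor row returns


def test_class_counts_all_filtered_out():
    counts = count_by_class(published_results(), significance_filter=0.0)
    assert all(v == 0 for v in counts.values())


# ---------------------------------------------------------------------------
# grouped correlations


def _mk_pair(rng, meta, n=60, rho=0.7):
    x = rng.normal(size=n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
    from drillct.profiles import normalize_minmax

    return AlignedPair(
        s=np.arange(n) * 0.1 + 0.1,
        intensity_norm=normalize_minmax(x),
        force_norm=normalize_minmax(y),
        shift_mm=0.0,
        meta=meta,
    )


def test_grouped_structure_and_n_additivity():
    rng = np.random.default_rng(0)
    pairs = [
        _mk_pair(rng, SpecimenMeta("A", "T", "T11"), n=40),
        _mk_pair(rng, SpecimenMeta("A", "L", "L1"), n=50),
        _mk_pair(rng, SpecimenMeta("B", "L", "L2"), n=60),
    ]
    results = {r.group: r for r in grouped_correlations(pairs)}
    # 3 specimens + 2 regions + 2 individuals + 3 non-empty region x
    # individual cells + overall
    assert len(results) == 3 + 2 + 2 + 3 + 1
    assert results["region_L"].n == 110
    assert results["individual_A"].n == 90
    assert results["overall"].n == 150
    assert results["A_T"].n == 40


def test_single_member_group_equals_specimen_result():
    rng = np.random.default_rng(1)
    pair = _mk_pair(rng, SpecimenMeta("B", "T", "T12"), n=45)
    results = {r.group: r for r in grouped_correlations([pair])}
    assert np.isclose(results["B_T"].r_spearman, results["B_T12"].r_spearman)
    assert results["B_T"].n == results["B_T12"].n


def test_grouped_deterministic():
    rng1 = np.random.default_rng(2)
    rng2 = np.random.default_rng(2)
    p1 = [_mk_pair(rng1, SpecimenMeta("A", "T", "T11"))]
    p2 = [_mk_pair(rng2, SpecimenMeta("A", "T", "T11"))]
    r1 = grouped_correlations(p1)[0]
    r2 = grouped_correlations(p2)[0]
    assert r1 == r2


def test_grouped_requires_metadata():
    rng = np.random.default_rng(3)
    pair = _mk_pair(rng, None)
    with pytest.raises(ValueError, match="metadata"):
        grouped_correlations([pair])


def test_correlate_pair_consistency():
    rng = np.random.default_rng(4)
    pair = _mk_pair(rng, SpecimenMeta("A", "L", "L3"))
    res = correlate_pair(pair)
    assert res.group == "A_L3"
    assert np.isclose(res.R2, res.r_pearson**2)
    assert res.strength == classify_r(res.r_spearman)
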
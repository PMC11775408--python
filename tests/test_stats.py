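"""Paired statistics: Wilcoxon signed-rank, Bland-Altman, cohort tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionshape import (
    DegenerateDifferencesError,
    StatsDomainError,
    bland_altman,
    compare_cohort,
    median_iqr,
    paired_table_from_markers,
    sensitivity_filter,
    wilcoxon_signed_rank,
)
from lesionshape.errors import CohortError
from lesionshape.markers import MARKER_NAMES


# -- median / IQR -----------------------------------------------------------


def test_median_iqr_order_statistics():
    assert median_iqr([1, 2, 3, 4, 5]) == (3, 2, 4)
    assert median_iqr([7]) == (7, 7, 7)


def test_median_iqr_uniform_sample(rng):
    med, q25, q75 = median_iqr(rng.random(1000))
    assert med == pytest.approx(0.5, abs=0.05)
    assert q25 == pytest.approx(0.25, abs=0.05)
    assert q75 == pytest.approx(0.75, abs=0.05)


def test_median_iqr_empty_raises():
    with pytest.raises(StatsDomainError):
        median_iqr([])


# -- Wilcoxon signed-rank ---------------------------------------------------


def brute_force_two_sided_p(diffs):
    """Enumerate all 2^n sign assignments: P(min(W+, W-) <= observed)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    n = len(d)
    total = ranks.sum()
    hits = 0
    for signs in itertools.product([0, 1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        if min(w_plus, total - w_plus) <= w_obs + 1e-12:
            hits += 1
    return hits / 2 ** n


def test_perfectly_symmetric_differences_give_p_one():
    a = np.array([1.0, 0.0, 2.0, 0.0, 3.0, 0.0])
    b = np.array([0.0, 1.0, 0.0, 2.0, 0.0, 3.0])
    res = wilcoxon_signed_rank(a, b)
    assert res.w_plus == res.w_minus
    assert res.pvalue == pytest.approx(1.0)


def test_all_positive_differences_exact_p():
    d = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    res = wilcoxon_signed_rank(d, np.zeros(6))
    assert res.statistic == 0.0
    assert res.pvalue == pytest.approx(2 / 64)
    assert res.method == "exact"


@pytest.mark.parametrize("seed", range(25))
def test_exact_p_matches_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 13))
    # integer-ish values to exercise mid-rank ties
    d = rng.integers(-5, 6, n).astype(float)
    if np.all(d == 0):
        d[0] = 1.0
    res = wilcoxon_signed_rank(d, np.zeros(n))
    assert res.pvalue == pytest.approx(brute_force_two_sided_p(d),
                                       abs=1e-12)


def test_exact_p_matches_scipy_on_tie_free_data(rng):
    d = rng.normal(0.4, 1.0, 18)
    res = wilcoxon_signed_rank(d, np.zeros(18))
    ref = scipy.stats.wilcoxon(d, alternative="two-sided", method="exact")
    assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-12)
    assert res.statistic == pytest.approx(ref.statistic)


def test_normal_approximation_close_to_exact_at_n25():
    rng = np.random.default_rng(7)
    from lesionshape.stats import _approx_two_sided_p, _exact_two_sided_p
    for _ in range(50):
        d = rng.normal(0.3, 1.0, 25)
        ranks = scipy.stats.rankdata(np.abs(d))
        w = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        assert abs(_exact_two_sided_p(ranks, w)
                   - _approx_two_sided_p(ranks, w)) < 0.01


@given(st.lists(st.integers(min_value=-9, max_value=9), min_size=5,
                max_size=12).filter(lambda d: any(x != 0 for x in d)))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_wilcoxon_exact_p_properties(diffs):
    """Exact p equals enumeration, lies in (0, 1], and is sign-symmetric."""
    d = np.asarray(diffs, float)
    res = wilcoxon_signed_rank(d, np.zeros_like(d))
    if res.pvalue is None:
        return
    assert 0.0 < res.pvalue <= 1.0
    assert res.pvalue == pytest.approx(brute_force_two_sided_p(d),
                                       abs=1e-12)
    flipped = wilcoxon_signed_rank(-d, np.zeros_like(d))
    assert flipped.pvalue == pytest.approx(res.pvalue, abs=1e-12)
    assert flipped.statistic == pytest.approx(res.statistic)


def test_zero_differences_are_dropped():
    a = np.array([1.0, 2.0, 3.0, 3.0, 5.0, 6.0, 7.0])
    b = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    res = wilcoxon_signed_rank(a, b)
    assert res.n_effective == 5


def test_all_zero_differences_raise():
    with pytest.raises(DegenerateDifferencesError):
        wilcoxon_signed_rank(np.ones(6), np.ones(6))


def test_too_few_pairs_yield_undefined_p():
    res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]), np.zeros(3))
    assert res.pvalue is None
    assert res.method == "too-few-pairs"


# -- Bland-Altman -----------------------------------------------------------


def test_identical_pairs_give_zero_agreement_band():
    a = np.arange(5, dtype=float)
    res = bland_altman(a, a)
    assert (res.mean_diff, res.loa_low, res.loa_high, res.sd_diff) == \
        (0, 0, 0, 0)


def test_two_point_closed_form():
    res = bland_altman(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
    assert res.mean_diff == pytest.approx(0.0)
    assert res.sd_diff == pytest.approx(np.sqrt(2))
    assert res.loa_high == pytest.approx(1.96 * np.sqrt(2))


def test_gaussian_simulation_recovers_bias_and_limits(rng):
    b = rng.normal(0, 1, 10_000)
    a = b + rng.normal(0.5, 1.0, 10_000)
    res = bland_altman(a, b)
    assert res.mean_diff == pytest.approx(0.5, abs=0.05)
    assert res.loa_low == pytest.approx(0.5 - 1.96, abs=0.05)
    assert res.loa_high == pytest.approx(0.5 + 1.96, abs=0.05)
    d = a - b
    coverage = np.mean((d >= res.loa_low) & (d <= res.loa_high))
    assert 0.93 <= coverage <= 0.97


def test_single_pair_raises():
    with pytest.raises(StatsDomainError):
        bland_altman(np.array([1.0]), np.array([2.0]))


# -- cohort tables ----------------------------------------------------------


def synthetic_table(n=8, delta=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        sid = f"s{i:02d}"
        vol = rng.uniform(5, 60)
        for marker in MARKER_NAMES:
            base = vol if marker == "volume_ml" else rng.uniform(0.4, 2.0)
            rows.append((sid, marker, base + delta, base))
    return pd.DataFrame(rows, columns=[
        "subject_id", "marker", "value_highquality", "value_clinical"])


def test_sensitivity_filter_excludes_when_either_arm_is_small():
    rows = []
    for sid, vh, vc in [("a", 12.0, 9.9), ("b", 28.0, 24.33),
                        ("c", 9.0, 15.0), ("d", 40.0, 39.0),
                        ("e", 11.0, 11.0)]:
        rows.append((sid, "volume_ml", vh, vc))
        rows.append((sid, "convexity", 0.5, 0.6))
    table = pd.DataFrame(rows, columns=[
        "subject_id", "marker", "value_highquality", "value_clinical"])
    kept = sensitivity_filter(table, 10.0)
    assert set(kept["subject_id"]) == {"b", "d", "e"}
    unchanged = sensitivity_filter(table, 0.0)
    assert len(unchanged) == len(table)


def test_sensitivity_filter_requires_volume_rows():
    table = pd.DataFrame(
        [("a", "convexity", 0.5, 0.6)],
        columns=["subject_id", "marker", "value_highquality",
                 "value_clinical"])
    with pytest.raises(CohortError):
        sensitivity_filter(table, 10.0)


def test_paired_table_drops_incomplete_subjects():
    markers = pd.DataFrame([
        {"subject_id": "a", "condition": "highquality", "volume_ml": 10.0},
        {"subject_id": "a", "condition": "clinical", "volume_ml": 9.0},
        {"subject_id": "b", "condition": "highquality", "volume_ml": 12.0},
    ])
    table = paired_table_from_markers(markers)
    assert set(table["subject_id"]) == {"a"}


def test_compare_identical_conditions_flags_nothing():
    table = synthetic_table(n=8, delta=0.0)
    report = compare_cohort(table, alpha=0.05)
    assert not report.table["significant"].any()
    assert np.allclose(report.table["mean_diff"], 0.0)
    assert (report.table["method"] == "degenerate-all-zero").all()


def test_compare_cohort_detects_shift():
    table = synthetic_table(n=12, delta=0.3, seed=3)
    report = compare_cohort(table, alpha=0.05)
    assert report.table["significant"].all()
    assert (report.table["median_highquality"]
            > report.table["median_clinical"]).all()


def test_compare_cohort_alpha_zero_flags_nothing():
    table = synthetic_table(n=12, delta=0.3, seed=3)
    report = compare_cohort(table, alpha=0.0)
    assert not report.table["significant"].any()


def test_compare_cohort_is_permutation_invariant():
    table = synthetic_table(n=10, delta=0.2, seed=5)
    shuffled = table.sample(frac=1.0, random_state=11).reset_index(drop=True)
    r1 = compare_cohort(table)
    r2 = compare_cohort(shuffled)
    pd.testing.assert_frame_equal(r1.table, r2.table)


def test_compare_cohort_needs_five_subjects():
    with pytest.raises(StatsDomainError):
        compare_cohort(synthetic_table(n=4))
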
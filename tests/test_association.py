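"""Allelic association statistics, HWE exact test, QC, and adjustment."""

from __future__ import annotations

import math
from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from varprio.association import (
    QCParams,
    adjust_pvalues,
    allele_frequencies,
    allelic_chi_square,
    allelic_odds_ratio,
    hwe_exact_test,
    qc_filter,
    run_association,
)
from varprio.cohort_io import AlleleCountTable, MISSING

from conftest import cohort_from_dosages, dosages_for_count

tables = st.builds(
    AlleleCountTable,
    st.integers(0, 30),
    st.integers(0, 30),
    st.integers(0, 30),
    st.integers(0, 30),
)


def hwe_enumeration_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-rational enumeration of the conditional heterozygote law."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    common = 2 * n - rare
    probs: dict[int, Fraction] = {}
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = n - h - hr
        if hr < 0 or hc < 0:
            continue
        probs[h] = Fraction(
            factorial(n) * 2**h * factorial(rare) * factorial(common),
            factorial(hr) * factorial(h) * factorial(hc) * factorial(2 * n),
        )
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


class TestAllelicChiSquare:
    @pytest.mark.parametrize(
        "table, chi2_printed, ndigits",
        [
            ((11, 13, 0, 22), 13.25, 2),
            ((10, 12, 0, 22), 12.94, 2),
            ((9, 13, 0, 22), 11.31, 2),
            ((8, 14, 0, 22), 9.778, 3),
            ((2, 20, 12, 10), 10.48, 2),
            ((7, 15, 0, 22), 8.324, 3),
            ((0, 24, 6, 16), 7.527, 3),
            ((6, 16, 15, 7), 7.379, 3),
            ((8, 14, 1, 21), 6.844, 3),
            ((11, 11, 3, 19), 6.705, 3),
        ],
    )
    def test_published_values(self, table, chi2_printed, ndigits):
        chi2, _ = allelic_chi_square(AlleleCountTable(*table))
        assert round(chi2, ndigits) == chi2_printed

    def test_published_pvalue(self):
        _, p = allelic_chi_square(AlleleCountTable(2, 20, 12, 10))
        assert f"{p:.4f}" == "0.0012"

    def test_balanced_table_is_null(self):
        chi2, p = allelic_chi_square(AlleleCountTable(5, 5, 5, 5))
        assert chi2 == 0.0
        assert p == 1.0

    def test_zero_margin_undefined_not_crashing(self):
        chi2, p = allelic_chi_square(AlleleCountTable(0, 10, 0, 12))
        assert math.isnan(chi2) and math.isnan(p)

    @given(tables)
    def test_group_and_allele_swap_invariance(self, t):
        chi2, _ = allelic_chi_square(t)
        swapped_groups, _ = allelic_chi_square(AlleleCountTable(t.c, t.d, t.a, t.b))
        swapped_alleles, _ = allelic_chi_square(AlleleCountTable(t.b, t.a, t.d, t.c))
        if math.isnan(chi2):
            assert math.isnan(swapped_groups) and math.isnan(swapped_alleles)
        else:
            assert swapped_groups == pytest.approx(chi2)
            assert swapped_alleles == pytest.approx(chi2)

    @given(tables)
    def test_matches_pearson_expected_counts_formulation(self, t):
        """Cross-check against the independently coded expected-counts chi2."""
        chi2, p = allelic_chi_square(t)
        obs = np.array([[t.a, t.b], [t.c, t.d]])
        if math.isnan(chi2):
            assert (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any()
            return
        ref = chi2_contingency(obs, correction=False)
        assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    @given(tables)
    def test_p_decreasing_in_chi2(self, t):
        chi2, p = allelic_chi_square(t)
        if math.isnan(chi2):
            return
        if chi2 == 0:
            assert p == 1.0
        chi2b, pb = allelic_chi_square(AlleleCountTable(t.a + 5, t.b, t.c, t.d + 5))
        if not math.isnan(chi2b) and chi2b > chi2:
            assert pb < p


class TestOddsRatioAndFrequencies:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((8, 14, 1, 21), 12.0),
            ((7, 15, 0, 22), None),
            ((0, 24, 6, 16), 0.0),
            ((2, 20, 12, 10), 1 / 12),
            ((11, 11, 3, 19), 19 / 3),
            ((6, 16, 15, 7), 0.175),
            ((3, 3, 3, 3), 1.0),
        ],
    )
    def test_odds_ratio_convention(self, table, expected):
        or_ = allelic_odds_ratio(AlleleCountTable(*table))
        if expected is None:
            assert or_ is None
        else:
            assert or_ == pytest.approx(expected)

    @given(tables)
    def test_or_inverts_under_group_swap(self, t):
        or_ = allelic_odds_ratio(t)
        or_swap = allelic_odds_ratio(AlleleCountTable(t.c, t.d, t.a, t.b))
        if or_ is not None and or_swap is not None and or_ > 0:
            assert or_swap == pytest.approx(1 / or_)

    @pytest.mark.parametrize(
        "table, f_a, f_u",
        [
            ((2, 20, 12, 10), 0.0909, 0.5455),
            ((0, 24, 6, 16), 0.0, 0.2727),
            ((24, 0, 0, 22), 1.0, 0.0),
            ((7, 15, 0, 22), 0.3182, 0.0),
        ],
    )
    def test_unflipped_alt_frequencies(self, table, f_a, f_u):
        got_a, got_u = allele_frequencies(AlleleCountTable(*table))
        assert round(got_a, 4) == f_a
        assert round(got_u, 4) == f_u

    def test_zero_denominator_flagged_as_nan(self):
        f_a, f_u = allele_frequencies(AlleleCountTable(0, 0, 3, 19))
        assert math.isnan(f_a) and f_u == pytest.approx(3 / 22)


class TestHweExactTest:
    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(0, 0, 23) == 1.0
        assert hwe_exact_test(23, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [(5, 10, 5), (10, 0, 10), (1, 1, 1), (12, 8, 3), (0, 5, 20), (7, 0, 2)],
    )
    def test_equals_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12
        )

    def test_all_homozygote_extreme_is_deep_tail(self):
        """An all-homozygote split of 20 alleles has essentially no HWE
        support; the exact two-sided p matches the enumeration oracle."""
        p = hwe_exact_test(10, 0, 10)
        assert p == pytest.approx(hwe_enumeration_oracle(10, 0, 10), rel=1e-9)
        assert p < 1e-5

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    def test_is_a_probability(self, hr, h, ha):
        p = hwe_exact_test(hr, h, ha)
        assert 0.0 < p <= 1.0


class TestAdjustPvalues:
    def test_single_pvalue_unchanged(self):
        assert adjust_pvalues([0.01], "bh") == [pytest.approx(0.01)]
        assert adjust_pvalues([0.01], "bonferroni") == [pytest.approx(0.01)]

    def test_bh_step_up_hand_oracle(self):
        # hand-worked: raw*m/rank = [.004, .02, .04, .04]; running min from
        # the largest rank keeps them as-is
        got = adjust_pvalues([0.001, 0.01, 0.03, 0.04], "bh")
        assert got == pytest.approx([0.004, 0.02, 0.04, 0.04])

    def test_bh_preserves_input_order(self):
        got = adjust_pvalues([0.04, 0.001, 0.03, 0.01], "bh")
        assert got == pytest.approx([0.04, 0.004, 0.04, 0.02])

    def test_bonferroni_kills_borderline_family(self):
        got = adjust_pvalues([0.004] * 13, "bonferroni")
        assert all(p == pytest.approx(0.052) for p in got)
        assert all(p > 0.05 for p in got)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2], "bh")

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_bonferroni_ge_bh_ge_raw(self, pvals):
        bh = adjust_pvalues(pvals, "bh")
        bonf = adjust_pvalues(pvals, "bonferroni")
        for raw, x, y in zip(pvals, bh, bonf):
            assert y >= x - 1e-12 >= raw - 2e-12

    def test_bh_monotone_in_raw_order(self):
        raw = [0.001, 0.002, 0.01, 0.2, 0.6]
        bh = adjust_pvalues(raw, "bh")
        assert bh == sorted(bh)


class TestQcFilter:
    def test_missingness_rule(self):
        col = [0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        gt, ph = cohort_from_dosages([col], [[MISSING] * 3 + [0] * 8])
        out, failures = qc_filter(gt, ph)
        assert out.n_variants == 0
        assert failures[0].rule == "missingness"
        assert failures[0].value == pytest.approx(3 / 23)

    def test_maf_rule(self):
        gt, ph = cohort_from_dosages([[1, 1] + [0] * 10], [[0] * 11])
        out, failures = qc_filter(gt, ph)
        assert failures[0].rule == "maf"
        assert failures[0].value == pytest.approx(2 / 46)

    def test_hwe_rule(self):
        # 12 hom-alt cases + 11 hom-ref controls: no heterozygotes at all
        gt, ph = cohort_from_dosages([[2] * 12], [[0] * 11])
        params = QCParams(hwe_p_threshold=1e-4)
        out, failures = qc_filter(gt, ph, params)
        assert failures and failures[0].rule == "hwe"

    def test_clean_variant_retained(self):
        gt, ph = cohort_from_dosages(
            [[1] * 6 + [0] * 6], [[1] * 5 + [0] * 6]
        )
        out, failures = qc_filter(gt, ph)
        assert out.n_variants == 1 and not failures


class TestRunAssociation:
    def test_planted_variant_ranks_first(self, rng):
        planted = dosages_for_count(11, 12)
        null_cols = [list(rng.integers(0, 3, size=12)) for _ in range(20)]
        null_ctrl = [list(rng.integers(0, 3, size=11)) for _ in range(20)]
        gt, ph = cohort_from_dosages(
            [planted] + null_cols, [[0] * 11] + null_ctrl
        )
        results = run_association(gt, ph)
        top = results[0]
        assert top.counts == AlleleCountTable(11, 13, 0, 22)
        assert round(top.chi2, 2) == 13.25

    def test_empty_after_qc(self):
        gt, ph = cohort_from_dosages([[MISSING] * 12], [[MISSING] * 11])
        assert run_association(gt, ph) == []

    def test_label_swap_inverts_odds_ratio(self):
        gt, ph = cohort_from_dosages(
            [[1] * 8 + [0] * 4], [[1] * 2 + [0] * 9]
        )
        fwd = run_association(gt, ph)[0]
        rev = run_association(gt, ph.swapped())[0]
        assert rev.chi2 == pytest.approx(fwd.chi2)
        assert rev.odds_ratio == pytest.approx(1 / fwd.odds_ratio)

    def test_adjusted_pvalues_attached_and_ordered(self):
        gt, ph = cohort_from_dosages(
            [dosages_for_count(11, 12), [1] * 6 + [0] * 6],
            [[0] * 11, [1] * 5 + [0] * 6],
        )
        results = run_association(gt, ph)
        for r in results:
            assert r.p_adj_bh >= r.p - 1e-12
            assert r.p_adj_bonferroni >= r.p_adj_bh - 1e-12
        assert [r.p for r in results] == sorted(r.p for r in results)
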
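"""Statistical conventions: quartiles, percentages, nonparametric tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dairysim import (
    DomainError,
    chi_square_independence,
    kruskal_wallis,
    mann_whitney,
    mcnemar,
    percent,
    pp_change,
    quartiles,
    round_half_up,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# Quartiles
# ---------------------------------------------------------------------------


class TestQuartiles:
    def test_type6_matches_r_oracle(self):
        # R: quantile(1:5, type=6) -> 1.5, 3, 4.5
        qs = quartiles([1, 2, 3, 4, 5], method="type6")
        assert (qs.p25, qs.p50, qs.p75) == (1.5, 3.0, 4.5)

    def test_tukey_hinges(self):
        qs = quartiles([1, 2, 3, 4, 5], method="hinges")
        assert (qs.p25, qs.p50, qs.p75) == (2.0, 3.0, 4.0)

    def test_singleton_and_constant(self):
        assert quartiles([7]).formatted() == "7.00 (7.00, 7.00)"
        assert quartiles([1, 1, 1, 1]).formatted() == "1.00 (1.00, 1.00)"

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            quartiles([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariant(self, values, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        a, b = quartiles(values), quartiles(shuffled)
        assert (a.p25, a.p50, a.p75) == (b.p25, b.p50, b.p75)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
           st.floats(0, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_monotone_under_componentwise_increase(self, values, shift):
        lo, hi = quartiles(values), quartiles([v + shift for v in values])
        assert hi.p50 >= lo.p50 - 1e-9
        assert hi.p25 >= lo.p25 - 1e-9
        assert hi.p75 >= lo.p75 - 1e-9


# ---------------------------------------------------------------------------
# Percent conventions
# ---------------------------------------------------------------------------


class TestPercentConventions:
    @pytest.mark.parametrize(
        "count, n, expected",
        [
            (597, 676, 88.31),
            (622, 676, 92.01),
            (619, 676, 91.57),
            (666, 676, 98.52),
            (0, 676, 0.00),
            (112, 224, 50.00),
            (95, 226, 42.04),
            (70, 226, 30.97),
        ],
    )
    def test_printed_pairs(self, count, n, expected):
        assert percent(count, n) == expected

    def test_half_up_not_bankers(self):
        # 0.125 -> 0.13 under half-up; banker's would give 0.12
        assert round_half_up(0.125, 2) == 0.13
        assert percent(1, 800) == 0.13

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            percent(1, 0)
        with pytest.raises(DomainError):
            percent(5, 4)

    @pytest.mark.parametrize(
        "before, after, expected",
        [
            (91.57, 75.44, 16.13),  # rounded-operand convention: raw gives 16.12
            (91.57, 64.35, 27.22),
            (68.79, 55.47, 13.32),
            (68.79, 67.16, 1.63),
            (42.42, 42.42, 0.00),
        ],
    )
    def test_pp_change(self, before, after, expected):
        assert pp_change(before, after) == expected

    def test_rounded_operand_convention_differs_from_raw_counts(self):
        # unrounded 100*(619-510)/676 = 16.124 -> 16.12, but the printed
        # convention differences the rounded percentages: 16.13
        raw = round_half_up(100 * (619 - 510) / 676, 2)
        assert raw == 16.12
        assert pp_change(percent(619, 676), percent(510, 676)) == 16.13


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def exact_signed_rank_p(d):
    """Brute-force oracle: enumerate all sign patterns of |d| ranks."""
    import itertools

    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    totals = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product((0, 1), repeat=len(d))
    ]
    totals = np.asarray(totals)
    return min(1.0, 2 * min((totals <= w_obs + 1e-12).mean(),
                            (totals >= w_obs - 1e-12).mean()))


class TestWilcoxon:
    def test_all_positive_differences_spss_z(self):
        # d = [1..5]: W+ = 15, z = 7.5/sqrt(13.75) = 2.0226, p = 0.0431
        res = wilcoxon_signed_rank([0] * 5, [1, 2, 3, 4, 5])
        assert res.n_effective == 5
        assert res.statistic == pytest.approx(2.0226, abs=1e-4)
        assert res.p_value == pytest.approx(0.0431, abs=1e-3)

    def test_all_positive_differences_exact(self):
        res = wilcoxon_signed_rank([0] * 5, [1, 2, 3, 4, 5], method="exact")
        assert res.p_value == pytest.approx(2 / 32)

    def test_antisymmetric_differences_null(self):
        res = wilcoxon_signed_rank([0, 0, 0, 0], [1, -1, 2, -2])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_differences_error(self):
        with pytest.raises(DomainError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_zeros_dropped(self):
        # zero differences reduce n_effective (SPSS 'wilcox' convention)
        res = wilcoxon_signed_rank([1, 5, 5, 5], [2, 5, 5, 5])
        assert res.n_effective == 1

    def test_matches_scipy_approx_convention(self):
        rng = np.random.default_rng(7)
        before = rng.normal(size=40)
        after = before + rng.normal(0.3, 1.0, size=40)
        ours = wilcoxon_signed_rank(before, after)
        ref = sps.wilcoxon(after, before, zero_method="wilcox",
                           correction=False, mode="approx")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_mode_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(-5, 6, size=8)
        d[d == 0] = 1
        res = wilcoxon_signed_rank(np.zeros(8), d, method="exact")
        assert res.p_value == pytest.approx(exact_signed_rank_p(d), abs=1e-9)


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------


def flags_from_counts(b, c, both=5, neither=5):
    before = [True] * (b + both) + [False] * (c + neither)
    after = [False] * b + [True] * both + [True] * c + [False] * neither
    return before, after


class TestMcNemar:
    def test_exact_one_sided_discordance(self):
        before, after = flags_from_counts(b=10, c=0)
        res = mcnemar(before, after)
        assert res.n_effective == 10
        assert res.p_value == pytest.approx(2 * 0.5**10)

    def test_symmetric_discordance_capped(self):
        before, after = flags_from_counts(b=5, c=5)
        assert mcnemar(before, after).p_value == 1.0

    def test_chi2_branch_continuity_corrected(self):
        before, after = flags_from_counts(b=30, c=10)
        res = mcnemar(before, after)
        assert res.statistic == pytest.approx(9.025)
        assert res.p_value == pytest.approx(sps.chi2.sf(9.025, 1))

    def test_degenerate_no_discordance(self):
        res = mcnemar([True, False], [True, False])
        assert res.degenerate and res.p_value == 1.0 and res.n_effective == 0

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(3, 1), (8, 12), (20, 30)]:
            before, after = flags_from_counts(b=b, c=c)
            ours = mcnemar(before, after)
            table = [[5, b], [c, 5]]
            ref = sm_mcnemar(table, exact=b + c < 25, correction=True)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# Kruskal-Wallis / Mann-Whitney / chi-square
# ---------------------------------------------------------------------------


class TestGroupTests:
    def test_kruskal_hand_value(self):
        res = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert res.statistic == pytest.approx(7.2)
        assert res.df == 2

    def test_kruskal_identical_groups(self):
        res = kruskal_wallis([1.0, 1.0], [1.0, 1.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_kruskal_needs_two_groups(self):
        with pytest.raises(DomainError):
            kruskal_wallis([1, 2, 3])

    def test_kruskal_two_groups_consistent_with_mann_whitney(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=15), rng.normal(0.8, 1, size=15)
        kw = kruskal_wallis(a, b)
        mw = mann_whitney(a, b, method="asymptotic")
        # H = z^2 for two groups; chi2(1) p equals two-sided normal p
        assert kw.p_value == pytest.approx(mw.p_value, rel=1e-6)

    def test_mann_whitney_exact_separated(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_mann_whitney_identical_multisets(self):
        assert mann_whitney([1, 2, 2, 3], [1, 2, 2, 3]).p_value == pytest.approx(1.0)

    def test_mann_whitney_shift_invariance(self):
        a, b = [1.0, 2.5, 3.0, 9.0], [2.0, 4.0, 8.0]
        r1 = mann_whitney(a, b)
        r2 = mann_whitney([x + 100 for x in a], [x + 100 for x in b])
        assert r1.statistic == r2.statistic and r1.p_value == r2.p_value

    def test_mann_whitney_exact_matches_scipy(self):
        rng = np.random.default_rng(11)
        a = rng.permutation(np.arange(14))[:6].astype(float)
        b = rng.permutation(np.arange(100, 114))[:6].astype(float)
        ours = mann_whitney(a, b, method="exact")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_chi_square_proportional_table(self):
        res = chi_square_independence([[10, 20], [5, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_chi_square_diagonal(self):
        res = chi_square_independence([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1

    def test_chi_square_age_by_subtype(self):
        # milk-powder consumers by age stratum: clearly age-dependent
        res = chi_square_independence(
            [[112, 112], [95, 131], [70, 156]]
        )
        assert res.df == 2
        assert res.p_value < 0.001

    def test_chi_square_zero_margin(self):
        with pytest.raises(DomainError):
            chi_square_independence([[0, 0], [1, 2]])
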
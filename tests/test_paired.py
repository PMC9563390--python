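"""McNemar statistics, exact p enumeration, and discordant-pair ORs."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from comorbscreen import (PairedTable, discordant_or, mcnemar_test,
                          paired_table_from_vectors)
from comorbscreen.paired import mcnemar_pvalues


def exact_binomial_oracle(b, c):
    """Two-sided exact McNemar p by direct enumeration of the
    Binomial(b+c, 1/2) null: sum the smaller tail with math.comb and
    double it (capped at 1)."""
    n = b + c
    k = min(b, c)
    tail = sum(math.comb(n, j) for j in range(k + 1)) / 2 ** n
    return min(1.0, 2.0 * tail)


class TestPairedTable:
    def test_collapse_enumerates_the_four_patterns(self):
        t = paired_table_from_vectors([1, 1, 0, 0], [1, 0, 1, 0])
        assert (t.n11, t.n10, t.n01, t.n00) == (1, 1, 1, 1)
        assert t.n_pairs == 4

    def test_all_concordant_negative(self):
        t = paired_table_from_vectors([0] * 5, [0] * 5)
        assert (t.n11, t.n10, t.n01, t.n00) == (0, 0, 0, 5)

    def test_duplicated_pairs_double_counts(self):
        case, ctrl = [1, 0, 1], [0, 0, 1]
        t1 = paired_table_from_vectors(case, ctrl)
        t2 = paired_table_from_vectors(case * 2, ctrl * 2)
        assert (t2.n11, t2.n10, t2.n01, t2.n00) == \
            (2 * t1.n11, 2 * t1.n10, 2 * t1.n01, 2 * t1.n00)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            PairedTable(0, -1, 2, 0)


class TestMcNemar:
    def test_chi2_statistic_hand_value(self):
        stat, p = mcnemar_test(PairedTable(0, 120, 2, 0), mode="chi2")
        assert stat == pytest.approx(118 ** 2 / 122)
        assert stat == pytest.approx(114.13, abs=0.005)

    def test_symmetric_table_gives_zero_statistic(self):
        stat, p = mcnemar_test(PairedTable(3, 5, 5, 7), mode="chi2")
        assert stat == 0.0
        assert p == 1.0

    def test_exact_small_table(self):
        stat, p = mcnemar_test(PairedTable(0, 3, 0, 0), mode="exact")
        assert p == pytest.approx(0.25)
        assert stat == 0

    def test_no_discordant_pairs_degenerate_not_raised(self):
        assert mcnemar_test(PairedTable(4, 0, 0, 6)) == (0.0, 1.0)

    def test_statistic_ignores_concordant_cells(self):
        s1, p1 = mcnemar_test(PairedTable(0, 30, 10, 0), mode="chi2")
        s2, p2 = mcnemar_test(PairedTable(500, 30, 10, 900), mode="chi2")
        assert (s1, p1) == (s2, p2)

    def test_continuity_corrected_variant(self):
        stat, _ = mcnemar_test(PairedTable(0, 30, 10, 0), mode="chi2_corrected")
        assert stat == pytest.approx((abs(30 - 10) - 1) ** 2 / 40)

    @given(st.integers(0, 12), st.integers(0, 12))
    def test_exact_p_matches_binomial_enumeration(self, b, c):
        if b + c == 0:
            return
        _, p = mcnemar_test(PairedTable(0, b, c, 0), mode="exact")
        assert p == pytest.approx(exact_binomial_oracle(b, c))

    def test_auto_mode_switches_on_discordant_total(self):
        small = PairedTable(0, 10, 5, 0)  # b+c = 15 < 25 -> exact
        assert mcnemar_test(small)[1] == mcnemar_test(small, "exact")[1]
        big = PairedTable(0, 20, 10, 0)  # b+c = 30 -> chi2
        assert mcnemar_test(big)[1] == mcnemar_test(big, "chi2")[1]

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(120, 2), (30, 18), (7, 3)]:
            table = [[0, b], [c, 0]]
            stat, p = mcnemar_test(PairedTable(0, b, c, 0), mode="chi2")
            sm = sm_mcnemar(table, exact=False, correction=False)
            assert p == pytest.approx(sm.pvalue)
            _, p_ex = mcnemar_test(PairedTable(0, b, c, 0), mode="exact")
            sm_ex = sm_mcnemar(table, exact=True)
            assert p_ex == pytest.approx(sm_ex.pvalue)

    def test_vectorised_pvalues_match_scalar(self):
        rng = np.random.default_rng(3)
        b = rng.integers(0, 60, size=200)
        c = rng.integers(0, 60, size=200)
        stat, p = mcnemar_pvalues(b, c)
        for i in range(200):
            s_i, p_i = mcnemar_test(PairedTable(0, int(b[i]), int(c[i]), 0))
            assert stat[i] == pytest.approx(s_i)
            assert p[i] == pytest.approx(p_i)


class TestDiscordantOR:
    @pytest.mark.parametrize("b, c, or_, lcl, ucl", [
        (120, 2, 60.0, 14.83, 242.69),
        (132, 6, 22.0, 9.71, 49.86),
        (88, 5, 17.6, 7.15, 43.34),
        (1553, 129, 12.04, 10.06, 14.41),
    ])
    def test_wald_ci_reproduces_printed_bounds(self, b, c, or_, lcl, ucl):
        est = discordant_or(PairedTable(0, b, c, 0))
        assert round(est.odds_ratio, 2) == or_
        assert round(est.ci_lower, 2) == lcl
        assert round(est.ci_upper, 2) == ucl
        assert est.degenerate_flag == "ok"

    @given(st.integers(1, 500))
    def test_equal_cells_give_unit_or_with_log_symmetric_ci(self, k):
        est = discordant_or(PairedTable(0, k, k, 0))
        assert est.odds_ratio == 1.0
        assert est.ci_lower * est.ci_upper == pytest.approx(1.0)

    @given(st.integers(1, 300), st.integers(1, 300))
    def test_swapping_cells_inverts_or_and_ci(self, b, c):
        fwd = discordant_or(PairedTable(0, b, c, 0))
        rev = discordant_or(PairedTable(0, c, b, 0))
        assert fwd.odds_ratio * rev.odds_ratio == pytest.approx(1.0)
        assert fwd.ci_lower == pytest.approx(1.0 / rev.ci_upper)
        assert fwd.ci_upper == pytest.approx(1.0 / rev.ci_lower)

    @given(st.integers(1, 300), st.integers(1, 300))
    def test_ci_contains_or_and_widens_with_z(self, b, c):
        narrow = discordant_or(PairedTable(0, b, c, 0), z=1.0)
        wide = discordant_or(PairedTable(0, b, c, 0), z=2.5)
        assert narrow.ci_lower <= narrow.odds_ratio <= narrow.ci_upper
        assert wide.ci_lower < narrow.ci_lower
        assert wide.ci_upper > narrow.ci_upper

    def test_zero_cell_flagged_nan_by_default(self):
        est = discordant_or(PairedTable(0, 5, 0, 0))
        assert est.degenerate_flag == "zero_cell"
        assert math.isnan(est.odds_ratio)

    def test_zero_cell_continuity_correction_opt_in(self):
        est = discordant_or(PairedTable(0, 5, 0, 0), continuity=True)
        assert est.degenerate_flag == "zero_cell"
        assert est.odds_ratio == pytest.approx(5.5 / 0.5)
        assert est.ci_lower < est.odds_ratio < est.ci_upper

    def test_no_discordant_flag(self):
        est = discordant_or(PairedTable(9, 0, 0, 1))
        assert est.degenerate_flag == "no_discordant"
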
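import math

import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2 as chi2_dist

from cinemort.causes import CAUSE_CODES
from cinemort.reference import CauseRow, MortalityTable, gender_proportion, load_reference
from cinemort.stats import (
    applicability,
    film_table_from_gender_counts,
    format_p,
    gender_gof_chisq,
    gender_independence_chisq,
    overall_shares,
    run_battery,
)


def oracle_gof(observed_men, observed_women, p_men):
    """Independent two-cell goodness-of-fit oracle: plain sum of (O-E)^2/E."""
    n = observed_men + observed_women
    e_men = n * p_men
    e_women = n * (1.0 - p_men)
    stat = (observed_men - e_men) ** 2 / e_men + (observed_women - e_women) ** 2 / e_women
    return stat, chi2_dist.sf(stat, df=1)


class TestGenderGofChisq:
    def test_published_heart_statistic(self, reference):
        p_men, _ = gender_proportion(reference, "heart")
        chi2, df, p = gender_gof_chisq(477, 171, p_men)
        assert round(chi2, 2) == 87.57
        assert df == 1
        assert p < 0.001

    def test_published_suicide_statistic(self, reference):
        p_men, _ = gender_proportion(reference, "suicide")
        chi2, _, p = gender_gof_chisq(1437, 945, p_men)
        assert round(chi2, 2) == 545.54
        assert p < 0.001
        # cross-check against the independent oracle
        o_stat, o_p = oracle_gof(1437, 945, p_men)
        assert math.isclose(chi2, o_stat, abs_tol=1e-10)
        assert math.isclose(p, o_p, abs_tol=1e-12)

    def test_published_cerebrovascular_statistic(self, reference):
        p_men, _ = gender_proportion(reference, "cerebrovascular")
        chi2, _, _ = gender_gof_chisq(50, 22, p_men)
        assert round(chi2, 2) == 19.72

    def test_published_accidents_statistic_within_rounding(self, reference):
        p_men, _ = gender_proportion(reference, "accidents")
        chi2, _, _ = gender_gof_chisq(765, 485, p_men)
        assert abs(chi2 - 15.81) <= 0.02

    def test_null_case_is_zero(self):
        chi2, _, p = gender_gof_chisq(30, 70, 0.3)
        assert math.isclose(chi2, 0.0, abs_tol=1e-12)
        assert math.isclose(p, 1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            gender_gof_chisq(0, 0, 0.5)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_reference_proportion_rejected(self, p):
        with pytest.raises(ValueError):
            gender_gof_chisq(10, 10, p)

    @settings(max_examples=300)
    @given(
        men=st.integers(min_value=0, max_value=10_000),
        women=st.integers(min_value=0, max_value=10_000),
        p=st.floats(min_value=0.01, max_value=0.99),
    )
    def test_agrees_with_oracle(self, men, women, p):
        if men + women == 0:
            return
        chi2, df, p_val = gender_gof_chisq(men, women, p)
        o_stat, o_p = oracle_gof(men, women, p)
        assert df == 1
        assert math.isclose(chi2, o_stat, rel_tol=0, abs_tol=1e-10)
        assert math.isclose(p_val, o_p, rel_tol=1e-9, abs_tol=1e-12)

    @given(
        men=st.integers(min_value=0, max_value=5_000),
        women=st.integers(min_value=0, max_value=5_000),
        p=st.floats(min_value=0.01, max_value=0.99),
    )
    def test_swap_invariance(self, men, women, p):
        if men + women == 0:
            return
        a, _, _ = gender_gof_chisq(men, women, p)
        b, _, _ = gender_gof_chisq(women, men, 1.0 - p)
        assert math.isclose(a, b, rel_tol=1e-12, abs_tol=1e-9)

    def test_monotone_in_distance_from_reference(self):
        n, p = 200, 0.35
        stats_above = [gender_gof_chisq(m, n - m, p)[0] for m in range(70, n + 1)]
        assert all(b >= a - 1e-9 for a, b in zip(stats_above, stats_above[1:]))
        stats_below = [gender_gof_chisq(m, n - m, p)[0] for m in range(70, -1, -1)]
        assert all(b >= a - 1e-9 for a, b in zip(stats_below, stats_below[1:]))

    def test_diverges_from_independence_test_for_suicide(self, reference):
        # the one-sample reading reproduces the published value; the 2x2 does not
        row = reference["suicide"]
        p_men, _ = gender_proportion(reference, "suicide")
        gof_stat, _, _ = gender_gof_chisq(1437, 945, p_men)
        ind_stat, _, _ = gender_independence_chisq(1437, 945, row.men, row.women)
        assert round(gof_stat, 2) == 545.54
        assert abs(ind_stat - 545.54) > 10


class TestApplicability:
    @pytest.mark.parametrize("count,ok", [(0, False), (4, False), (5, True), (6, True), (72, True)])
    def test_threshold(self, count, ok):
        assert applicability(count) is ok

    def test_custom_threshold(self):
        assert applicability(9, threshold=10) is False

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            applicability(-1)


class TestOverallShares:
    def _table(self, totals, population_id="t"):
        rows = [CauseRow(c, totals.get(c, 0), 0, totals.get(c, 0)) for c in CAUSE_CODES]
        return MortalityTable(rows=rows, population_id=population_id)

    def test_identity_distribution(self, reference):
        shares = overall_shares(reference, reference)
        for s in shares:
            assert math.isclose(s.representation_ratio, 1.0)

    def test_hand_arithmetic(self):
        film = self._table({"suicide": 50, "heart": 50})
        ref = self._table({"suicide": 10, "heart": 90})
        by_cause = {s.cause: s for s in overall_shares(film, ref)}
        assert math.isclose(by_cause["suicide"].representation_ratio, 5.0)
        assert math.isclose(by_cause["heart"].representation_ratio, 0.5 / 0.9)

    def test_shares_sum_to_one(self, reference):
        film = self._table({"suicide": 30, "heart": 20, "other": 50})
        shares = overall_shares(film, reference)
        assert math.isclose(sum(s.share_film for s in shares), 1.0)
        assert math.isclose(sum(s.share_ref for s in shares), 1.0)

    def test_zero_reference_share_flagged(self):
        film = self._table({"suicide": 5, "heart": 5})
        ref = self._table({"suicide": 10, "heart": 0, "cancer": 10})
        by_cause = {s.cause: s for s in overall_shares(film, ref)}
        assert by_cause["heart"].representation_ratio is None

    def test_empty_film_table_rejected(self, reference):
        with pytest.raises(ValueError, match="empty"):
            overall_shares(self._table({}), reference)

    def test_ratio_above_one_iff_film_share_larger(self, reference):
        film = self._table({"suicide": 60, "heart": 40})
        for s in overall_shares(film, reference):
            if s.representation_ratio is not None and s.share_ref > 0:
                assert (s.representation_ratio > 1) == (s.share_film > s.share_ref)


class TestRunBattery:
    def test_all_below_threshold(self, reference):
        film = film_table_from_gender_counts({"heart": (2, 1), "suicide": (1, 2)})
        results = run_battery(film, reference)
        assert all(not r.applicable for r in results)
        assert all(r.chi2 is None and r.p_value is None for r in results)

    def test_published_four_causes(self, reference):
        film = film_table_from_gender_counts(
            {
                "heart": (477, 171),
                "cerebrovascular": (50, 22),
                "suicide": (1437, 945),
                "accidents": (765, 485),
            }
        )
        by_cause = {r.cause: r for r in run_battery(film, reference)}
        assert round(by_cause["heart"].chi2, 2) == 87.57
        assert round(by_cause["cerebrovascular"].chi2, 2) == 19.72
        assert round(by_cause["suicide"].chi2, 2) == 545.54
        assert abs(by_cause["accidents"].chi2 - 15.81) <= 0.02
        for cause in ("heart", "cerebrovascular", "suicide", "accidents"):
            r = by_cause[cause]
            assert r.applicable and r.df == 1 and r.p_value < 0.001

    def test_ordering_matches_display_names(self, reference):
        film = film_table_from_gender_counts({"heart": (10, 10)})
        results = run_battery(film, reference)
        names = [r.cause for r in results]
        # ASCII display-name order: Accidents first, COVID-19 before Cancer
        assert names[0] == "accidents"
        assert names.index("covid19") < names.index("cancer")
        assert len(results) == len(CAUSE_CODES)

    def test_extra_film_cause_rejected(self, reference):
        film = MortalityTable(rows=[CauseRow("heart", 10, 5, 5), CauseRow("cancer", 3, 2, 1)])
        # vocabulary mismatch surfaces via overall_shares' shared-vocabulary check
        with pytest.raises(ValueError):
            run_battery(film, reference)

    def test_unknown_method_rejected(self, reference):
        film = film_table_from_gender_counts({"heart": (10, 10)})
        with pytest.raises(ValueError, match="method"):
            run_battery(film, reference, method="bayes")


class TestFormatP:
    @pytest.mark.parametrize(
        "p,display",
        [(None, "—"), (0.0005, "<.001"), (0.59, ".590"), (0.001, ".001"), (0.0499, ".050")],
    )
    def test_display(self, p, display):
        assert format_p(p) == display
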
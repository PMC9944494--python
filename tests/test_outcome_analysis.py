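"""Odds ratios, mortality summaries, chi-square and ANOVA comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hrsclust as hc
from hrsclust.outcome_analysis import round_half_away


def cohort_from_counts(cluster_counts):
    """Minimal cohort with exact per-cluster (deaths, survivors) counts."""
    labels, outcome = [], []
    for cluster, (deaths, survivors) in cluster_counts.items():
        labels += [cluster] * (deaths + survivors)
        outcome += [1] * deaths + [0] * survivors
    n = len(labels)
    index = pd.RangeIndex(n, name="admission_id")
    data = pd.DataFrame({"Marker": np.zeros(n, dtype=int)}, index=index)
    cohort = hc.CohortTable(
        data=data,
        variables=[hc.VariableSpec("Marker", "binary")],
        outcome=pd.Series(outcome, index=index),
    )
    return cohort, np.array(labels)


# printed per-cluster mortality: deaths / survivors
PUBLISHED = {1: (545, 1072), 2: (392, 1185), 3: (449, 193), 4: (470, 1258)}


class TestOddsRatio:
    @pytest.mark.parametrize(
        "table,expected",
        [
            (hc.TwoByTwo(449, 193, 392, 1185), 7.03),
            (hc.TwoByTwo(545, 1072, 392, 1185), 1.53),
            (hc.TwoByTwo(470, 1258, 392, 1185), 1.13),
        ],
    )
    def test_published_mortality_contrasts(self, table, expected):
        result = hc.odds_ratio(table)
        assert result.or_point == pytest.approx(expected, abs=0.01)

    def test_woolf_interval_for_highest_risk_cluster(self):
        result = hc.odds_ratio(hc.TwoByTwo(449, 193, 392, 1185))
        assert result.ci_low == pytest.approx(5.73, abs=0.01)
        assert result.ci_high == pytest.approx(8.62, abs=0.01)

    def test_identical_rows_give_unit_or_with_symmetric_ci(self):
        result = hc.odds_ratio(hc.TwoByTwo(30, 70, 30, 70))
        assert result.or_point == pytest.approx(1.0)
        assert math.log(result.ci_low) == pytest.approx(-math.log(result.ci_high))

    def test_zero_cell_requires_correction(self):
        with pytest.raises(ValueError, match="zero cell"):
            hc.odds_ratio(hc.TwoByTwo(0, 10, 5, 5))
        corrected = hc.odds_ratio(
            hc.TwoByTwo(0, 10, 5, 5), continuity_correction=True
        )
        assert corrected.or_point > 0

    @given(st.integers(1, 500), st.integers(1, 500),
           st.integers(1, 500), st.integers(1, 500))
    def test_reciprocal_and_scaling_invariance(self, a, b, c, d):
        forward = hc.odds_ratio(hc.TwoByTwo(a, b, c, d)).or_point
        backward = hc.odds_ratio(hc.TwoByTwo(c, d, a, b)).or_point
        assert forward * backward == pytest.approx(1.0, rel=1e-12)
        scaled = hc.odds_ratio(hc.TwoByTwo(3 * a, 3 * b, 3 * c, 3 * d)).or_point
        assert scaled == pytest.approx(forward, rel=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            hc.TwoByTwo(-1, 5, 5, 5)


class TestMortalityByCluster:
    def test_published_percentages(self):
        cohort, labels = cohort_from_counts(PUBLISHED)
        table = hc.mortality_by_cluster(cohort, labels)
        assert table.loc[3, "percent"] == 70.0
        assert table.loc[2, "percent"] == 25.0
        assert table.loc[1, "percent"] == 34.0
        assert table.loc[4, "percent"] == 27.0
        assert table.loc["overall", "percent"] == 33.0
        assert table.loc["overall", "deaths"] == 545 + 392 + 449 + 470

    def test_all_survivors(self):
        cohort, labels = cohort_from_counts({1: (0, 10), 2: (0, 5)})
        table = hc.mortality_by_cluster(cohort, labels)
        assert (table["percent"] == 0.0).all()

    def test_missing_outcome_rejected(self):
        cohort, labels = cohort_from_counts({1: (1, 1)})
        cohort.outcome = None
        with pytest.raises(ValueError, match="outcome"):
            hc.mortality_by_cluster(cohort, labels)


class TestReferenceCluster:
    def test_lowest_mortality_wins(self):
        cohort, labels = cohort_from_counts(PUBLISHED)
        table = hc.mortality_by_cluster(cohort, labels)
        assert hc.reference_cluster(table) == 2

    def test_tie_breaks_to_lower_label(self):
        cohort, labels = cohort_from_counts({1: (1, 9), 2: (1, 9), 3: (5, 5)})
        table = hc.mortality_by_cluster(cohort, labels)
        assert hc.reference_cluster(table) == 1

    def test_full_table_against_reference(self):
        cohort, labels = cohort_from_counts(PUBLISHED)
        table = hc.odds_ratios_vs_reference(cohort, labels)
        assert table.loc[2, "reference"]
        assert table.loc[3, "odds_ratio"] == pytest.approx(7.03, abs=0.01)
        assert table.loc[1, "odds_ratio"] == pytest.approx(1.53, abs=0.01)
        assert table.loc[4, "odds_ratio"] == pytest.approx(1.13, abs=0.01)


class TestChiSquare:
    def test_identical_distributions(self):
        stat, df, p = hc.chisq_homogeneity([[10, 10], [10, 10]])
        assert stat == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_published_mortality_table_is_significant(self):
        table = [[545, 1072], [392, 1185], [449, 193], [470, 1258]]
        stat, df, p = hc.chisq_homogeneity(table)
        assert df == 3
        assert p < 0.001

    @given(
        st.lists(
            st.lists(st.integers(1, 200), min_size=2, max_size=4),
            min_size=2,
            max_size=5,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_matches_hand_computed_statistic(self, rows):
        observed = np.array(rows, dtype=float)
        stat, df, _ = hc.chisq_homogeneity(observed)
        # independent oracle: expected counts from the margins
        expected = np.outer(observed.sum(1), observed.sum(0)) / observed.sum()
        oracle = float(((observed - expected) ** 2 / expected).sum())
        assert abs(stat - oracle) <= 1e-10
        assert df == (observed.shape[0] - 1) * (observed.shape[1] - 1)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            hc.chisq_homogeneity([[0, 0], [5, 5]])


class TestANOVA:
    def test_identical_groups(self):
        f, df, p = hc.anova_oneway([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert df == (1, 4)

    def test_constant_equal_groups(self):
        f, _, p = hc.anova_oneway([np.array([5.0, 5, 5]), np.array([5.0, 5, 5])])
        assert f == 0.0 and p == 1.0

    def test_separated_groups_are_significant(self):
        rng = np.random.default_rng(0)
        g1 = 0.0 + 1e-6 * rng.normal(size=3)
        g2 = 10.0 + 1e-6 * rng.normal(size=3)
        _, _, p = hc.anova_oneway([g1, g2])
        assert p < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            hc.anova_oneway([np.array([1.0, 2.0])])


class TestCompareClustersTable:
    def test_generated_percentages_near_parameters(
        self, table1_cohort, table1_profiles
    ):
        table = hc.compare_clusters_table(table1_cohort, table1_cohort.true_labels)
        by_label = {p.label: p for p in table1_profiles}
        for label in (1, 2, 3, 4):
            cell = table.loc["Alcoholic cirrhosis", f"cluster {label}"]
            count = int(cell.split(" ")[0])
            n_c = int((table1_cohort.true_labels == label).sum())
            p = by_label[label].binary_probs["Alcoholic cirrhosis"]
            se = math.sqrt(p * (1 - p) / n_c)
            assert abs(count / n_c - p) <= 3 * se
        assert float(table.loc["Age", "p"]) < 0.001

    def test_single_cluster_has_no_pvalues(self):
        cohort, labels = cohort_from_counts({1: (3, 7)})
        table = hc.compare_clusters_table(cohort, labels)
        assert (table["p"] == "").all()

    def test_constant_variable_reports_not_applicable(self):
        cohort, labels = cohort_from_counts({1: (3, 7), 2: (2, 8)})
        table = hc.compare_clusters_table(cohort, labels)
        assert table.loc["Marker", "p"] == "n/a"


@pytest.mark.parametrize(
    "value,expected",
    [(69.94, 70.0), (24.86, 25.0), (33.36, 33.0), (11.54, 12.0), (-2.5, -3.0), (2.5, 3.0)],
)
def test_round_half_away(value, expected):
    assert round_half_away(value) == expected
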
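"""Grouping rules, normality-gated comparisons (with an exact Mann–Whitney
enumeration oracle), correlations, adjusted logistic regression, and the
threshold classifier."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rsomskin import cohort_stats
from rsomskin.cohort_stats import (
    assign_group,
    atherosclerosis_stratum,
    compare_groups,
    mannwhitney_p,
    rank_auc,
    stars,
    summarize_groups,
    threshold_roc,
)


class TestAssignGroup:
    @pytest.mark.parametrize("diabetic,nds,nss,ascvd,expected", [
        (False, None, None, False, "healthy"),
        (True, 0, 0, False, "NC"),
        (True, 3, 3, False, "LN"),    # the study's low-score exemplar
        (True, 9, 9, False, "HN"),    # the study's high-score exemplar
        (True, 2, 9, False, "HN"),    # HN precedence when both disjunctions hold
        (True, 0, 1, False, "LN"),
        (True, 6, 0, True, "HN"),
    ])
    def test_taxonomy(self, diabetic, nds, nss, ascvd, expected):
        assert assign_group(diabetic, nds, nss, ascvd) == expected

    def test_missing_scores_rejected(self):
        with pytest.raises(ValueError):
            assign_group(True, None, 3)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            assign_group(True, 11, 0)

    def test_ascvd_without_neuropathy_rejected(self):
        with pytest.raises(ValueError):
            assign_group(True, 0, 0, ascvd=True)

    def test_stratification(self):
        assert atherosclerosis_stratum("LN", False) == "NnA"
        assert atherosclerosis_stratum("HN", True) == "NA"
        assert atherosclerosis_stratum("NC", False) is None


class TestStars:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @pytest.mark.parametrize("p,expected", [
        (0.05, ""), (0.049999, "*"), (0.01, "*"), (0.009999, "**"),
        (0.001, "**"), (0.000999, "***"), (0.5, ""),
    ])
    def test_boundaries_exact(self, p, expected):
        assert stars(p) == expected

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=200, derandomize=True)
    def test_star_count_monotone_in_p(self, p):
        """Smaller p never earns fewer stars; the mapping is the exact
        threshold rule."""
        expected = "***" if p < 0.001 else "**" if p < 0.01 else \
            "*" if p < 0.05 else ""
        assert stars(p) == expected


def exact_mw_p(a, b):
    """Oracle: exhaustive enumeration of all C(n₁+n₂, n₁) rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = len(pooled)
    count = 0
    total = 0
    stat_obs = min(u_obs, n1 * (len(b)) - u_obs)
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        s = min(u, n1 * len(b) - u)
        if s <= stat_obs + 1e-9:
            count += 1
        total += 1
    return count / total


class TestCompareGroups:
    def test_identical_samples_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        c = compare_groups(a, a.copy())
        assert c.p_value == pytest.approx(1.0)
        assert c.star == ""

    def test_identical_constant_samples(self):
        c = compare_groups([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert c.p_value == 1.0

    def test_separated_3v3_exact_p(self):
        """Complete separation of 3 vs 3: the smallest attainable two-sided
        exact p is 2/20 = 0.1 (enumeration over all 20 rank assignments)."""
        c = compare_groups([1, 2, 3], [10, 11, 12], test="mannwhitney")
        assert c.test == "Mann-Whitney U"
        assert c.p_value == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 6), (5, 5), (8, 8)])
    def test_exact_p_matches_enumeration(self, n1, n2, rng):
        a = rng.normal(size=n1)
        b = rng.normal(0.8, size=n2)
        _, p = mannwhitney_p(a, b)
        assert p == pytest.approx(exact_mw_p(a, b), abs=1e-10)

    def test_normality_gate_picks_t_for_gaussian(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        assert compare_groups(a, b).test == "unpaired t"

    def test_normality_gate_picks_mw_for_skewed(self, rng):
        a = rng.exponential(1, 60) ** 2
        b = rng.exponential(2, 60) ** 2
        assert compare_groups(a, b).test == "Mann-Whitney U"

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2], [3, 4, 5])

    def test_printed_svn_parameters_highly_significant(self, rng):
        """Healthy vs diabetic small-vessel counts at the printed group
        parameters (48 vs 95): p < 0.001 in ≥ 95 % of replicates."""
        hits = 0
        reps = 40
        for _ in range(reps):
            a = rng.normal(9.78, 3.41, 48)
            b = rng.normal(3.45, 2.62, 95)
            if compare_groups(a, b).p_value < 0.001:
                hits += 1
        assert hits >= 0.95 * reps


class TestSpearman:
    def _table(self, x, y):
        return pd.DataFrame({"age": x, "duration_y": x, "hba1c": x, "bmi": x,
                             "tbv_pct": y, "svn": y})

    def test_perfect_monotone(self):
        x = np.arange(20.0)
        out = cohort_stats.spearman_correlations(self._table(x, x))
        assert np.allclose(out["rho"], 1.0)
        out = cohort_stats.spearman_correlations(self._table(x, -x))
        assert np.allclose(out["rho"], -1.0)

    def test_constant_column_reported_missing(self):
        x = np.arange(10.0)
        out = cohort_stats.spearman_correlations(self._table(np.ones(10), x))
        assert out["rho"].isna().all()

    def test_null_rho_small(self, rng):
        hits = 0
        reps = 40
        for _ in range(reps):
            t = self._table(rng.normal(size=100), rng.normal(size=100))
            out = cohort_stats.spearman_correlations(t)
            if np.all(np.abs(out["rho"]) < 0.2):
                hits += 1
        assert hits >= 0.9 * reps

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            cohort_stats.spearman_correlations(
                self._table(np.arange(3.0), np.arange(3.0)))


class TestAdjustedLogistic:
    def _simulate(self, rng, slope, n=400):
        x = rng.normal(size=n)
        cov = rng.normal(size=(n, 4))
        logit = slope * x
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        table = pd.DataFrame(cov, columns=["age", "duration_y", "hba1c", "bmi"])
        table["svn"] = x
        return table, y

    def test_slope_recovery(self, rng):
        table, y = self._simulate(rng, slope=1.0)
        fit = cohort_stats.adjusted_logistic(table, y, "svn")
        est = fit.set_index("term").loc["svn", "estimate"]
        assert est == pytest.approx(1.0, abs=0.3)

    def test_constant_covariate_dropped(self, rng):
        table, y = self._simulate(rng, slope=0.5)
        table["bmi"] = 27.0
        with pytest.warns(UserWarning, match="constant covariate"):
            fit = cohort_stats.adjusted_logistic(table, y, "svn")
        assert "bmi" not in set(fit["term"])

    def test_perfect_separation_diagnosed(self):
        table = pd.DataFrame({"svn": np.r_[np.zeros(20), np.ones(20)],
                              "age": np.random.default_rng(0).normal(size=40)})
        y = np.r_[np.zeros(20), np.ones(20)]
        with pytest.raises(ValueError, match="separation"):
            cohort_stats.adjusted_logistic(table, y, "svn", covariates=("age",))

    def test_non_binary_outcome_rejected(self, rng):
        table, y = self._simulate(rng, 0.0)
        with pytest.raises(ValueError):
            cohort_stats.adjusted_logistic(table, y + 5, "svn")


class TestThresholdRoc:
    def test_perfect_separation_auc_one(self):
        out = threshold_roc(np.r_[np.zeros(10), np.ones(10) + 5],
                            np.r_[np.ones(10), np.zeros(10)])
        assert out["auc"] == 1.0
        assert out["accuracy"] == 100.0
        assert out["sensitivity"] == 100.0
        assert out["specificity"] == 100.0

    def test_rank_identity_equals_trapezoidal(self, rng):
        """Dual route: hand-rolled rank AUC vs sklearn ROC-curve trapezoid."""
        from sklearn.metrics import roc_auc_score

        for _ in range(5):
            v = rng.normal(size=200) + rng.integers(0, 2, 200)
            y = rng.integers(0, 2, 200)
            if y.sum() in (0, 200):
                continue
            # classifier scores are -v (low value → diabetic)
            assert rank_auc(v, y) == pytest.approx(
                roc_auc_score(y, -v), abs=1e-12)

    def test_shuffled_labels_auc_half(self, rng):
        aucs = [rank_auc(rng.normal(size=200), rng.permutation(
            np.r_[np.ones(100), np.zeros(100)]).astype(int))
            for _ in range(30)]
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            threshold_roc([1.0, 2.0], [1, 1])

    def test_ties_handled_with_midranks(self):
        v = np.array([1.0, 1.0, 2.0, 2.0])
        y = np.array([1, 0, 1, 0])
        assert rank_auc(v, y) == pytest.approx(0.5)


class TestSummarize:
    def test_single_subject_sd_zero(self):
        t = pd.DataFrame({"group": ["healthy"], "svn": [5.0]})
        out = summarize_groups(t, columns=["svn"])
        assert out.loc[0, "svn_sd"] == 0.0

    def test_two_equal_values_sd_zero(self):
        t = pd.DataFrame({"group": ["NC", "NC"], "svn": [4.0, 4.0]})
        out = summarize_groups(t, columns=["svn"])
        assert out.loc[0, "svn_sd"] == 0.0

    def test_generator_round_trip_within_3_se(self):
        from rsomskin import phantom

        spec = phantom.CohortSpec(seed=31)
        table = phantom.make_cohort(spec)
        out = summarize_groups(table, columns=["svn"]).set_index("group")
        for g in ("healthy", "NC"):
            mean, sd = spec.group_biomarkers[g]["svn"]
            n = spec.group_sizes[g]
            assert abs(out.loc[g, "svn_mean"] - mean) < 3 * sd / np.sqrt(n)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_groups(pd.DataFrame())
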
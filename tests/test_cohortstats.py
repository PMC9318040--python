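"""Statistics battery tests, with independent oracles for the AUC, Youden
cutoff and confidence-interval machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from melif.cohortstats import (
    cohort_report,
    group_summary,
    normality_test,
    pearson_with_regression,
    roc_youden,
    ttest_unpaired,
)
from melif.errors import ValidationError


class TestGroupSummary:
    def test_seven_integers(self):
        # hand computation: median 4, quartiles 2 and 6, no outliers
        s = group_summary([1, 2, 3, 4, 5, 6, 7])
        assert s.median == 4
        assert (s.q1, s.q3) == (2, 6)
        assert s.outliers == []
        assert s.whisker_low == 1 and s.whisker_high == 7

    def test_single_value(self):
        s = group_summary([5.0])
        assert s.sd is None
        assert s.median == 5.0

    def test_constant_group(self):
        s = group_summary([3.0] * 10)
        assert s.sd == 0.0
        assert s.whisker_low == s.whisker_high == 3.0

    def test_outlier_detection(self):
        s = group_summary([1, 2, 3, 4, 5, 6, 7, 100])
        assert 100 in s.outliers

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            group_summary([])


class TestNormality:
    def test_small_n_not_assessable(self):
        res = normality_test([1.0, 2.0, 3.0, 4.0])
        assert not res.assessable

    def test_type_i_error_rate(self):
        # 5000 standard-normal draws: p > 0.01 in >= 95% of 100 seeds
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(5000)
            if normality_test(x).p_value > 0.01:
                hits += 1
        assert hits >= 95

    def test_power_against_exponential(self):
        x = np.random.default_rng(0).exponential(size=5000)
        assert normality_test(x).p_value < 0.01

    def test_matches_scipy(self):
        x = np.random.default_rng(5).normal(size=50)
        res = normality_test(x)
        stat, p = stats.normaltest(x)
        assert res.statistic == pytest.approx(float(stat))
        assert res.p_value == pytest.approx(float(p))


class TestTTest:
    def test_identical_groups(self):
        t, df, p = ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_oracle(self):
        # pooled SD 1, SE sqrt(2/3): t = -3/0.8165 = -3.674, p ~ 0.021
        t, df, p = ttest_unpaired([1, 2, 3], [4, 5, 6])
        assert abs(t) == pytest.approx(3.674, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.0213, abs=1e-3)

    def test_scale_invariance(self):
        t1, _, _ = ttest_unpaired([1, 2, 3], [4, 5, 6])
        t2, _, _ = ttest_unpaired([10, 20, 30], [40, 50, 60])
        assert t1 == pytest.approx(t2)

    def test_welch_option(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [10.0, 30.0, 50.0]
        _, df_pooled, _ = ttest_unpaired(a, b)
        _, df_welch, _ = ttest_unpaired(a, b, welch=True)
        assert df_welch < df_pooled

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            ttest_unpaired([1.0], [2.0, 3.0])


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson_with_regression(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        assert pearson_with_regression(x, -x).r == pytest.approx(-1.0)

    def test_fisher_ci_coverage(self):
        """Fisher-z 95% CI covers true rho = -0.6 in ~95% of seeded draws."""
        rho, n, covered = -0.6, 195, 0
        n_rep = 1000
        cov = np.array([[1.0, rho], [rho, 1.0]])
        for seed in range(n_rep):
            xy = np.random.default_rng(seed).multivariate_normal([0, 0], cov, size=n)
            res = pearson_with_regression(xy[:, 0], xy[:, 1])
            if res.ci_low <= rho <= res.ci_high:
                covered += 1
        assert 0.93 <= covered / n_rep <= 0.97

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_with_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestROCYouden:
    def test_perfect_separation(self):
        res = roc_youden([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0], positive_is_low=True)
        assert res.auc == 1.0
        assert res.sensitivity_pct == 100.0 and res.specificity_pct == 100.0

    def test_null_case(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        res = roc_youden(scores, labels, positive_is_low=True)
        assert res.ci_low <= 0.5 <= res.ci_high
        assert abs(res.auc - 0.5) < 0.15

    def test_four_point_oracle(self):
        # scores {1,2,3,4}, labels {0,0,1,1}, positives high: AUC 1,
        # Youden cutoff falls between 2 and 3
        res = roc_youden([1, 2, 3, 4], [0, 0, 1, 1], positive_is_low=False)
        assert res.auc == 1.0
        assert 2 < res.cutoff < 3

    def test_rank_auc_equals_trapezoid(self):
        """Rank-statistic AUC must equal trapezoidal integration of the
        empirical ROC curve (sklearn as the independent oracle)."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(20, 200))
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            res = roc_youden(scores, labels, positive_is_low=False)
            assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_youden_equals_exhaustive_enumeration(self):
        """Best J from brute-force over every observed threshold."""
        rng = np.random.default_rng(9)
        scores = np.round(rng.normal(50, 10, size=120), 1)
        labels = (rng.random(120) < 0.4).astype(int)
        res = roc_youden(scores, labels, positive_is_low=True)
        best_j = -np.inf
        for c in np.unique(np.concatenate([scores - 0.05, scores + 0.05])):
            sens = (scores[labels == 1] <= c).mean()
            spec = (scores[labels == 0] > c).mean()
            best_j = max(best_j, sens + spec - 1)
        j_impl = res.sensitivity_pct / 100 + res.specificity_pct / 100 - 1
        assert j_impl == pytest.approx(best_j, abs=1e-12)

    def test_binormal_model_matches_closed_form(self):
        """Mean simulated AUC under a binormal model equals
        Phi(dmu / sqrt(s1^2 + s2^2)) within Monte-Carlo error."""
        mu1, sd1, n1 = 55.0, 11.0, 132   # printed normal-group summary
        mu2, sd2, n2 = 42.0, 11.0, 59    # printed impaired-group summary
        expected = stats.norm.cdf((mu1 - mu2) / np.hypot(sd1, sd2))
        aucs = []
        for seed in range(400):
            rng = np.random.default_rng(seed)
            a = rng.normal(mu1, sd1, n1)
            b = rng.normal(mu2, sd2, n2)
            scores = np.concatenate([a, b])
            labels = np.concatenate([np.zeros(n1), np.ones(n2)])
            aucs.append(roc_youden(scores, labels, positive_is_low=True).auc)
        assert np.mean(aucs) == pytest.approx(expected, abs=0.01)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_youden([1.0, 2.0], [1, 1])


def _synthetic_cohort(n_normal=30, n_impaired=20, n_severe=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, meld_rng, melif_mu in (
        ("normal", n_normal, (6, 10), 55.0),
        ("impaired", n_impaired, (11, 18), 42.0),
        ("severe", n_severe, (19, 30), 29.0),
    ):
        for i in range(n):
            rows.append(
                {
                    "id": f"{group}-{i}",
                    "meld": int(rng.integers(meld_rng[0], meld_rng[1] + 1)),
                    "meld_group": group,
                    "melif": rng.normal(melif_mu, 8.0),
                    "rrt1_mean_pct": rng.normal(melif_mu - 1, 8.0),
                }
            )
    return pd.DataFrame(rows)


class TestCohortReport:
    def test_group_ordering_and_sections(self, tmp_path):
        df = _synthetic_cohort()
        report = cohort_report(df, out_dir=tmp_path)
        g = report["groups"]
        assert (
            g["normal"]["melif"]["mean"]
            > g["impaired"]["melif"]["mean"]
            > g["severe"]["melif"]["mean"]
        )
        assert report["roc_normal_vs_impaired"]["melif"]["auc"] > 0.6
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "group_summary.csv").exists()

    def test_single_group_omits_roc(self):
        df = _synthetic_cohort(n_normal=10, n_impaired=0, n_severe=0)
        report = cohort_report(df)
        assert report["roc_normal_vs_impaired"] is None

    def test_determinism(self):
        df = _synthetic_cohort()
        import json

        r1 = json.dumps(cohort_report(df), sort_keys=True, default=str)
        r2 = json.dumps(cohort_report(df.copy()), sort_keys=True, default=str)
        assert r1 == r2

    def test_duplicate_ids_rejected(self):
        df = _synthetic_cohort()
        df.loc[1, "id"] = df.loc[0, "id"]
        with pytest.raises(ValidationError):
            cohort_report(df)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError):
            cohort_report(pd.DataFrame({"id": ["a"], "melif": [50.0]}))
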
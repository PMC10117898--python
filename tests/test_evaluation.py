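import numpy as np
import pytest

from orthosav import (
    UndefinedMetricError,
    ValidationError,
    auroc,
    average_precision,
    confusion_at_threshold,
    evaluate_predictors,
    pearson_r,
    spearman_rho,
)

from oracles import mann_whitney_auc, midrank, stepwise_ap, textbook_pearson


class TestConfusion:
    def test_perfect_split(self):
        c = confusion_at_threshold([9, 1], [True, False], t=5)
        assert (c.TP, c.FP, c.TN, c.FN) == (1, 0, 1, 0)
        r = c.rates()
        assert r["TPR"] == 1.0 and r["FPR"] == 0.0 and r["precision"] == 1.0

    def test_threshold_below_all_scores(self):
        scores = [3.0, 1.0, 2.0, 5.0]
        labels = [True, False, False, True]
        c = confusion_at_threshold(scores, labels, t=0.0)
        assert c.TP == 2 and c.FP == 2 and c.TN == 0 and c.FN == 0

    def test_counts_conserve_n_at_every_threshold(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=20)
        labels = rng.random(20) < 0.4
        for t in np.unique(scores):
            assert confusion_at_threshold(scores, labels, t).n == 20

    def test_matches_exhaustive_tabulation(self):
        rng = np.random.default_rng(7)
        scores = rng.integers(0, 5, size=20).astype(float)
        labels = rng.random(20) < 0.5
        for t in np.unique(scores):
            c = confusion_at_threshold(scores, labels, t)
            tp = sum(1 for s, y in zip(scores, labels) if s >= t and y)
            fp = sum(1 for s, y in zip(scores, labels) if s >= t and not y)
            assert (c.TP, c.FP) == (tp, fp)

    def test_no_positives_tpr_undefined(self, caplog):
        c = confusion_at_threshold([1.0, 2.0], [False, False], t=1.5)
        with caplog.at_level("WARNING"):
            assert c.rates()["TPR"] is None


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([3, 4, 1, 2], [True, True, False, False]) == 1.0

    def test_identical_scores_chance(self):
        assert auroc([5, 5, 5, 5], [True, False, True, False]) == 0.5

    def test_equals_mann_whitney_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(4, 31))
            scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert auroc(scores, labels) == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12
            )

    def test_complement_under_score_negation(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=25)  # continuous, tie-free
        labels = rng.random(25) < 0.4
        assert auroc(scores, labels) + auroc(-scores, labels) == pytest.approx(1.0, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auroc([1.0, 2.0], [True, True])

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(17)
        scores = rng.integers(0, 8, size=40).astype(float)
        labels = rng.random(40) < 0.5
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([4, 3, 2, 1], [True, True, False, False]) == 1.0

    def test_single_positive_ranked_last(self):
        n = 7
        scores = list(range(n, 0, -1))
        labels = [False] * (n - 1) + [True]
        assert average_precision(scores, labels) == pytest.approx(1 / n)

    def test_matches_confusion_summation_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            n = int(rng.integers(5, 31))
            scores = rng.integers(0, 6, size=n).astype(float)
            labels = rng.random(n) < 0.4
            if not labels.any():
                continue
            assert average_precision(scores, labels) == pytest.approx(
                stepwise_ap(scores, labels), abs=1e-12
            )

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import average_precision_score
        rng = np.random.default_rng(23)
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.3
        assert average_precision(scores, labels) == pytest.approx(
            average_precision_score(labels, scores), abs=1e-12
        )

    def test_random_scores_approach_prevalence(self):
        # E[AP] under a random ranking converges to the prevalence from above
        # (small-sample bias is positive), so check at a size where the bias
        # is inside the Monte-Carlo tolerance, and check the perfect-ranking
        # bound AP >= prevalence always holds.
        rng = np.random.default_rng(29)
        n, P = 400, 120
        prevalence = P / n
        labels = np.r_[np.ones(P, bool), np.zeros(n - P, bool)]
        aps = [average_precision(rng.permutation(n).astype(float), labels)
               for _ in range(300)]
        assert np.mean(aps) == pytest.approx(prevalence, abs=0.03)
        assert min(aps) >= 0.0 and max(aps) <= 1.0
        perfect = average_precision(np.r_[np.ones(P), np.zeros(n - P)], labels)
        assert perfect >= prevalence

    def test_no_positives_rejected(self):
        with pytest.raises(UndefinedMetricError):
            average_precision([1.0, 2.0], [False, False])


class TestCorrelations:
    def test_pearson_linear_relations(self):
        x = np.arange(10, dtype=float)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and p == pytest.approx(0.0, abs=1e-12)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_pearson_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 2.5, 4.0, 5.5, 6.0, 7.1, 8.0, 9.2, 10.0])
        y = np.array([2.1, 1.9, 3.5, 3.2, 5.0, 6.1, 6.0, 7.5, 8.1, 9.9])
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(textbook_pearson(x, y), abs=1e-12)

    def test_pearson_p_matches_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(31)
        x, y = rng.normal(size=15), rng.normal(size=15)
        r, p = pearson_r(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_pearson_exact_permutation_small_n(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.1, 2.3, 2.9, 4.4, 4.8])
        r, p = pearson_r(x, y, method="permutation")
        assert 0 < p < 0.05  # strong monotone association, exact tail

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_spearman_monotone_transform_invariance(self):
        x = np.array([0.3, 1.2, 2.2, 3.9, 5.0, 7.7])
        r, _ = spearman_rho(x, np.exp(x))
        assert r == pytest.approx(1.0)
        r, _ = spearman_rho(x, -(x**3))
        assert r == pytest.approx(-1.0)

    def test_spearman_midranks_with_ties(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0])
        rho, _ = spearman_rho(x, y)
        expected = textbook_pearson(midrank(x), midrank(y))
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_spearman_matches_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(37)
        x = rng.integers(0, 6, size=25).astype(float)
        y = x + rng.normal(size=25)
        rho, p = spearman_rho(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestReport:
    def test_report_on_synthetic_labeled_set(self):
        from orthosav.synthetic_data import gen_af_conservation, gen_score_table
        table, truth = gen_score_table(n_variants=60, n_damaging=10, seed=41)
        ann = gen_af_conservation(truth, seed=41)
        report = evaluate_predictors(table, ann)
        assert set(report.index) == set(table.predictors)
        # planted scores rank pathogenic above benign
        assert (report["auroc"].dropna() > 0.5).all()
        assert report["pearson_r_neglog10_af"].notna().all()

    def test_one_class_labels_yield_nan_not_crash(self, published_scores,
                                                  published_annotations, caplog):
        # only one pathogenic label and no benign among the printed variants
        with caplog.at_level("WARNING"):
            report = evaluate_predictors(published_scores, published_annotations)
        assert np.isnan(report.at["ESM", "auroc"])
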
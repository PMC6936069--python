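import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from brainnetmf import (
    ClassifierSpec,
    FeatureMatrix,
    Partition,
    WeightedNetwork,
    auc,
    compare_feature_scopes,
    evaluate_classifier,
    loocv_scores,
    pso_select,
    rfe_select,
    roc_curve,
)

from conftest import random_symmetric_nonneg


def make_feature_matrix(X, y):
    names = [(f"a{j}", f"b{j}") for j in range(X.shape[1])]
    return FeatureMatrix([f"s{i}" for i in range(len(X))], X, names, y)


def signal_dataset(rng, n=30, n_features=20, informative=(0, 1), shift=2.0):
    """Gaussian features; the informative columns are mean-shifted by class."""
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, n_features))
    for j in informative:
        X[:, j] += shift * y
    return X, y


class TestRocCurve:
    def test_matches_exhaustive_confusion_enumeration(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        roc = roc_curve(scores, labels, "score_range")
        for t, tpr, fpr in zip(roc.thresholds, roc.tpr, roc.fpr):
            tp = sum(s >= t and l == 1 for s, l in zip(scores, labels))
            fp = sum(s >= t and l == 0 for s, l in zip(scores, labels))
            assert tpr == tp / 2
            assert fpr == fp / 2

    def test_perfect_probabilities_reach_corner(self):
        roc = roc_curve([0.0, 0.0, 1.0, 1.0], [0, 0, 1, 1], "unit_interval")
        assert any(f == 0.0 and t == 1.0 for f, t in zip(roc.fpr, roc.tpr))

    def test_constant_scores_collapse_to_diagonal_endpoints(self):
        roc = roc_curve([0.5, 0.5, 0.5], [0, 1, 1], "score_range")
        points = set(zip(roc.fpr, roc.tpr))
        assert points == {(0.0, 0.0), (1.0, 1.0)}

    def test_endpoints_always_present(self, rng):
        for mode in ("score_range", "unit_interval"):
            scores = rng.uniform(0, 1, 10)
            labels = rng.integers(0, 2, 10)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            roc = roc_curve(scores, labels, mode)
            pts = set(zip(roc.fpr, roc.tpr))
            assert (0.0, 0.0) in pts and (1.0, 1.0) in pts

    def test_rates_non_increasing_in_threshold(self, rng):
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        roc = roc_curve(scores, labels, "score_range")
        assert (np.diff(roc.tpr) <= 0).all()
        assert (np.diff(roc.fpr) <= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.9], [1, 1], "score_range")


class TestAuc:
    def test_perfect_classifier(self):
        roc = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], "score_range")
        assert roc.auc == pytest.approx(1.0)

    def test_constant_scores_give_chance(self):
        roc = roc_curve([0.3, 0.3, 0.3, 0.3], [0, 0, 1, 1], "score_range")
        assert roc.auc == pytest.approx(0.5)

    def test_equals_pairwise_rank_statistic_on_tie_free_scores(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 30))
            scores = rng.permutation(n).astype(float)  # tie-free
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            roc = roc_curve(scores, labels, "score_range")
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            pairwise = np.mean([p > q for p in pos for q in neg])
            assert roc.auc == pytest.approx(pairwise, abs=1e-12)
            assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_score_transform(self, rng):
        scores = rng.normal(size=15)
        labels = rng.integers(0, 2, 15)
        labels[:2] = [0, 1]
        a1 = roc_curve(scores, labels, "score_range").auc
        a2 = roc_curve(np.exp(3 * scores), labels, "score_range").auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_label_flip_mirrors_auc(self, rng):
        scores = rng.permutation(12).astype(float)
        labels = np.array([0, 1] * 6)
        a = roc_curve(scores, labels, "score_range").auc
        flipped = roc_curve(scores, 1 - labels, "score_range").auc
        assert flipped == pytest.approx(1.0 - a, abs=1e-12)
        both = roc_curve(-scores, 1 - labels, "score_range").auc
        assert both == pytest.approx(a, abs=1e-12)


class TestLoocv:
    def test_one_score_per_subject(self, rng):
        X, y = signal_dataset(rng, n=4, n_features=3)
        fm = make_feature_matrix(X, y)
        scores = loocv_scores(fm, ClassifierSpec("lda", seed=0))
        assert scores.shape == (4,)

    def test_separated_clusters_svm_scores_signed_correctly(self, rng):
        y = np.array([0] * 6 + [1] * 6)
        X = rng.normal(scale=0.1, size=(12, 2))
        X[y == 1] += 5.0
        fm = make_feature_matrix(X, y)
        scores = loocv_scores(fm, ClassifierSpec("linear_svm", seed=0))
        assert (scores[y == 1] > 0).all()
        assert (scores[y == 0] < 0).all()

    def test_shuffled_labels_give_chance_level_auc(self, rng):
        X = rng.normal(size=(50, 10))
        aucs = []
        for _ in range(20):
            y = rng.permutation([0] * 25 + [1] * 25)
            fm = make_feature_matrix(X, y)
            scores = loocv_scores(fm, ClassifierSpec("lda", seed=1))
            aucs.append(roc_curve(scores, y, "unit_interval").auc)
        assert 0.3 <= np.mean(aucs) <= 0.7
        assert min(aucs) > 0.1 and max(aucs) < 0.9

    def test_deterministic_given_seed(self, rng):
        X, y = signal_dataset(rng, n=12, n_features=6)
        fm = make_feature_matrix(X, y)
        s1 = loocv_scores(fm, ClassifierSpec("random_forest", {"n_estimators": 25}, seed=9))
        s2 = loocv_scores(fm, ClassifierSpec("random_forest", {"n_estimators": 25}, seed=9))
        np.testing.assert_array_equal(s1, s2)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            ClassifierSpec("deep_net")

    @pytest.mark.parametrize("kind", ["lda", "lasso_logistic", "knn", "linear_svm"])
    def test_strong_signal_recovered_by_each_classifier(self, rng, kind):
        X, y = signal_dataset(rng, n=20, n_features=5, shift=4.0)
        fm = make_feature_matrix(X, y)
        _, roc = evaluate_classifier(fm, ClassifierSpec(kind, seed=0))
        assert roc.auc > 0.9


class TestRfe:
    def test_keep_all_is_identity(self, rng):
        X, y = signal_dataset(rng, n=12, n_features=6)
        np.testing.assert_array_equal(rfe_select(X, y, n_keep=6), np.arange(6))

    def test_informative_features_survive(self, rng):
        hits = 0
        for rep in range(20):
            X, y = signal_dataset(rng, n=30, n_features=20, shift=2.5)
            kept = rfe_select(X, y, n_keep=2)
            hits += set(kept) == {0, 1}
        assert hits >= 18

    def test_halving_schedule_runs_two_rounds(self, rng, monkeypatch):
        import brainnetmf.classify as mod

        fits = []
        orig = mod.SVC

        class CountingSVC(orig):
            def fit(self, X, y, **kw):
                fits.append(X.shape[1])
                return super().fit(X, y, **kw)

        monkeypatch.setattr(mod, "SVC", CountingSVC)
        X, y = signal_dataset(rng, n=12, n_features=8)
        kept = rfe_select(X, y, n_keep=2, step=0.5)
        assert len(kept) == 2
        assert fits == [8, 4]  # two elimination rounds

    def test_n_keep_beyond_f_rejected(self, rng):
        X, y = signal_dataset(rng, n=10, n_features=4)
        with pytest.raises(ValueError):
            rfe_select(X, y, n_keep=5)


class TestPso:
    def test_single_feature_mask_is_one(self, rng):
        X, y = signal_dataset(rng, n=12, n_features=1, informative=(0,))
        mask = pso_select(X, y, swarm_size=3, iterations=2, seed=0)
        np.testing.assert_array_equal(mask, [1])

    def test_deterministic_given_seed(self, rng):
        X, y = signal_dataset(rng, n=16, n_features=8)
        m1 = pso_select(X, y, swarm_size=4, iterations=3, seed=5)
        m2 = pso_select(X, y, swarm_size=4, iterations=3, seed=5)
        np.testing.assert_array_equal(m1, m2)

    def test_never_below_all_ones_baseline(self, rng):
        X, y = signal_dataset(rng, n=30, n_features=20, shift=2.0)
        mask, info = pso_select(
            X, y, swarm_size=10, iterations=15, seed=2, full_output=True
        )
        assert mask.any()
        assert info["gbest_fitness"] >= info["all_ones_fitness"]


class TestCompareScopes:
    def test_identical_scopes_give_identical_aucs(self, rng):
        ids = [f"r{i}" for i in range(6)]
        nets = [
            WeightedNetwork(ids, random_symmetric_nonneg(rng, 6)) for _ in range(10)
        ]
        labels = np.array([0, 1] * 5)
        part = Partition(np.zeros(6, dtype=int), 1)  # one module holding all nodes
        table = compare_feature_scopes(
            nets, labels, part, 0, [ClassifierSpec("lda", seed=0)]
        )
        assert table.loc["module", "lda"] == table.loc["whole_network", "lda"]

    def test_table_shape(self, rng):
        ids = [f"r{i}" for i in range(6)]
        nets = [
            WeightedNetwork(ids, random_symmetric_nonneg(rng, 6)) for _ in range(8)
        ]
        labels = np.array([0, 1] * 4)
        part = Partition(np.array([0, 0, 0, 1, 1, 1]), 2)
        specs = [ClassifierSpec("lda", seed=0), ClassifierSpec("knn", seed=0)]
        table = compare_feature_scopes(nets, labels, part, 0, specs)
        assert table.shape == (2, 2)
        assert list(table.index) == ["module", "whole_network"]
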
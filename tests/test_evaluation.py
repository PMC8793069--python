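import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from walkboost import (
    GBDTClassifier,
    GBDTConfig,
    ResamplingPlan,
    compute_auc,
    compute_aupr,
    cross_validate,
    rank_candidates,
    sample_balanced_negatives,
    stratified_kfold,
)
from walkboost.evaluation import pr_curve_points, roc_curve_points


def brute_force_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Direct pair counting: concordant + half the ties, over all pos/neg pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def trapezoid_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    pts = roc_curve_points(labels, scores)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


class OracleClassifier:
    """Scores every sample with its true label — the AUC=1 upper bound."""

    def __init__(self, X, y):
        self._lookup = {row.tobytes(): label for row, label in zip(X, y)}

    def train(self, X, y):
        pass

    def score(self, X):
        return np.array([self._lookup[row.tobytes()] for row in X])


class SeededRandomClassifier:
    def __init__(self, seed=0):
        self.rng = np.random.default_rng(seed)

    def train(self, X, y):
        pass

    def score(self, X):
        return self.rng.random(len(X))


class TestAUC:
    def test_perfect_separation(self):
        assert compute_auc(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_all_tied_scores(self):
        assert compute_auc(np.array([0, 1, 0, 1]), np.ones(4)) == 0.5

    def test_worked_example(self):
        auc = compute_auc(np.array([1, 0, 1, 0]), np.array([0.9, 0.8, 0.7, 0.1]))
        assert auc == 0.75  # 3 of 4 pos/neg pairs concordant

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_auc(np.ones(3), np.arange(3.0))

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_pair_counting_and_trapezoid(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        auc = compute_auc(labels, scores)
        assert auc == pytest.approx(brute_force_auc(labels, scores), abs=1e-12)
        assert auc == pytest.approx(trapezoid_auc(labels, scores), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 0, 1
        scores = rng.normal(size=n)
        a = compute_auc(labels, scores)
        b = compute_auc(labels, np.exp(3.0 * scores))  # strictly monotone
        assert a == pytest.approx(b, abs=1e-12)


class TestAUPR:
    def test_perfect_ranking(self):
        assert compute_aupr(np.array([0, 0, 1]), np.array([0.1, 0.2, 0.9])) == 1.0

    def test_single_positive_ranked_last(self):
        aupr = compute_aupr(np.array([0, 0, 0, 1]), np.array([0.9, 0.8, 0.7, 0.1]))
        assert aupr == pytest.approx(0.25)

    def test_all_positive_labels(self):
        assert compute_aupr(np.ones(4, dtype=int), np.arange(4.0)) == 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            compute_aupr(np.zeros(3), np.arange(3.0))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sklearn_average_precision(self, seed):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(seed)
        n = 50
        labels = (rng.random(n) < 0.3).astype(int)
        labels[0] = 1
        scores = np.round(rng.random(n), 1)
        assert compute_aupr(labels, scores) == pytest.approx(
            average_precision_score(labels, scores), abs=1e-12
        )

    def test_pr_points_end_at_full_recall(self):
        rng = np.random.default_rng(1)
        labels = np.array([1, 0, 1, 0, 1])
        pts = pr_curve_points(labels, rng.random(5))
        assert pts[-1, 0] == pytest.approx(1.0)


class TestStratifiedKFold:
    def test_perfect_stratification(self):
        y = np.repeat([0, 1], 10)
        folds = stratified_kfold(y, k=10, seed=0)
        for f in range(10):
            assert y[folds == f].sum() == 1
            assert (folds == f).sum() == 2

    def test_k1_rejected(self):
        with pytest.raises(ValueError, match="k must be >= 2"):
            stratified_kfold(np.array([0, 1, 0, 1]), k=1)

    def test_small_class_rejected(self):
        y = np.array([0] * 20 + [1] * 3)
        with pytest.raises(ValueError, match="fewer than k"):
            stratified_kfold(y, k=5)

    def test_balanced_870_samples_in_tens(self):
        y = np.repeat([0, 1], 435)
        folds = stratified_kfold(y, k=10, seed=1)
        sizes = np.bincount(folds)
        assert np.all(sizes == 87)

    def test_deterministic_given_seed(self):
        y = np.repeat([0, 1], 30)
        assert np.array_equal(
            stratified_kfold(y, 5, seed=9), stratified_kfold(y, 5, seed=9)
        )


class TestSampleBalancedNegatives:
    def test_pool_equals_draw_size(self):
        draws = sample_balanced_negatives(
            [0, 1, 2], [10, 11, 12], ResamplingPlan(n_repeats=3, rng_seed=4)
        )
        for d in draws:
            assert list(d) == [10, 11, 12]

    def test_balanced_draw_of_435_from_896(self):
        positives = list(range(435))
        pool = list(range(435, 435 + 896))
        draws = sample_balanced_negatives(positives, pool, ResamplingPlan(n_repeats=5, rng_seed=0))
        assert len(draws) == 5
        assert all(len(d) == 435 for d in draws)
        assert all(set(d) <= set(pool) for d in draws)
        assert any(not np.array_equal(draws[0], d) for d in draws[1:])

    def test_same_seed_identical_draws(self):
        plan = ResamplingPlan(n_repeats=2, rng_seed=77)
        a = sample_balanced_negatives(range(5), range(10, 30), plan)
        b = sample_balanced_negatives(range(5), range(10, 30), plan)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_pool_too_small(self):
        with pytest.raises(ValueError, match="smaller"):
            sample_balanced_negatives(range(10), range(5), ResamplingPlan())


@pytest.fixture(scope="module")
def toy_features():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(60, 5))
    X[:20, 0] += 3.0  # positives separable on feature 0
    return X


class TestCrossValidate:
    def test_oracle_classifier_reaches_auc_one(self, toy_features):
        labels = np.concatenate([np.ones(20), np.zeros(40)])
        oracle = OracleClassifier(toy_features, labels)
        res = cross_validate(
            toy_features, range(20), range(20, 60), oracle,
            plan=ResamplingPlan(n_repeats=2, rng_seed=0), k=4, seed=0,
        )
        assert res.mean_auc == 1.0 and res.sd_auc == 0.0
        assert res.mean_aupr == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 3))
        res = cross_validate(
            X, range(150), range(150, 300),
            lambda: SeededRandomClassifier(seed=8),
            plan=ResamplingPlan(n_repeats=4, rng_seed=1), k=5, seed=2,
        )
        assert 0.45 <= res.mean_auc <= 0.55

    def test_fold_counts_and_metric_lists(self, toy_features):
        labels = np.concatenate([np.ones(20), np.zeros(40)])
        res = cross_validate(
            toy_features, range(20), range(20, 60),
            OracleClassifier(toy_features, labels),
            plan=ResamplingPlan(n_repeats=3, rng_seed=0), k=4, seed=0,
        )
        assert len(res.per_fold_auc) == 12 == len(res.per_fold_aupr)
        assert res.k == 4 and res.n_repeats == 3

    def test_population_sd_definition(self, toy_features):
        res = cross_validate(
            toy_features, range(20), range(20, 60),
            lambda: SeededRandomClassifier(seed=5),
            plan=ResamplingPlan(n_repeats=2, rng_seed=0), k=4, seed=1,
        )
        assert res.sd_auc == pytest.approx(np.std(res.per_fold_auc), abs=1e-15)
        res.sd_mode = "standard_error"
        assert res.sd_auc == pytest.approx(
            np.std(res.per_fold_auc) / np.sqrt(len(res.per_fold_auc)), abs=1e-15
        )

    def test_gbdt_separates_planted_signal(self, toy_features):
        cfg = GBDTConfig(n_rounds=20, max_depth=2, min_leaf=2)
        res = cross_validate(
            toy_features, range(20), range(20, 60),
            lambda: GBDTClassifier(cfg),
            plan=ResamplingPlan(n_repeats=2, rng_seed=0), k=4, seed=0,
        )
        assert res.mean_auc > 0.9


class TestRankCandidates:
    def test_all_genes_labeled_gives_empty_table(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        ranked = rank_candidates(X, range(5), range(5, 10))
        assert ranked == []

    def test_held_out_module_genes_rank_high(self):
        rng = np.random.default_rng(1)
        n_pos, n_neg, n_unlabeled = 20, 40, 10
        X = rng.normal(size=(70, 4))
        X[:n_pos, 0] += 3.0
        X[60:, 0] += 3.0  # unlabeled genes carry the positive signature
        cfg = GBDTConfig(n_rounds=30, max_depth=2, min_leaf=2)
        ranked = rank_candidates(
            X, range(n_pos), range(n_pos, n_pos + n_neg), config=cfg,
            plan=ResamplingPlan(n_repeats=3, rng_seed=0),
        )
        assert len(ranked) == n_unlabeled
        top = [idx for idx, _, _ in ranked]
        assert set(top) == set(range(60, 70))
        means = [m for _, m, _ in ranked]
        assert means == sorted(means, reverse=True)
        assert means[0] > 0.5
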
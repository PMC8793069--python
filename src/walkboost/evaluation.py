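"""Evaluation protocol: balanced negative sampling, stratified k-fold CV,
and rank-based AUC / AUPR computed from first principles.

The pool of genes not known to be disease-associated vastly outnumbers the
known positives, so training sets are balanced by repeatedly drawing a
negatives subset equal in size to the positives; metrics are aggregated
across all folds of all draws and reported as mean plus/minus the standard
deviation (population sd by default, configurable to standard error).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.stats import rankdata

from .gbdt import GBDTConfig, GBDTModel, fit_gbdt, fit_regression_tree
from .rwr import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResamplingPlan:
    """Balanced negative-sampling plan.

    n_repeats:
        Number of independent negative draws (10 for the headline CV,
        5 for classifier comparisons).
    negatives_per_draw:
        Draw size; None means match the positive count (balanced).
    rng_seed:
        Seed for the draw generator; identical seeds give identical draws.
    """

    n_repeats: int = 10
    negatives_per_draw: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@runtime_checkable
class Classifier(Protocol):
    """Pluggable classifier contract used by the CV harness."""

    def train(self, features: np.ndarray, labels: np.ndarray) -> None: ...

    def score(self, features: np.ndarray) -> np.ndarray: ...


class GBDTClassifier:
    """Adapter putting the boosted-tree model behind the train/score contract."""

    def __init__(self, config: GBDTConfig | None = None, seed: int = 0) -> None:
        self.config = config or GBDTConfig()
        self.seed = seed
        self.model_: GBDTModel | None = None

    def train(self, features: np.ndarray, labels: np.ndarray) -> None:
        self.model_ = fit_gbdt(features, labels, self.config, seed=self.seed)

    def score(self, features: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("classifier not trained")
        return self.model_.predict_proba(features)


class SingleTreeClassifier:
    """Depth-limited CART regression tree on the raw 0/1 labels.

    The weak-learner baseline: scores are leaf means, i.e. the empirical
    positive rate of the region a gene falls in.
    """

    def __init__(self, max_depth: int = 3, min_leaf: int = 5) -> None:
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.tree_ = None

    def train(self, features: np.ndarray, labels: np.ndarray) -> None:
        self.tree_ = fit_regression_tree(
            features, labels, max_depth=self.max_depth, min_leaf=self.min_leaf
        )

    def score(self, features: np.ndarray) -> np.ndarray:
        if self.tree_ is None:
            raise RuntimeError("classifier not trained")
        return self.tree_.predict(features)


@dataclass
class CVResult:
    """Per-fold metrics across all negative draws, with summary statistics."""

    per_fold_auc: list[float]
    per_fold_aupr: list[float]
    k: int
    n_repeats: int
    sd_mode: str = "population"
    config: dict = field(default_factory=dict)

    def _spread(self, values: np.ndarray) -> float:
        sd = float(np.std(values))  # population sd across fold-level metrics
        if self.sd_mode == "standard_error":
            return sd / np.sqrt(len(values))
        return sd

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_fold_auc))

    @property
    def sd_auc(self) -> float:
        return self._spread(np.asarray(self.per_fold_auc))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.per_fold_aupr))

    @property
    def sd_aupr(self) -> float:
        return self._spread(np.asarray(self.per_fold_aupr))

    def summary(self) -> str:
        return (
            f"AUC {self.mean_auc:.3f} ± {self.sd_auc:.3f}, "
            f"AUPR {self.mean_aupr:.3f} ± {self.sd_aupr:.3f} "
            f"({self.k}-fold × {self.n_repeats} draws)"
        )

    def to_dict(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "mean_aupr": self.mean_aupr,
            "sd_aupr": self.sd_aupr,
            "per_fold_auc": self.per_fold_auc,
            "per_fold_aupr": self.per_fold_aupr,
            "k": self.k,
            "n_repeats": self.n_repeats,
            "sd_mode": self.sd_mode,
            "config": self.config,
        }

    def write_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Sampling and folds
# ---------------------------------------------------------------------------


def sample_balanced_negatives(
    positives: Sequence[int],
    negative_pool: Sequence[int],
    plan: ResamplingPlan,
) -> list[np.ndarray]:
    """Uniform without-replacement negative draws, one per repeat.

    Each draw has ``plan.negatives_per_draw`` elements (default: the
    positive count, i.e. a balanced set). Deterministic given the plan seed.
    """
    pool = np.asarray(sorted(negative_pool), dtype=np.int64)
    size = plan.negatives_per_draw if plan.negatives_per_draw is not None else len(positives)
    if size > len(pool):
        raise ValueError(f"negative pool ({len(pool)}) smaller than draw size ({size})")
    rng = np.random.default_rng(plan.rng_seed)
    return [np.sort(rng.choice(pool, size=size, replace=False)) for _ in range(plan.n_repeats)]


def stratified_kfold(labels: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment: per-class fold sizes differ by at most 1.

    Returns an integer array of fold indices in [0, k). Samples of each
    class are shuffled and dealt round-robin to folds; deterministic given
    the seed.
    """
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2 (k=1 leaves no held-out data)")
    rng = np.random.default_rng(seed)
    fold = np.empty(len(y), dtype=np.int64)
    classes = np.unique(y)
    for ci, cls in enumerate(classes):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls!r} has {len(idx)} members, fewer than k={k}")
        rng.shuffle(idx)
        # stagger the remainder across classes so overall fold sizes balance
        offset = (ci * k) // len(classes)
        fold[idx] = (np.arange(len(idx)) + offset) % k
    return fold


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def compute_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann–Whitney concordance probability.

    (concordant pairs + half the tied pairs) / (n_pos * n_neg), computed
    via midranks; mathematically identical to trapezoidal integration of
    the ROC curve.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores have different lengths")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s, method="average")
    rank_sum_pos = float(ranks[y == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def compute_aupr(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve (average precision).

    Descending-score sweep with tied scores processed as one group:
    AP = sum over groups of precision-after-group times the recall gained
    in that group (step-wise interpolation).
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores have different lengths")
    n_pos = float((y == 1).sum())
    if n_pos == 0:
        raise ValueError("AUPR undefined: no positive samples")

    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    # group boundaries: last index of each tied-score block
    boundary = np.flatnonzero(np.diff(s_sorted) != 0)
    ends = np.append(boundary, len(s_sorted) - 1)

    tp = np.cumsum(y_sorted)[ends]
    n_seen = ends + 1.0
    precision = tp / n_seen
    recall = tp / n_pos
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum(precision * (recall - recall_prev)))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def _classifier_factory(classifier):
    """Accept a Classifier instance (re-trained in place each fold), a
    classifier class, or a zero-argument factory callable."""
    if isinstance(classifier, type):
        return classifier
    if hasattr(classifier, "train") and hasattr(classifier, "score"):
        return lambda: classifier
    if callable(classifier):
        return classifier
    raise TypeError("classifier must expose train/score or be a factory")


def cross_validate(
    features: FeatureMatrix | np.ndarray,
    positives: Sequence[int],
    negative_pool: Sequence[int],
    classifier,
    plan: ResamplingPlan = ResamplingPlan(),
    k: int = 10,
    seed: int = 0,
    sd_mode: str = "population",
) -> CVResult:
    """Repeated stratified k-fold CV over balanced negative draws.

    For each negative draw the positives plus the drawn negatives form the
    dataset; each fold trains on k-1 folds and scores the held-out fold,
    yielding one AUC and one AUPR per fold. Train and test indices are
    asserted disjoint on every fold. ``classifier`` is either an object
    with train/score (re-trained each fold) or a zero-argument factory.

    Features are computed once on the full network beforehand; the
    diffusion embedding never sees the labels, so this does not leak
    held-out information.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    positives = np.asarray(sorted(positives), dtype=np.int64)
    factory = _classifier_factory(classifier)

    draws = sample_balanced_negatives(positives, negative_pool, plan)
    fold_seeds = np.random.SeedSequence(seed).generate_state(plan.n_repeats) % (2**31)

    per_fold_auc: list[float] = []
    per_fold_aupr: list[float] = []
    for rep, negatives in enumerate(draws):
        sample_idx = np.concatenate([positives, negatives])
        y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
        folds = stratified_kfold(y, k, seed=int(fold_seeds[rep]))
        for f in range(k):
            test_mask = folds == f
            train_rows = sample_idx[~test_mask]
            test_rows = sample_idx[test_mask]
            assert not set(train_rows) & set(test_rows), "train/test leakage"
            clf = factory()
            clf.train(X[train_rows], y[~test_mask])
            scores = clf.score(X[test_rows])
            per_fold_auc.append(compute_auc(y[test_mask], scores))
            per_fold_aupr.append(compute_aupr(y[test_mask], scores))

    result = CVResult(
        per_fold_auc=per_fold_auc,
        per_fold_aupr=per_fold_aupr,
        k=k,
        n_repeats=plan.n_repeats,
        sd_mode=sd_mode,
        config={
            "k": k,
            "n_repeats": plan.n_repeats,
            "negatives_per_draw": plan.negatives_per_draw or len(positives),
            "rng_seed": plan.rng_seed,
            "cv_seed": seed,
        },
    )
    logger.info("cross-validation: %s", result.summary())
    return result


def roc_curve_points(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """(FPR, TPR) points of the empirical ROC curve, tied scores grouped."""
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    boundary = np.flatnonzero(np.diff(s[order]) != 0)
    ends = np.append(boundary, len(y) - 1)
    tp = np.cumsum(y_sorted)[ends]
    fp = ends + 1 - tp
    n_pos = max(y.sum(), 1.0)
    n_neg = max(len(y) - y.sum(), 1.0)
    pts = np.column_stack([fp / n_neg, tp / n_pos])
    return np.vstack([[0.0, 0.0], pts])


def pr_curve_points(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """(recall, precision) points of the PR curve, tied scores grouped."""
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    boundary = np.flatnonzero(np.diff(s[order]) != 0)
    ends = np.append(boundary, len(y) - 1)
    tp = np.cumsum(y_sorted)[ends]
    precision = tp / (ends + 1.0)
    recall = tp / max(y.sum(), 1.0)
    return np.column_stack([recall, precision])


# ---------------------------------------------------------------------------
# Candidate ranking
# ---------------------------------------------------------------------------


def rank_candidates(
    features: FeatureMatrix | np.ndarray,
    positives: Sequence[int],
    negative_pool: Sequence[int],
    config: GBDTConfig | None = None,
    plan: ResamplingPlan = ResamplingPlan(),
    seed: int = 0,
) -> list[tuple[int, float, float]]:
    """Score every unlabeled gene, averaging over balanced negative draws.

    Trains one model per draw on positives + drawn negatives and scores the
    genes appearing in neither set. Returns (gene_index, mean_score,
    sd_across_draws) sorted by descending mean score; an empty list (with a
    warning) when every gene is labeled.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    gene_order = features.gene_order if isinstance(features, FeatureMatrix) else None
    positives = np.asarray(sorted(positives), dtype=np.int64)
    pool = np.asarray(sorted(negative_pool), dtype=np.int64)
    labeled = set(positives) | set(pool)
    unlabeled = np.array([i for i in range(X.shape[0]) if i not in labeled], dtype=np.int64)
    if len(unlabeled) == 0:
        logger.warning("no unlabeled genes to rank")
        return []

    cfg = config or GBDTConfig()
    draws = sample_balanced_negatives(positives, pool, plan)
    scores = np.empty((len(draws), len(unlabeled)))
    for rep, negatives in enumerate(draws):
        rows = np.concatenate([positives, negatives])
        y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
        model = fit_gbdt(X[rows], y, cfg, seed=seed)
        scores[rep] = model.predict_proba(X[unlabeled])

    mean = scores.mean(axis=0)
    sd = scores.std(axis=0)
    # descending score; gene index (or symbol order) breaks exact ties
    order = np.lexsort((unlabeled, -mean))
    ranked = [(int(unlabeled[i]), float(mean[i]), float(sd[i])) for i in order]
    if gene_order is not None:
        logger.info("top candidate: %s (score %.4f)", gene_order[ranked[0][0]], ranked[0][1])
    return ranked
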
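"""Gradient-boosted CART regression trees, built from first principles.

The classifier is a stagewise additive model

    f_M(x) = f_0 + sum_m sum_j gamma_jm * I(x in R_jm)

where each round fits a binary CART regression tree to the negative
gradient (pseudo-residual) of the loss at the current model and then
re-optimizes each leaf's value for the loss. The split search is exact:
every midpoint between consecutive distinct sorted values of every feature
is a candidate, and the (feature, threshold) pair minimizing total
within-region squared error wins, ties broken to the lower feature index
and then the lower threshold. Samples exactly at the threshold go left
(x^(j) <= s).

The tree grower is vectorized level-by-level over presorted feature
columns, so boosting many rounds on a few thousand features stays cheap
without approximate (histogram) splits.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numba
import numpy as np

logger = logging.getLogger(__name__)

_LOSSES = ("logistic", "squared")
_LEAF_CLIP = 4.0  # logistic leaf values clipped to +/- this for stability
_GAIN_EPS = 1e-12  # minimum relative SSE reduction to accept a split


@dataclass(frozen=True)
class SplitRule:
    """Axis-aligned split: left region is x^(feature_index) <= threshold."""

    feature_index: int
    threshold: float


@dataclass(frozen=True)
class GBDTConfig:
    """Boosting hyperparameters.

    n_rounds:
        Number of boosting rounds M.
    learning_rate:
        Shrinkage nu in (0, 1] scaling each tree's leaf values; 1 is the
        plain additive update, 0.1 the regularized default.
    max_depth / min_leaf / max_leaves:
        CART growth limits per round; ``max_leaves`` (J) is optional.
    loss:
        ``logistic`` (binomial deviance, for 0/1 labels) or ``squared``.
    """

    n_rounds: int = 200
    learning_rate: float = 0.1
    max_depth: int = 3
    min_leaf: int = 5
    max_leaves: int | None = None
    loss: str = "logistic"

    def __post_init__(self) -> None:
        if self.n_rounds < 0:
            raise ValueError("n_rounds must be >= 0")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.loss not in _LOSSES:
            raise ValueError(f"loss must be one of {_LOSSES}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class RegressionTree:
    """Binary CART regression tree stored as flat node arrays.

    Internal nodes hold a :class:`SplitRule`; leaves hold the fitted value
    (the region mean for plain CART, the loss-optimal step for boosting).
    """

    def __init__(self) -> None:
        self.feature: list[int] = [-1]
        self.threshold: list[float] = [np.nan]
        self.left: list[int] = [-1]
        self.right: list[int] = [-1]
        self.value: list[float] = [0.0]
        self.count: list[int] = [0]

    # -- construction ------------------------------------------------------

    def _add_children(self, node: int, j: int, s: float) -> tuple[int, int]:
        li, ri = len(self.feature), len(self.feature) + 1
        for _ in range(2):
            self.feature.append(-1)
            self.threshold.append(np.nan)
            self.left.append(-1)
            self.right.append(-1)
            self.value.append(0.0)
            self.count.append(0)
        self.feature[node] = j
        self.threshold[node] = s
        self.left[node] = li
        self.right[node] = ri
        return li, ri

    def _freeze(self) -> None:
        self._feat = np.asarray(self.feature, dtype=np.int64)
        self._thr = np.asarray(self.threshold, dtype=float)
        self._left = np.asarray(self.left, dtype=np.int64)
        self._right = np.asarray(self.right, dtype=np.int64)
        self._val = np.asarray(self.value, dtype=float)

    # -- inspection --------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def leaf_ids(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.feature) < 0)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids())

    def set_leaf_values(self, values: dict[int, float]) -> None:
        for node, v in values.items():
            if self.feature[node] >= 0:
                raise ValueError(f"node {node} is not a leaf")
            self.value[node] = float(v)
        self._freeze()

    # -- prediction --------------------------------------------------------

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf node id reached by each sample."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        node = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            active = self._feat[node] >= 0
            if not active.any():
                return node
            idx = np.flatnonzero(active)
            cur = node[idx]
            go_left = X[idx, self._feat[cur]] <= self._thr[cur]
            node[idx] = np.where(go_left, self._left[cur], self._right[cur])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._val[self.apply(X)]

    # -- serialization -----------------------------------------------------

    def _node_dict(self, node: int) -> dict:
        if self.feature[node] < 0:
            return {"value": self.value[node], "count": self.count[node]}
        return {
            "feature_index": int(self.feature[node]),
            "threshold": float(self.threshold[node]),
            "left": self._node_dict(self.left[node]),
            "right": self._node_dict(self.right[node]),
        }

    def to_dict(self) -> dict:
        return self._node_dict(0)

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        tree = cls()

        def build(node_id: int, nd: dict) -> None:
            if "feature_index" not in nd:
                tree.value[node_id] = float(nd["value"])
                tree.count[node_id] = int(nd.get("count", 0))
                return
            li, ri = tree._add_children(node_id, int(nd["feature_index"]), float(nd["threshold"]))
            build(li, nd["left"])
            build(ri, nd["right"])

        build(0, d)
        tree._freeze()
        return tree


# ---------------------------------------------------------------------------
# Split search
# ---------------------------------------------------------------------------
#
# The exact split scan is compiled with numba. Feature values, targets and
# the per-feature sorted sample indices are kept column-contiguous
# (Fortran order), so each feature's scan touches one contiguous int32
# column plus L1-resident random reads of X and y — a single fused pass
# instead of a stack of temporaries. Both kernels preserve the CART
# semantics exactly: every midpoint between consecutive distinct sorted
# values is a candidate, ties break to the lower feature index and then
# the lower threshold, and the within-node partition is stable.


@numba.njit(cache=True, fastmath=False)
def _level_best_splits(XF, y, sidx, seg_a, seg_b, totals, min_leaf):  # pragma: no cover
    """Best split per segment. Segments are contiguous row ranges of the
    per-feature sorted index matrix ``sidx``; ``totals`` holds each
    segment's target sum. Returns (feature, position, threshold, score)
    per segment; feature -1 means no valid candidate."""
    F = XF.shape[1]
    S = seg_a.shape[0]
    best_j = np.full(S, -1, np.int64)
    best_pos = np.full(S, -1, np.int64)
    best_thr = np.zeros(S, np.float64)
    best_score = np.full(S, -np.inf)
    for j in range(F):
        for s in range(S):
            a, b = seg_a[s], seg_b[s]
            m = b - a
            if m < 2 * min_leaf:
                continue
            total = totals[s]
            left_sum = 0.0
            for r in range(a, b - 1):
                i = sidx[r, j]
                left_sum += y[i]
                l = r - a + 1
                if l < min_leaf or m - l < min_leaf:
                    continue
                x_here = XF[i, j]
                x_next = XF[sidx[r + 1, j], j]
                if x_next <= x_here:
                    continue
                right_sum = total - left_sum
                score = left_sum * left_sum / l + right_sum * right_sum / (m - l)
                if score > best_score[s]:
                    best_score[s] = score
                    best_j[s] = j
                    best_pos[s] = r - a
                    best_thr[s] = (x_here + x_next) / 2.0
    return best_j, best_pos, best_thr, best_score


@numba.njit(cache=True)
def _level_partition(sidx, seg_a, seg_b, go_left, buf):  # pragma: no cover
    """Stable in-place partition of each segment's sorted-index columns:
    samples with ``go_left`` keep relative order and move to the front."""
    F = sidx.shape[1]
    S = seg_a.shape[0]
    for j in range(F):
        for s in range(S):
            a, b = seg_a[s], seg_b[s]
            lpos = a
            rcount = 0
            for r in range(a, b):
                i = sidx[r, j]
                if go_left[i]:
                    sidx[lpos, j] = i
                    lpos += 1
                else:
                    buf[rcount] = i
                    rcount += 1
            for t in range(rcount):
                sidx[lpos + t, j] = buf[t]


def _presort(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-contiguous feature matrix and per-feature stable argsort."""
    XF = np.asfortranarray(X, dtype=np.float64)
    order = np.asfortranarray(np.argsort(XF, axis=0, kind="stable").astype(np.int32))
    return XF, order


def best_split(
    features: np.ndarray, targets: np.ndarray, min_leaf: int = 1
) -> tuple[SplitRule | None, float]:
    """Exhaustive best split of one region; returns (rule, post-split SSE).

    The rule minimizes total within-region squared error over every
    (feature, midpoint-threshold) candidate; it is None when no split
    satisfies ``min_leaf`` on both sides or reduces the squared error, and
    the returned SSE is then that of the unsplit region.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and np.asarray(targets).size > 1:
        X = X.T
    y = np.ascontiguousarray(targets, dtype=np.float64)
    m = X.shape[0]
    node_sse = float(((y - y.mean()) ** 2).sum()) if m else 0.0
    if m < 2 * min_leaf or m < 2 or node_sse <= 1e-12:
        return None, node_sse
    XF, order = _presort(X)
    total = np.array([y.sum()])
    js, pos, thr, score = _level_best_splits(
        XF, y, order, np.array([0]), np.array([m]), total, min_leaf
    )
    base = float(total[0]) ** 2 / m
    gain = float(score[0]) - base
    if js[0] < 0 or gain <= _GAIN_EPS * max(1.0, abs(base)):
        return None, node_sse
    return SplitRule(feature_index=int(js[0]), threshold=float(thr[0])), node_sse - gain


# ---------------------------------------------------------------------------
# Tree fitting (level-wise, presorted)
# ---------------------------------------------------------------------------


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    max_depth: int,
    min_leaf: int,
    max_leaves: int | None = None,
    presorted: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[RegressionTree, np.ndarray]:
    """Fit a CART regression tree; returns (tree, leaf id per sample).

    ``presorted`` is the (XF, order) pair from :func:`_presort` and may be
    shared across boosting rounds (X does not change between rounds). Each
    level scans the per-feature sorted sample indices for the best exact
    split per node, then stably repartitions the index columns — no
    re-sort after the initial one.
    """
    if presorted is None:
        XF, order = _presort(np.atleast_2d(np.asarray(X, dtype=float)))
    else:
        XF, order = presorted
    y = np.ascontiguousarray(y, dtype=np.float64)
    n, _F = XF.shape
    if n == 0:
        raise ValueError("empty dataset")

    tree = RegressionTree()
    tree.value[0] = float(y.mean())
    tree.count[0] = n
    leaf_of = np.zeros(n, dtype=np.int64)

    sidx = order.copy(order="F")
    # active segments: (start, end, node_id, sum(y), sum(y^2)), contiguous rows
    segments: list[tuple[int, int, int, float, float]] = [
        (0, n, 0, float(y.sum()), float(y @ y))
    ]
    n_leaves = 1
    buf = np.empty(n, dtype=np.int32)

    for _depth in range(max_depth):
        if not segments:
            break
        # a region is split whenever a valid candidate exists and the region
        # is not pure — zero immediate gain is allowed, since a deeper split
        # may still reduce the error (XOR-type interactions); the reference
        # CART behavior.
        candidates = [
            seg for seg in segments
            if seg[1] - seg[0] >= 2 * min_leaf
            and seg[4] - seg[3] ** 2 / (seg[1] - seg[0]) > 1e-12
        ]
        if not candidates:
            break
        seg_a = np.array([s[0] for s in candidates], dtype=np.int64)
        seg_b = np.array([s[1] for s in candidates], dtype=np.int64)
        totals = np.array([s[3] for s in candidates], dtype=np.float64)
        js, pos, thr, score = _level_best_splits(
            XF, y, sidx, seg_a, seg_b, totals, min_leaf
        )

        splits: list[tuple[int, int, int, int, float, int]] = []
        for si, (a, b, node, _total, _sumsq) in enumerate(candidates):
            if js[si] < 0:
                continue
            if max_leaves is not None and n_leaves + 1 > max_leaves:
                continue
            splits.append((a, b, node, int(js[si]), float(thr[si]), int(pos[si])))
            n_leaves += 1
        if not splits:
            break

        go_left = np.zeros(n, dtype=np.bool_)
        for a, b, node, j, s, _p in splits:
            rows = sidx[a:b, 0]
            go_left[rows] = XF[rows, j] <= s
        _level_partition(
            sidx,
            np.array([sp[0] for sp in splits], dtype=np.int64),
            np.array([sp[1] for sp in splits], dtype=np.int64),
            go_left,
            buf,
        )

        next_segments: list[tuple[int, int, int, float, float]] = []
        for a, b, node, j, s, p in splits:
            n_left = p + 1
            li, ri = tree._add_children(node, j, s)
            yl = y[sidx[a : a + n_left, 0]]
            yr = y[sidx[a + n_left : b, 0]]
            leaf_of[sidx[a : a + n_left, 0]] = li
            leaf_of[sidx[a + n_left : b, 0]] = ri
            left_sum, right_sum = float(yl.sum()), float(yr.sum())
            tree.value[li] = left_sum / n_left
            tree.value[ri] = right_sum / (b - a - n_left)
            tree.count[li] = n_left
            tree.count[ri] = b - a - n_left
            next_segments.append((a, a + n_left, li, left_sum, float(yl @ yl)))
            next_segments.append((a + n_left, b, ri, right_sum, float(yr @ yr)))
        segments = next_segments

    tree._freeze()
    return tree, leaf_of


def fit_regression_tree(
    features: np.ndarray,
    targets: np.ndarray,
    max_depth: int = 3,
    min_leaf: int = 1,
    max_leaves: int | None = None,
) -> RegressionTree:
    """Fit a plain CART regression tree; leaves predict their region mean.

    Growth stops at ``max_depth``, when a region is pure, or when no
    candidate satisfies ``min_leaf`` on both sides (all feature values
    tied). A non-pure region is split even when the immediate error
    reduction is zero, since child splits may still reduce it.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and np.asarray(targets).size > 1:
        X = X.T
    tree, _ = _grow_tree(X, np.asarray(targets, float), max_depth, min_leaf, max_leaves)
    return tree


# ---------------------------------------------------------------------------
# Boosting
# ---------------------------------------------------------------------------


def init_model(labels: np.ndarray, loss: str) -> float:
    """Optimal constant initial score f0 = argmin_c sum L(y_i, c).

    Squared loss: the label mean. Logistic loss: the log-odds of the
    positive rate, which requires both classes to be present.
    """
    y = np.asarray(labels, dtype=float)
    if loss == "squared":
        return float(y.mean())
    if loss == "logistic":
        p = float(y.mean())
        if p <= 0.0 or p >= 1.0:
            raise ValueError("degenerate labels: logistic loss needs both classes")
        return float(np.log(p / (1.0 - p)))
    raise ValueError(f"loss must be one of {_LOSSES}")


def negative_gradient(labels: np.ndarray, f_current: np.ndarray, loss: str) -> np.ndarray:
    """Pseudo-residual r_i = -dL(y_i, f)/df at the current model.

    Squared loss: y - f. Logistic loss: y - sigmoid(f), always in (-1, 1).
    """
    y = np.asarray(labels, dtype=float)
    f = np.asarray(f_current, dtype=float)
    if y.shape != f.shape:
        raise ValueError("labels and scores have different lengths")
    if loss == "squared":
        return y - f
    if loss == "logistic":
        return y - _sigmoid(f)
    raise ValueError(f"loss must be one of {_LOSSES}")


def fit_leaf_values(
    tree: RegressionTree,
    features: np.ndarray,
    labels: np.ndarray,
    f_prev: np.ndarray,
    loss: str,
    leaf_of: np.ndarray | None = None,
) -> dict[int, float]:
    """Loss-optimal per-leaf step gamma_jm = argmin sum L(y_i, f_prev + gamma).

    Squared loss has the closed form (the leaf mean of the residuals);
    logistic loss takes the standard single Newton step
    sum(r) / sum(p (1 - p)) with p = sigmoid(f_prev), clipped to
    [-4, 4]. A zero Newton denominator yields 0 with a logged warning.
    """
    y = np.asarray(labels, dtype=float)
    f = np.asarray(f_prev, dtype=float)
    if leaf_of is None:
        leaf_of = tree.apply(np.asarray(features, dtype=float))
    r = negative_gradient(y, f, loss)
    values: dict[int, float] = {}
    for leaf in tree.leaf_ids():
        mask = leaf_of == leaf
        if not mask.any():
            values[int(leaf)] = 0.0
            continue
        if loss == "squared":
            values[int(leaf)] = float(r[mask].mean())
            continue
        num = float(r[mask].sum())
        p = _sigmoid(f[mask])
        den = float((p * (1.0 - p)).sum())
        if den <= 0.0:
            logger.warning("zero Newton denominator at leaf %d; value set to 0", leaf)
            values[int(leaf)] = 0.0
        else:
            values[int(leaf)] = float(np.clip(num / den, -_LEAF_CLIP, _LEAF_CLIP))
    return values


def _training_loss(y: np.ndarray, f: np.ndarray, loss: str) -> float:
    if loss == "squared":
        return float(((y - f) ** 2).sum())
    # binomial deviance: sum log(1 + exp(-(2y-1) f)) in the 0/1 convention
    margin = np.where(y > 0.5, f, -f)
    return float(np.logaddexp(0.0, -margin).sum())


@dataclass
class GBDTModel:
    """Fitted boosted-tree model: f(x) = f0 + sum of (already shrunk) trees."""

    f0: float
    trees: list[RegressionTree]
    loss: str
    config: GBDTConfig
    train_loss: list[float] = field(default_factory=list)
    n_features: int | None = None

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if self.n_features is not None and X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} != training dimension {self.n_features}"
            )
        score = np.full(X.shape[0], self.f0, dtype=float)
        for tree in self.trees:
            score += tree.predict(X)
        return score

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        score = self.decision_function(features)
        return _sigmoid(score) if self.loss == "logistic" else score

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "f0": self.f0,
            "loss": self.loss,
            "learning_rate": self.config.learning_rate,
            "config": {
                "n_rounds": self.config.n_rounds,
                "learning_rate": self.config.learning_rate,
                "max_depth": self.config.max_depth,
                "min_leaf": self.config.min_leaf,
                "max_leaves": self.config.max_leaves,
                "loss": self.config.loss,
            },
            "n_features": self.n_features,
            "train_loss": self.train_loss,
            "trees": [t.to_dict() for t in self.trees],
        }

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
                fh.write("\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "GBDTModel":
        cfg = GBDTConfig(**d["config"])
        return cls(
            f0=float(d["f0"]),
            trees=[RegressionTree.from_dict(t) for t in d["trees"]],
            loss=d["loss"],
            config=cfg,
            train_loss=[float(v) for v in d.get("train_loss", [])],
            n_features=d.get("n_features"),
        )

    @classmethod
    def from_json(cls, text_or_path: str | os.PathLike) -> "GBDTModel":
        text = str(text_or_path)
        if os.path.exists(text):
            with open(text) as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))


def fit_gbdt(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: GBDTConfig = GBDTConfig(),
    seed: int = 0,
) -> GBDTModel:
    """Fit the boosted model: M rounds of residual-tree fitting.

    Each round computes the negative gradient at the current scores, grows
    a CART regression tree on (x_i, r_i), replaces each leaf's value by the
    loss-optimal step scaled by the learning rate, and adds the tree to the
    ensemble. Training loss (deviance or SSE) is recorded per round.

    The fit itself is deterministic (no row or column subsampling); ``seed``
    is accepted for interface symmetry with stochastic classifiers.
    """
    del seed  # deterministic: exact greedy splits, no subsampling
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels have different sample counts")

    f0 = init_model(y, cfg.loss)
    f = np.full(X.shape[0], f0, dtype=float)
    trees: list[RegressionTree] = []
    losses = [_training_loss(y, f, cfg.loss)]

    presorted = _presort(X)  # shared across rounds: X never changes
    for _round in range(cfg.n_rounds):
        r = negative_gradient(y, f, cfg.loss)
        tree, leaf_of = _grow_tree(
            X, r, cfg.max_depth, cfg.min_leaf, cfg.max_leaves, presorted=presorted
        )
        gammas = fit_leaf_values(tree, X, y, f, cfg.loss, leaf_of=leaf_of)
        scaled = {leaf: cfg.learning_rate * g for leaf, g in gammas.items()}
        tree.set_leaf_values(scaled)
        f += tree._val[leaf_of]
        trees.append(tree)
        losses.append(_training_loss(y, f, cfg.loss))

    return GBDTModel(
        f0=f0,
        trees=trees,
        loss=cfg.loss,
        config=cfg,
        train_loss=losses,
        n_features=X.shape[1],
    )


def predict_score(model: GBDTModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw additive score and its probability mapping (sigmoid under logistic)."""
    raw = model.decision_function(features)
    prob = _sigmoid(raw) if model.loss == "logistic" else raw
    return raw, prob
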
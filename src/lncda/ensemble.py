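"""Pair classification: feed-forward network, boosted trees, soft voting.

A lncRNA-disease pair is represented by the concatenation of the lncRNA and
disease embedding columns (length 2F).  Two member classifiers score each
pair — a feed-forward network with rectified hidden layers and a logistic
output, and an additive ensemble of regression trees trained on the
second-order (Newton) approximation of the logistic loss: per round the
gradients are g_i = p_i - y_i and hessians h_i = p_i(1 - p_i), splits are
chosen by the regularized gain

    G = 1/2 [ (Sum_L g)^2/(Sum_L h + lambda) + (Sum_R g)^2/(Sum_R h + lambda)
              - (Sum g)^2/(Sum h + lambda) ]

and leaves get the optimal weight w* = -Sum g / (Sum h + lambda).  The tree
learner here is exact greedy on raw feature values (tables at this scale are
tiny); an established histogram-based boosting backend can be swapped in for
cross-checking.  The final score is the soft vote
alpha * C_DNN + beta * C_trees (defaults 0.4 / 0.6) with a pair called
positive iff its score exceeds 0.5 strictly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone

from .autodiff import Adam, Tensor, bce_with_logits, sigmoid_np
from .encoder import EncoderState

__all__ = [
    "PairFeatureTable",
    "build_pair_features",
    "DNNClassifier",
    "GradientBoostingTrees",
    "SoftVotingClassifier",
    "leaf_weight_and_gain",
    "soft_vote",
]


# ---------------------------------------------------------------------------
# pair features
# ---------------------------------------------------------------------------

@dataclass
class PairFeatureTable:
    """Feature vectors for lncRNA-disease pairs (one row per pair)."""

    pairs: list[tuple[int, int]]
    X: np.ndarray                      # len(pairs) x 2F
    y: np.ndarray | None = None        # 0/1 labels or None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite features")
        if len(self.pairs) != self.X.shape[0]:
            raise ValueError("pair/feature row mismatch")
        if self.y is not None:
            self.y = np.asarray(self.y)
            if len(self.y) != len(self.pairs):
                raise ValueError("label length mismatch")


def build_pair_features(state: EncoderState, pairs: list[tuple[int, int]],
                        labels: np.ndarray | None = None) -> PairFeatureTable:
    """Concatenate embedding columns: x = [X_c[:, i] || X_d[:, j]]."""
    n, m = state.X_c.shape[1], state.X_d.shape[1]
    for i, j in pairs:
        if not (0 <= i < n and 0 <= j < m):
            raise IndexError(f"pair ({i}, {j}) out of range for {n} x {m}")
    idx_l = np.fromiter((p[0] for p in pairs), dtype=int, count=len(pairs))
    idx_d = np.fromiter((p[1] for p in pairs), dtype=int, count=len(pairs))
    X = np.hstack([state.X_c[:, idx_l].T, state.X_d[:, idx_d].T])
    return PairFeatureTable(list(pairs), X, labels)


# ---------------------------------------------------------------------------
# feed-forward network
# ---------------------------------------------------------------------------

class DNNClassifier(BaseEstimator, ClassifierMixin):
    """Fully connected binary classifier with ReLU hidden layers.

    Hidden unit pre-activations are affine (h = sum_i w_i x_i + b),
    rectified; the output layer applies the logistic function
    sigma(h) = 1 / (1 + e^{-h}).  Trained full-batch with Adam on binary
    cross-entropy, so runs are deterministic for a fixed seed.
    """

    def __init__(self, hidden_layer_sizes: tuple[int, ...] = (128, 64),
                 epochs: int = 200, learning_rate: float = 1e-3, seed: int = 0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed

    @classmethod
    def from_weights(cls, weights: list[np.ndarray],
                     biases: list[np.ndarray]) -> "DNNClassifier":
        """Build an already-'fitted' model from explicit layer parameters."""
        model = cls(hidden_layer_sizes=tuple(w.shape[1] for w in weights[:-1]))
        model.weights_ = [np.asarray(w, dtype=np.float64) for w in weights]
        model.biases_ = [np.asarray(b, dtype=np.float64) for b in biases]
        model.classes_ = np.array([0, 1])
        return model

    def _decision_raw(self, X: np.ndarray) -> np.ndarray:
        H = np.asarray(X, dtype=np.float64)
        if H.shape[1] != self.weights_[0].shape[0]:
            raise ValueError("feature dimension mismatch")
        for W, b in zip(self.weights_[:-1], self.biases_[:-1]):
            H = np.maximum(H @ W + b, 0.0)
        return (H @ self.weights_[-1] + self.biases_[-1]).ravel()

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DNNClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes present to train")
        rng = np.random.default_rng(self.seed)
        sizes = [X.shape[1], *self.hidden_layer_sizes, 1]
        Ws = [Tensor(rng.uniform(-1, 1, (a, b)) * np.sqrt(6.0 / (a + b)),
                     requires_grad=True) for a, b in zip(sizes[:-1], sizes[1:])]
        bs = [Tensor(np.zeros(b), requires_grad=True) for b in sizes[1:]]
        opt = Adam(Ws + bs, lr=self.learning_rate)
        Xt = Tensor(X)
        history = []
        for epoch in range(self.epochs):
            opt.zero_grad()
            H = Xt
            for W, b in zip(Ws[:-1], bs[:-1]):
                H = (H @ W + b).relu()
            logits = H @ Ws[-1] + bs[-1]
            loss = bce_with_logits(logits, y[:, None])
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"training diverged at epoch {epoch + 1}")
            history.append(float(loss.data))
            loss.backward()
            opt.step()
        self.weights_ = [W.data for W in Ws]
        self.biases_ = [b.data for b in bs]
        self.loss_history_ = history
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._decision_raw(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = sigmoid_np(self._decision_raw(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


# ---------------------------------------------------------------------------
# second-order gradient boosting
# ---------------------------------------------------------------------------

def leaf_weight_and_gain(g: np.ndarray, h: np.ndarray, lam: float = 0.0,
                         left_mask: np.ndarray | None = None) -> tuple[float, float]:
    """Optimal leaf weight of a node and (optionally) the gain of a split.

    ``w* = -Sum g / (Sum h + lambda)``.  With ``left_mask`` given, also the
    regularized gain of splitting the node into left/right halves; without a
    split the gain is 0.
    """
    g = np.asarray(g, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    if h.sum() + lam <= 0:
        raise ZeroDivisionError("Sum h + lambda must be positive")
    w_star = -g.sum() / (h.sum() + lam)
    if left_mask is None:
        return w_star, 0.0
    left = np.asarray(left_mask, dtype=bool)
    gl, hl = g[left].sum(), h[left].sum()
    gr, hr = g[~left].sum(), h[~left].sum()
    gain = 0.5 * (gl ** 2 / (hl + lam) + gr ** 2 / (hr + lam)
                  - (gl + gr) ** 2 / (hl + hr + lam))
    return w_star, gain


@dataclass
class _TreeNode:
    feature: int = -1
    threshold: float = 0.0
    left: int = -1
    right: int = -1
    value: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0


class _RegressionTree:
    """Leaf-wise exact-greedy tree on (g, h) statistics."""

    def __init__(self, max_leaves: int, lam: float):
        self.max_leaves = max_leaves
        self.lam = lam
        self.nodes: list[_TreeNode] = []

    @staticmethod
    def _best_split(X, g, h, idx, lam):
        """Exact scan over all features/thresholds of one node.

        Returns (gain, feature, threshold, left_idx); gain 0 and feature -1
        when no value change offers a positive gain.  Thresholds are
        midpoints between consecutive distinct sorted values.
        """
        best_gain, best = 0.0, (-1, 0.0, None)
        gp, hp = g[idx].sum(), h[idx].sum()
        parent_term = gp ** 2 / (hp + lam)
        for f in range(X.shape[1]):
            vals = X[idx, f]
            order = np.argsort(vals, kind="mergesort")
            sv = vals[order]
            change = np.nonzero(sv[1:] > sv[:-1])[0]
            if change.size == 0:
                continue
            sg = np.cumsum(g[idx][order])
            sh = np.cumsum(h[idx][order])
            gl, hl = sg[change], sh[change]
            gains = 0.5 * (gl ** 2 / (hl + lam)
                           + (gp - gl) ** 2 / (hp - hl + lam) - parent_term)
            t = int(np.argmax(gains))
            if gains[t] > best_gain + 1e-12:
                c = change[t]
                best_gain = float(gains[t])
                best = (f, 0.5 * (sv[c] + sv[c + 1]), idx[order[:c + 1]])
        return best_gain, *best

    def fit(self, X, g, h):
        import heapq

        root_idx = np.arange(X.shape[0])
        w, _ = leaf_weight_and_gain(g[root_idx], h[root_idx], self.lam)
        self.nodes = [_TreeNode(value=w)]
        # best-first growth: heap of candidate splits keyed by -gain, with
        # node id as the deterministic tie-break
        heap: list = []
        gain, f, thr, left_idx = self._best_split(X, g, h, root_idx, self.lam)
        if f >= 0:
            heapq.heappush(heap, (-gain, 0, thr, f, root_idx, left_idx))
        n_leaves = 1
        while n_leaves < self.max_leaves and heap:
            neg_gain, node_id, thr, f, idx, left_idx = heapq.heappop(heap)
            if -neg_gain <= 0:
                break
            in_left = np.zeros(X.shape[0], dtype=bool)
            in_left[left_idx] = True
            right_idx = idx[~in_left[idx]]
            wl, _ = leaf_weight_and_gain(g[left_idx], h[left_idx], self.lam)
            wr, _ = leaf_weight_and_gain(g[right_idx], h[right_idx], self.lam)
            self.nodes.append(_TreeNode(value=wl))
            self.nodes.append(_TreeNode(value=wr))
            node = self.nodes[node_id]
            node.feature, node.threshold = f, thr
            node.left, node.right = len(self.nodes) - 2, len(self.nodes) - 1
            for child_id, child_idx in ((node.left, left_idx), (node.right, right_idx)):
                if len(child_idx) >= 2:
                    cg, cf, cthr, cleft = self._best_split(X, g, h, child_idx, self.lam)
                    if cf >= 0:
                        heapq.heappush(heap, (-cg, child_id, cthr, cf, child_idx, cleft))
            n_leaves += 1
        return self

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes if n.is_leaf)

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        for r in range(X.shape[0]):
            node = self.nodes[0]
            while not node.is_leaf:
                node = self.nodes[node.left] if X[r, node.feature] <= node.threshold \
                    else self.nodes[node.right]
            out[r] = node.value
        return out


class GradientBoostingTrees(BaseEstimator, ClassifierMixin):
    """Additive regression-tree classifier with a Newton (second-order) objective.

    The built-in trainer grows each tree leaf-wise by exact greedy split
    search; ``backend='lightgbm'`` delegates to the histogram-based library
    with matched hyperparameters (used for parity checks).
    """

    def __init__(self, n_estimators: int = 100, max_leaves: int = 31,
                 reg_lambda: float = 1.0, learning_rate: float = 0.1,
                 seed: int = 0, backend: str = "builtin"):
        self.n_estimators = n_estimators
        self.max_leaves = max_leaves
        self.reg_lambda = reg_lambda
        self.learning_rate = learning_rate
        self.seed = seed
        self.backend = backend

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GradientBoostingTrees":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if not np.isfinite(X).all():
            raise ValueError("non-finite features")
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes present to train")
        if self.backend == "lightgbm":
            import lightgbm as lgb
            self._lgb_ = lgb.LGBMClassifier(
                n_estimators=self.n_estimators, num_leaves=self.max_leaves,
                reg_lambda=self.reg_lambda, learning_rate=self.learning_rate,
                min_child_samples=1, min_split_gain=0.0, subsample=1.0,
                colsample_bytree=1.0, random_state=self.seed, verbose=-1)
            self._lgb_.fit(X, y.astype(int))
            self.trees_ = []
            self.classes_ = np.array([0, 1])
            return self
        if self.backend != "builtin":
            raise ValueError(f"unknown backend {self.backend!r}")
        self.trees_: list[_RegressionTree] = []
        F = np.zeros(X.shape[0])  # raw scores; sigmoid(0) = 0.5 start
        for _ in range(self.n_estimators):
            p = sigmoid_np(F)
            g = p - y
            h = p * (1.0 - p)
            tree = _RegressionTree(self.max_leaves, self.reg_lambda).fit(X, g, h)
            F += self.learning_rate * tree.predict(X)
            self.trees_.append(tree)
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        F = np.zeros(X.shape[0])
        for tree in self.trees_:
            F += self.learning_rate * tree.predict(X)
        return F

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if getattr(self, "_lgb_", None) is not None and not self.trees_:
            return self._lgb_.predict_proba(np.asarray(X, dtype=np.float64))
        p = sigmoid_np(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


# ---------------------------------------------------------------------------
# soft voting
# ---------------------------------------------------------------------------

def soft_vote(c_dnn: np.ndarray, c_gbm: np.ndarray, alpha: float = 0.4,
              beta: float = 0.6, threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-average ensemble score and strict-threshold labels.

    Score = alpha * C_DNN + beta * C_trees; a pair is positive iff
    Score > threshold (ties at the threshold are negative).
    """
    c_dnn = np.asarray(c_dnn, dtype=np.float64)
    c_gbm = np.asarray(c_gbm, dtype=np.float64)
    if c_dnn.shape != c_gbm.shape:
        raise ValueError("score vectors differ in length")
    for name, c in (("c_dnn", c_dnn), ("c_gbm", c_gbm)):
        if ((c < 0) | (c > 1)).any():
            raise ValueError(f"{name} outside [0, 1]")
    if alpha < 0 or beta < 0 or abs(alpha + beta - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    score = alpha * c_dnn + beta * c_gbm
    return score, (score > threshold).astype(int)


class SoftVotingClassifier(BaseEstimator, ClassifierMixin):
    """Soft-voting ensemble of the network and tree classifiers."""

    def __init__(self, dnn: DNNClassifier | None = None,
                 gbm: GradientBoostingTrees | None = None,
                 alpha: float = 0.4, beta: float = 0.6, threshold: float = 0.5):
        self.dnn = dnn
        self.gbm = gbm
        self.alpha = alpha
        self.beta = beta
        self.threshold = threshold

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SoftVotingClassifier":
        soft_vote(np.zeros(1), np.zeros(1), self.alpha, self.beta, self.threshold)
        self.dnn_ = clone(self.dnn) if self.dnn is not None else DNNClassifier()
        self.gbm_ = clone(self.gbm) if self.gbm is not None else GradientBoostingTrees()
        self.dnn_.fit(X, y)
        self.gbm_.fit(X, y)
        self.classes_ = np.array([0, 1])
        return self

    def member_scores(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.dnn_.predict_proba(X)[:, 1], self.gbm_.predict_proba(X)[:, 1]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        cd, cg = self.member_scores(X)
        score, _ = soft_vote(cd, cg, self.alpha, self.beta, self.threshold)
        return np.column_stack([1.0 - score, score])

    def predict(self, X: np.ndarray) -> np.ndarray:
        cd, cg = self.member_scores(X)
        _, labels = soft_vote(cd, cg, self.alpha, self.beta, self.threshold)
        return labels
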
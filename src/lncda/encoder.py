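"""GCN -> GAT -> GCN graph encoder with a 1-D CNN combiner.

Each similarity graph (lncRNA side C, disease side D) is passed through a
graph-convolution layer, a multi-head graph-attention layer and a second
graph-convolution layer.  The first and third layer outputs are combined by
a two-channel 1-D convolution along the feature axis into the embedding
matrices ``X_c`` (F x n) and ``X_d`` (F x m).  Their inner product
``U = X_c^T X_d`` is the preference matrix; training minimizes the binary
cross-entropy between ``sigmoid(U)`` and the known association matrix Y by
Adam over all layer, attention and convolution parameters.

Initial node features are the similarity matrix rows themselves, so the
encoder needs no external feature source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .autodiff import Adam, Tensor, bce_with_logits, sigmoid_np, stack2
from .data import AssociationNetwork
from .similarity import SimilarityMatrix

__all__ = [
    "EncoderConfig",
    "EncoderState",
    "GraphEncoder",
    "gcn_forward",
    "gat_forward",
    "combine_cnn",
    "preference_matrix",
    "normalized_propagation",
]


@dataclass
class EncoderConfig:
    """Hyperparameters of the graph encoder."""

    embedding_dim: int = 64
    heads: int = 2
    epochs: int = 200
    learning_rate: float = 1e-3
    cnn_kernel_width: int = 3
    negative_slope: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if self.heads < 1 or self.epochs < 1 or self.cnn_kernel_width < 1:
            raise ValueError("heads, epochs and cnn_kernel_width must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class EncoderState:
    """Layer outputs, embeddings and preference matrix of one forward pass."""

    H_c: list[np.ndarray]  # [H0, H1, H2, H3] for the lncRNA graph
    H_d: list[np.ndarray]
    X_c: np.ndarray        # F x n
    X_d: np.ndarray        # F x m
    U: np.ndarray          # n x m preference matrix
    loss_history: list[float] = field(default_factory=list)
    config: EncoderConfig | None = None


def normalized_propagation(S: np.ndarray) -> np.ndarray:
    """Symmetric normalized propagation operator A^{-1/2} (I + S) A^{-1/2}.

    A is the diagonal degree matrix of S' = I + S; its diagonal is >= 1, so
    the operator is always defined.
    """
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    Sp = S + np.eye(S.shape[0])
    dinv = 1.0 / np.sqrt(Sp.sum(axis=1))
    return dinv[:, None] * Sp * dinv[None, :]


def _gcn(P: Tensor, H: Tensor, Q: Tensor) -> Tensor:
    return ((P @ H) @ Q).relu()


def gcn_forward(S: np.ndarray, H: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Graph-convolution layer: ReLU(A^{-1/2}(I+S)A^{-1/2} H Q)."""
    S = np.asarray(S, dtype=np.float64)
    H = np.asarray(H, dtype=np.float64)
    if H.shape[0] != S.shape[0]:
        raise ValueError("H rows must match S")
    return _gcn(Tensor(normalized_propagation(S)), Tensor(H), Tensor(Q)).data


@dataclass
class GATParams:
    """Per-head parameters of one graph-attention layer.

    Each head k carries a weight matrix W_k (F_in x F_out), an attention
    vector a_k of length 2*F_out + 1 and a trainable edge-weight scalar B_k
    that multiplies the similarity S_ij inside the attention logit.
    """

    W: list[Tensor]
    a: list[Tensor]
    B: list[Tensor]
    negative_slope: float = 0.2

    @property
    def heads(self) -> int:
        return len(self.W)


def _gat(S: np.ndarray, H: Tensor, params: GATParams,
         return_attention: bool = False):
    """Attention layer; neighbourhoods are S_ij > 0 plus self-loops."""
    n = S.shape[0]
    mask = (S > 0) | np.eye(n, dtype=bool)
    S_t = Tensor(S)
    head_sum = None
    attention = []
    for W, a_full, B in zip(params.W, params.a, params.B):
        F_out = W.data.shape[1]
        WH = H @ W
        # a^T [W h_i || W h_j || B S_ij] = (W h_i).a1 + (W h_j).a2 + a3 B S_ij
        a1 = Tensor._from_op(a_full.data[:F_out, None], (a_full,), None)
        if a1.requires_grad:
            def b1(g, a=a_full, F=F_out):
                ga = np.zeros_like(a.data); ga[:F] = g[:, 0]; a._accum(ga)
            a1._backward = b1
        a2 = Tensor._from_op(a_full.data[F_out:2 * F_out, None], (a_full,), None)
        if a2.requires_grad:
            def b2(g, a=a_full, F=F_out):
                ga = np.zeros_like(a.data); ga[F:2 * F] = g[:, 0]; a._accum(ga)
            a2._backward = b2
        a3 = Tensor._from_op(a_full.data[2 * F_out:2 * F_out + 1], (a_full,), None)
        if a3.requires_grad:
            def b3(g, a=a_full, F=F_out):
                ga = np.zeros_like(a.data); ga[2 * F] = g.reshape(-1)[0]; a._accum(ga)
            a3._backward = b3
        u = WH @ a1                                    # n x 1
        v = WH @ a2                                    # n x 1
        logits = u + v.T + (a3 * B) * S_t              # n x n, broadcast
        logits = logits.leaky_relu(params.negative_slope)
        phi = logits.masked_softmax(mask, axis=1)
        attention.append(phi.data)
        contrib = phi @ WH
        head_sum = contrib if head_sum is None else head_sum + contrib
    out = (head_sum * (1.0 / params.heads)).relu()
    if return_attention:
        return out, attention
    return out


def gat_forward(S: np.ndarray, H: np.ndarray, params: GATParams,
                return_attention: bool = False):
    """Multi-head attention layer on numpy inputs.

    Per head, phi_ij = softmax over j in N(i) of
    LeakyReLU(a_k^T [W_k H_i || W_k H_j || B_k S_ij]); node output is
    ReLU((1/K) sum_k sum_j phi_ij^k W_k H_j).
    """
    res = _gat(np.asarray(S, dtype=np.float64), Tensor(np.asarray(H, dtype=np.float64)),
               params, return_attention)
    if return_attention:
        return res[0].data, res[1]
    return res.data


def _combine_cnn(H1: Tensor, H3: Tensor, kernel: Tensor, bias: Tensor) -> Tensor:
    """Two-channel same-padded 1-D convolution over the feature axis -> F x N."""
    return stack2(H1, H3).conv1d_same(kernel, bias).T


def combine_cnn(H1: np.ndarray, H3: np.ndarray, kernel: np.ndarray,
                bias: float = 0.0) -> np.ndarray:
    """Combine first- and third-layer outputs into an embedding matrix X (F x N)."""
    H1 = np.asarray(H1, dtype=np.float64)
    H3 = np.asarray(H3, dtype=np.float64)
    if H1.shape != H3.shape:
        raise ValueError("H1 and H3 must have the same shape")
    return _combine_cnn(Tensor(H1), Tensor(H3), Tensor(kernel),
                        Tensor(np.asarray(float(bias)))).data


def preference_matrix(X_c: np.ndarray, X_d: np.ndarray) -> np.ndarray:
    """Preference matrix U = X_c^T X_d (n x m) from F x n and F x m embeddings."""
    X_c = np.asarray(X_c, dtype=np.float64)
    X_d = np.asarray(X_d, dtype=np.float64)
    if X_c.shape[0] != X_d.shape[0]:
        raise ValueError("embedding dimensions differ")
    return X_c.T @ X_d


class GraphEncoder(BaseEstimator):
    """Learns lncRNA and disease embeddings from their similarity graphs.

    Parameters mirror :class:`EncoderConfig`.  After :meth:`fit` the fitted
    attributes are ``X_c_`` (F x n), ``X_d_`` (F x m), ``U_`` (n x m),
    ``loss_history_`` and ``state_``.
    """

    def __init__(self, embedding_dim: int = 64, heads: int = 2, epochs: int = 200,
                 learning_rate: float = 1e-3, cnn_kernel_width: int = 3,
                 negative_slope: float = 0.2, seed: int = 0):
        self.embedding_dim = embedding_dim
        self.heads = heads
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.cnn_kernel_width = cnn_kernel_width
        self.negative_slope = negative_slope
        self.seed = seed

    # -- parameter construction ----------------------------------------------

    def _config(self) -> EncoderConfig:
        return EncoderConfig(self.embedding_dim, self.heads, self.epochs,
                             self.learning_rate, self.cnn_kernel_width,
                             self.negative_slope, self.seed)

    @staticmethod
    def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
        scale = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-scale, scale, size=(fan_in, fan_out))

    def _init_graph_params(self, rng: np.random.Generator, n_nodes: int) -> dict:
        F = self.embedding_dim
        params = {
            "Q1": Tensor(self._glorot(rng, n_nodes, F), requires_grad=True),
            "Q2": Tensor(self._glorot(rng, F, F), requires_grad=True),
            "gat": GATParams(
                W=[Tensor(self._glorot(rng, F, F), requires_grad=True)
                   for _ in range(self.heads)],
                a=[Tensor(rng.uniform(-0.1, 0.1, size=2 * F + 1), requires_grad=True)
                   for _ in range(self.heads)],
                B=[Tensor(np.asarray(1.0), requires_grad=True)
                   for _ in range(self.heads)],
                negative_slope=self.negative_slope,
            ),
            "cnn_k": Tensor(rng.uniform(-0.5, 0.5, size=(2, self.cnn_kernel_width)),
                            requires_grad=True),
            "cnn_b": Tensor(np.asarray(0.0), requires_grad=True),
        }
        return params

    @staticmethod
    def _collect(params: dict) -> list[Tensor]:
        out = [params["Q1"], params["Q2"], params["cnn_k"], params["cnn_b"]]
        out += params["gat"].W + params["gat"].a + params["gat"].B
        return out

    def _forward_graph(self, S: np.ndarray, params: dict) -> tuple[list[Tensor], Tensor]:
        P = Tensor(normalized_propagation(S))
        H0 = Tensor(S)  # initial node features: the similarity rows themselves
        H1 = _gcn(P, H0, params["Q1"])
        H2 = _gat(S, H1, params["gat"])
        H3 = _gcn(P, H2, params["Q2"])
        X = _combine_cnn(H1, H3, params["cnn_k"], params["cnn_b"])
        return [H0, H1, H2, H3], X

    def _forward(self, C: np.ndarray, D: np.ndarray,
                 pc: dict, pd_: dict):
        Hc, Xc = self._forward_graph(C, pc)
        Hd, Xd = self._forward_graph(D, pd_)
        U = Xc.T @ Xd
        return Hc, Hd, Xc, Xd, U

    @staticmethod
    def _as_matrix(S) -> np.ndarray:
        return S.M if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=np.float64)

    # -- public API -----------------------------------------------------------

    def encode(self, C, D) -> EncoderState:
        """Single untrained forward pass (freshly initialized parameters)."""
        C, D = self._as_matrix(C), self._as_matrix(D)
        cfg = self._config()
        rng = np.random.default_rng(self.seed)
        pc = self._init_graph_params(rng, C.shape[0])
        pd_ = self._init_graph_params(rng, D.shape[0])
        Hc, Hd, Xc, Xd, U = self._forward(C, D, pc, pd_)
        return EncoderState([h.data for h in Hc], [h.data for h in Hd],
                            Xc.data, Xd.data, U.data, [], cfg)

    def fit(self, C, D, Y: np.ndarray | AssociationNetwork) -> "GraphEncoder":
        """Train embeddings against the association matrix Y.

        Minimizes BCE(sigmoid(X_c^T X_d), Y) with Adam; raises if the loss
        becomes non-finite, reporting the epoch.
        """
        C, D = self._as_matrix(C), self._as_matrix(D)
        Ym = Y.Y if isinstance(Y, AssociationNetwork) else np.asarray(Y)
        if Ym.shape != (C.shape[0], D.shape[0]):
            raise ValueError("Y shape inconsistent with C and D")
        cfg = self._config()
        rng = np.random.default_rng(self.seed)
        pc = self._init_graph_params(rng, C.shape[0])
        pd_ = self._init_graph_params(rng, D.shape[0])
        opt = Adam(self._collect(pc) + self._collect(pd_), lr=self.learning_rate)
        history: list[float] = []
        for epoch in range(self.epochs):
            opt.zero_grad()
            _, _, _, _, U = self._forward(C, D, pc, pd_)
            loss = bce_with_logits(U, Ym)
            val = float(loss.data)
            if not np.isfinite(val):
                raise FloatingPointError(f"training diverged at epoch {epoch + 1}")
            history.append(val)
            loss.backward()
            opt.step()
        Hc, Hd, Xc, Xd, U = self._forward(C, D, pc, pd_)
        self.state_ = EncoderState([h.data for h in Hc], [h.data for h in Hd],
                                   Xc.data, Xd.data, U.data, history, cfg)
        self.X_c_ = self.state_.X_c
        self.X_d_ = self.state_.X_d
        self.U_ = self.state_.U
        self.loss_history_ = history
        return self

    def predict_scores(self) -> np.ndarray:
        """sigmoid(U) on the trained state — the preference-matrix view of Y."""
        return sigmoid_np(self.U_)
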
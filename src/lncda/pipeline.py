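"""End-to-end association predictor: similarities -> encoder -> ensemble.

:class:`AssociationPredictor` glues the stages together behind a single
scikit-learn-style estimator: build the fused similarity matrices from the
association network (and optional ontology), train the graph encoder against
Y, concatenate embedding columns into pair features, and fit the soft-voting
ensemble on known positives plus uniformly sampled unknown pairs as
negatives.  A single master seed fans out to per-stage seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import AssociationNetwork, DiseaseOntology, PredictionTable
from .encoder import GraphEncoder
from .ensemble import (DNNClassifier, GradientBoostingTrees,
                       SoftVotingClassifier, build_pair_features, soft_vote)
from .similarity import build_similarities

__all__ = ["AssociationPredictor", "sample_negatives"]


def sample_negatives(network: AssociationNetwork, ratio: float = 1.0,
                     seed: int = 0,
                     exclude: set[tuple[int, int]] | None = None) -> list[tuple[int, int]]:
    """Uniform sample (without replacement) of unknown pairs as negatives.

    Draws ``round(ratio * positives)`` pairs with y_ij = 0, optionally also
    excluding ``exclude`` (e.g. pairs already assigned to a test split).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    zeros = list(zip(*np.nonzero(network.Y == 0)))
    if exclude:
        zeros = [p for p in zeros if (int(p[0]), int(p[1])) not in exclude]
    count = int(round(ratio * network.n_associations))
    if count > len(zeros):
        raise ValueError(f"requested {count} negatives but only {len(zeros)} "
                         "unknown pairs are available")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(zeros), size=count, replace=False)
    return [(int(zeros[k][0]), int(zeros[k][1])) for k in chosen]


class AssociationPredictor(BaseEstimator):
    """Full pipeline estimator for lncRNA-disease association scoring.

    ``fit`` accepts an :class:`AssociationNetwork` (plus optional ontology);
    explicit training pairs/labels may be supplied for cross-validation,
    otherwise all positives and an equal number of sampled negatives are
    used.  ``score_pairs`` returns soft-vote probabilities for (i, j) index
    pairs and ``predict_table`` scores every pair in the matrix.
    """

    def __init__(self, gamma_prime: float = 1.0, decay: float = 0.5,
                 embedding_dim: int = 64, heads: int = 2,
                 encoder_epochs: int = 200, encoder_lr: float = 1e-3,
                 cnn_kernel_width: int = 3,
                 dnn_hidden: tuple[int, ...] = (128, 64), dnn_epochs: int = 200,
                 dnn_lr: float = 1e-3,
                 gbm_estimators: int = 100, gbm_max_leaves: int = 31,
                 gbm_lambda: float = 1.0, gbm_shrinkage: float = 0.1,
                 alpha: float = 0.4, beta: float = 0.6, threshold: float = 0.5,
                 negative_ratio: float = 1.0, seed: int = 0):
        self.gamma_prime = gamma_prime
        self.decay = decay
        self.embedding_dim = embedding_dim
        self.heads = heads
        self.encoder_epochs = encoder_epochs
        self.encoder_lr = encoder_lr
        self.cnn_kernel_width = cnn_kernel_width
        self.dnn_hidden = dnn_hidden
        self.dnn_epochs = dnn_epochs
        self.dnn_lr = dnn_lr
        self.gbm_estimators = gbm_estimators
        self.gbm_max_leaves = gbm_max_leaves
        self.gbm_lambda = gbm_lambda
        self.gbm_shrinkage = gbm_shrinkage
        self.alpha = alpha
        self.beta = beta
        self.threshold = threshold
        self.negative_ratio = negative_ratio
        self.seed = seed

    def _stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        enc, dnn, gbm, neg = (int(s) % (2 ** 31) for s in ss.generate_state(4))
        return {"encoder": enc, "dnn": dnn, "gbm": gbm, "negatives": neg}

    def fit(self, network: AssociationNetwork,
            ontology: DiseaseOntology | None = None,
            train_pairs: list[tuple[int, int]] | None = None,
            train_labels: np.ndarray | None = None) -> "AssociationPredictor":
        seeds = self._stage_seeds()
        self.network_ = network
        self.C_, self.D_ = build_similarities(network, ontology,
                                              self.gamma_prime, self.decay)
        self.encoder_ = GraphEncoder(
            embedding_dim=self.embedding_dim, heads=self.heads,
            epochs=self.encoder_epochs, learning_rate=self.encoder_lr,
            cnn_kernel_width=self.cnn_kernel_width, seed=seeds["encoder"])
        self.encoder_.fit(self.C_, self.D_, network)

        if train_pairs is None:
            positives = [(int(i), int(j)) for i, j in zip(*np.nonzero(network.Y))]
            negatives = sample_negatives(network, self.negative_ratio,
                                         seed=seeds["negatives"])
            train_pairs = positives + negatives
            train_labels = np.array([1] * len(positives) + [0] * len(negatives))
        elif train_labels is None:
            raise ValueError("train_labels required with explicit train_pairs")

        table = build_pair_features(self.encoder_.state_, train_pairs,
                                    np.asarray(train_labels))
        self.ensemble_ = SoftVotingClassifier(
            dnn=DNNClassifier(hidden_layer_sizes=self.dnn_hidden,
                              epochs=self.dnn_epochs, learning_rate=self.dnn_lr,
                              seed=seeds["dnn"]),
            gbm=GradientBoostingTrees(n_estimators=self.gbm_estimators,
                                      max_leaves=self.gbm_max_leaves,
                                      reg_lambda=self.gbm_lambda,
                                      learning_rate=self.gbm_shrinkage,
                                      seed=seeds["gbm"]),
            alpha=self.alpha, beta=self.beta, threshold=self.threshold)
        self.ensemble_.fit(table.X, table.y)
        return self

    # -- scoring --------------------------------------------------------------

    def _features(self, pairs: list[tuple[int, int]]):
        return build_pair_features(self.encoder_.state_, pairs)

    def score_pairs(self, pairs: list[tuple[int, int]],
                    model: str = "ensemble") -> np.ndarray:
        """Association probabilities for index pairs.

        ``model`` selects the full soft vote or a single member
        ('dnn' / 'gbm'), the single-model ablation view.
        """
        X = self._features(pairs).X
        cd, cg = self.ensemble_.member_scores(X)
        if model == "dnn":
            return cd
        if model == "gbm":
            return cg
        if model == "ensemble":
            score, _ = soft_vote(cd, cg, self.alpha, self.beta, self.threshold)
            return score
        raise ValueError(f"unknown model {model!r}")

    def predict_pairs(self, pairs: list[tuple[int, int]]) -> np.ndarray:
        scores = self.score_pairs(pairs)
        return (scores > self.threshold).astype(int)

    def predict_table(self, pairs: list[tuple[int, int]] | None = None,
                      model: str = "ensemble") -> PredictionTable:
        """Score pairs (default: every pair in the matrix) into a table."""
        net = self.network_
        if pairs is None:
            pairs = [(i, j) for i in range(net.n_lncrnas)
                     for j in range(net.n_diseases)]
        scores = self.score_pairs(pairs, model=model)
        frame = pd.DataFrame({
            "lncrna": [net.lncrna_ids[i] for i, _ in pairs],
            "disease": [net.disease_ids[j] for _, j in pairs],
            "score": scores,
            "predicted_label": (scores > self.threshold).astype(int),
            "known_label": [int(net.Y[i, j]) for i, j in pairs],
        })
        return PredictionTable(frame)

    def rank_disease(self, disease: str, top_k: int = 20) -> pd.DataFrame:
        """Top-k candidate lncRNAs for one disease, known positives excluded."""
        net = self.network_
        j = net.disease_index(disease)
        pairs = [(i, j) for i in range(net.n_lncrnas)]
        scores = self.score_pairs(pairs)
        df = pd.DataFrame({
            "disease": disease,
            "lncrna": net.lncrna_ids,
            "score": scores,
            "known": net.Y[:, j].astype(int),
        })
        df = df[df["known"] == 0]
        df = df.sort_values(["score", "lncrna"], ascending=[False, True],
                            kind="mergesort").head(top_k)
        df["rank"] = np.arange(1, len(df) + 1)
        return df[["disease", "rank", "lncrna", "score"]].reset_index(drop=True)
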
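"""Cross-validation protocols, negative sampling and metric computation.

Three schemes probe different prediction regimes:

* CV1 holds out a fraction of lncRNAs — every pair touching a held-out
  lncRNA is test-only, the cold-start "new lncRNA" setting;
* CV2 does the same over diseases ("new disease");
* CV3 holds out labeled pairs while all entities stay in the training graph.

Under CV1/CV2 the held-out entities' associations are zeroed out of Y before
any similarity or encoder computation, so no association signal from a test
entity can leak into training; ontology-derived semantic similarity is
association-independent and stays intact.  Metrics are the thresholded
confusion-matrix quartet plus tie-aware AUC and step-integrated AUPR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.base import clone

from .data import AssociationNetwork, DiseaseOntology
from .pipeline import AssociationPredictor, sample_negatives

logger = logging.getLogger(__name__)

__all__ = [
    "CVScheme",
    "Split",
    "EvaluationReport",
    "split",
    "compute_metrics",
    "run_experiment",
    "sample_negatives",
]

METRIC_NAMES = ["precision", "recall", "accuracy", "f1", "auc", "aupr"]


@dataclass
class CVScheme:
    """Cross-validation configuration (mode cv1 | cv2 | cv3)."""

    mode: str = "cv3"
    train_fraction: float = 0.8
    repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.mode not in {"cv1", "cv2", "cv3"}:
            raise ValueError("mode must be one of cv1, cv2, cv3")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class Split:
    """One repeat's train/test division of labeled pairs."""

    train_pairs: list[tuple[int, int]]
    train_labels: np.ndarray
    test_pairs: list[tuple[int, int]]
    test_labels: np.ndarray
    held_out_lncrnas: list[int] = field(default_factory=list)
    held_out_diseases: list[int] = field(default_factory=list)


def _one_split(scheme: CVScheme, network: AssociationNetwork,
               negatives: list[tuple[int, int]], rng: np.random.Generator) -> Split:
    positives = [(int(i), int(j)) for i, j in zip(*np.nonzero(network.Y))]
    labeled = [(p, 1) for p in positives] + [(p, 0) for p in negatives]
    for attempt in range(100):
        if scheme.mode == "cv3":
            order = rng.permutation(len(labeled))
            n_train = int(round(scheme.train_fraction * len(labeled)))
            tr = [labeled[k] for k in order[:n_train]]
            te = [labeled[k] for k in order[n_train:]]
            held_l, held_d = [], []
        else:
            if scheme.mode == "cv1":
                ids = rng.permutation(network.n_lncrnas)
                n_train = int(round(scheme.train_fraction * network.n_lncrnas))
                test_set = set(int(i) for i in ids[n_train:])
                tr = [(p, y) for p, y in labeled if p[0] not in test_set]
                te = [(p, y) for p, y in labeled if p[0] in test_set]
                held_l, held_d = sorted(test_set), []
            else:
                ids = rng.permutation(network.n_diseases)
                n_train = int(round(scheme.train_fraction * network.n_diseases))
                test_set = set(int(j) for j in ids[n_train:])
                tr = [(p, y) for p, y in labeled if p[1] not in test_set]
                te = [(p, y) for p, y in labeled if p[1] in test_set]
                held_l, held_d = [], sorted(test_set)
        tr_y = np.array([y for _, y in tr])
        te_y = np.array([y for _, y in te])
        if len(tr) and len(te) and tr_y.any() and te_y.any() \
                and not tr_y.all() and not te_y.all():
            if attempt:
                logger.info("split resampled %d time(s)", attempt)
            return Split([p for p, _ in tr], tr_y, [p for p, _ in te], te_y,
                         held_l, held_d)
    raise RuntimeError("could not find a split with positives and negatives "
                       "on both sides after 100 attempts")


def split(scheme: CVScheme, network: AssociationNetwork,
          negatives: list[tuple[int, int]]) -> list[Split]:
    """Per-repeat train/test splits of the labeled pair list."""
    rng = np.random.default_rng(scheme.seed)
    return [_one_split(scheme, network, negatives, rng)
            for _ in range(scheme.repeats)]


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> dict[str, float]:
    """Precision/recall/accuracy/F1 at the strict threshold, plus AUC/AUPR.

    AUC is the tie-aware rank statistic (trapezoidal ROC area); AUPR is the
    step-wise precision-recall integral (average precision).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    pred = (scores > threshold).astype(int)
    return {
        "precision": float(skm.precision_score(labels, pred, zero_division=0)),
        "recall": float(skm.recall_score(labels, pred, zero_division=0)),
        "accuracy": float(skm.accuracy_score(labels, pred)),
        "f1": float(skm.f1_score(labels, pred, zero_division=0)),
        "auc": float(skm.roc_auc_score(labels, scores)),
        "aupr": float(skm.average_precision_score(labels, scores)),
    }


@dataclass
class EvaluationReport:
    """Per-repeat metric rows and their mean/std aggregate."""

    scheme: CVScheme
    per_repeat: pd.DataFrame
    aggregate: pd.DataFrame

    @classmethod
    def from_rows(cls, scheme: CVScheme, rows: list[dict[str, float]]) -> "EvaluationReport":
        per_repeat = pd.DataFrame(rows)
        per_repeat.insert(0, "repeat", np.arange(1, len(rows) + 1))
        agg = per_repeat[METRIC_NAMES].agg(["mean", "std"]).T
        agg.index.name = "metric"
        return cls(scheme, per_repeat, agg.reset_index())

    def mean(self, metric: str) -> float:
        return float(self.per_repeat[metric].mean())

    def to_json_dict(self) -> dict:
        return {
            "scheme": vars(self.scheme),
            "per_repeat": self.per_repeat.to_dict(orient="records"),
            "aggregate": self.aggregate.to_dict(orient="records"),
        }


def run_experiment(network: AssociationNetwork,
                   predictor: AssociationPredictor | None = None,
                   scheme: CVScheme | None = None,
                   ontology: DiseaseOntology | None = None,
                   negative_ratio: float = 1.0,
                   model: str = "ensemble") -> EvaluationReport:
    """Run one cross-validation experiment end to end.

    Per repeat: sample negatives, split, zero the held-out associations out
    of Y, retrain the full pipeline on the masked network with the repeat's
    training pairs only, score the test pairs and compute metrics.  Fully
    deterministic given the scheme seed and predictor seed.
    """
    predictor = predictor if predictor is not None else AssociationPredictor()
    scheme = scheme if scheme is not None else CVScheme()
    rng = np.random.default_rng(scheme.seed)
    rows = []
    for rep in range(scheme.repeats):
        neg_seed = int(rng.integers(2 ** 31))
        negatives = sample_negatives(network, negative_ratio, seed=neg_seed)
        sp = _one_split(scheme, network, negatives, rng)
        # hide held-out association signal from every training-side quantity
        test_positive_pairs = [p for p, y in zip(sp.test_pairs, sp.test_labels) if y]
        masked = network.masked(lncrna_rows=sp.held_out_lncrnas,
                                disease_cols=sp.held_out_diseases,
                                pairs=test_positive_pairs)
        rep_predictor = clone(predictor)
        rep_predictor.set_params(seed=int(rng.integers(2 ** 31)))
        rep_predictor.fit(masked, ontology=ontology,
                          train_pairs=sp.train_pairs, train_labels=sp.train_labels)
        scores = rep_predictor.score_pairs(sp.test_pairs, model=model)
        rows.append(compute_metrics(scores, sp.test_labels, predictor.threshold))
    return EvaluationReport.from_rows(scheme, rows)
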
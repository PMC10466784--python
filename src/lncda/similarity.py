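"""Similarity matrices for lncRNAs and diseases.

Four constructions, the standard triple in the lncRNA-disease association
literature plus a fusion rule:

* Gaussian interaction-profile (GIP) kernel on rows/columns of the binary
  association matrix, with the bandwidth normalized by the mean squared
  profile norm so the kernel is scale-free in network density;
* DAG-based disease semantic similarity with depth-decayed ancestor
  contributions (Wang-style, decay 0.5 by default);
* lncRNA functional similarity by best-match averaging over the diseases
  each lncRNA is associated with;
* fusion by arithmetic mean where both inputs are defined, falling back to
  the kernel elsewhere (ontology-absent diseases, association-free lncRNAs).

Every emitted matrix is square, symmetric, unit-diagonal and in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import AssociationNetwork, DiseaseOntology

__all__ = [
    "SimilarityMatrix",
    "gaussian_kernel",
    "disease_semantic_similarity",
    "lncrna_functional_similarity",
    "fuse",
    "build_similarities",
]


@dataclass
class SimilarityMatrix:
    """A square similarity matrix with an id registry and a defined-mask.

    ``defined[i, j]`` is False where the construction had no information for
    the pair (e.g. a disease absent from the ontology); values there are
    placeholders that fusion will ignore.
    """

    entity_ids: list[str]
    M: np.ndarray
    defined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.entity_ids = list(self.entity_ids)
        self.M = np.asarray(self.M, dtype=np.float64)
        k = len(self.entity_ids)
        if self.M.shape != (k, k):
            raise ValueError(f"matrix shape {self.M.shape} != ({k}, {k})")
        if self.defined is None:
            self.defined = np.ones((k, k), dtype=bool)
        else:
            self.defined = np.asarray(self.defined, dtype=bool)
        d = self.defined
        if not np.allclose(self.M, self.M.T, atol=1e-9):
            raise ValueError("similarity matrix is not symmetric")
        if (self.M[d] < -1e-12).any() or (self.M[d] > 1 + 1e-12).any():
            raise ValueError("similarity values outside [0, 1]")
        if not np.allclose(np.diag(self.M), 1.0, atol=1e-9):
            raise ValueError("diagonal must equal 1")
        np.clip(self.M, 0.0, 1.0, out=self.M)

    def __len__(self) -> int:
        return len(self.entity_ids)


def gaussian_kernel(profiles: np.ndarray, entity_ids: Sequence[str] | None = None,
                    gamma_prime: float = 1.0) -> SimilarityMatrix:
    """GIP kernel similarity from binary interaction profiles (one row each).

    K(i, j) = exp(-gamma * ||row_i - row_j||^2) with
    gamma = gamma_prime / mean_i ||row_i||^2.
    """
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    P = np.asarray(profiles, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need a 2-D profile matrix with at least 2 rows")
    norms = (P ** 2).sum(axis=1)
    mean_norm = norms.mean()
    if mean_norm == 0:
        raise ValueError("all-zero profile matrix: kernel bandwidth undefined")
    gamma = gamma_prime / mean_norm
    sq = norms[:, None] + norms[None, :] - 2.0 * (P @ P.T)
    np.maximum(sq, 0.0, out=sq)
    K = np.exp(-gamma * sq)
    np.fill_diagonal(K, 1.0)
    K = (K + K.T) / 2.0
    ids = list(entity_ids) if entity_ids is not None else [str(i) for i in range(P.shape[0])]
    return SimilarityMatrix(ids, K)


def _ancestor_contributions(ontology: DiseaseOntology, term: str,
                            decay: float) -> dict[str, float]:
    """Depth-decayed contribution of each ancestor (and the term itself).

    The term contributes 1 to itself; an ancestor t contributes the maximum
    over downward paths of decay^len(path), i.e. S(parent) = decay * S(child)
    relaxed to the max over children.
    """
    scores = {term: 1.0}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for p in ontology.parents(t):
            cand = decay * scores[t]
            if cand > scores.get(p, 0.0):
                scores[p] = cand
                frontier.append(p)
    return scores


def disease_semantic_similarity(ontology: DiseaseOntology, diseases: Sequence[str],
                                decay: float = 0.5) -> SimilarityMatrix:
    """Semantic similarity from shared ontology ancestors.

    sim(a, b) = sum over shared terms of (S_a(t) + S_b(t)) divided by the sum
    of all contributions of a plus all of b.  Diseases absent from the
    ontology are defined only on the diagonal.
    """
    if not (0.0 < decay < 1.0):
        raise ValueError("decay must lie in (0, 1)")
    diseases = list(diseases)
    m = len(diseases)
    contribs: list[dict[str, float] | None] = [
        _ancestor_contributions(ontology, d, decay) if d in ontology else None
        for d in diseases
    ]
    totals = [sum(c.values()) if c is not None else 0.0 for c in contribs]
    M = np.eye(m)
    defined = np.eye(m, dtype=bool)
    for i in range(m):
        if contribs[i] is None:
            continue
        for j in range(i + 1, m):
            if contribs[j] is None:
                continue
            ci, cj = contribs[i], contribs[j]
            shared = ci.keys() & cj.keys()
            num = sum(ci[t] + cj[t] for t in shared)
            M[i, j] = M[j, i] = num / (totals[i] + totals[j])
            defined[i, j] = defined[j, i] = True
    return SimilarityMatrix(diseases, M, defined)


def lncrna_functional_similarity(network: AssociationNetwork,
                                 disease_sim: SimilarityMatrix) -> SimilarityMatrix:
    """Best-match-average functional similarity over associated disease sets.

    For lncRNAs with disease index sets A and B,
    FS = (sum_{a in A} max_{b in B} sim(a,b) + sum_{b in B} max_{a in A} sim(a,b))
         / (|A| + |B|).
    lncRNAs with no associations are undefined off-diagonal (value 0).
    """
    if list(disease_sim.entity_ids) != list(network.disease_ids):
        raise ValueError("disease similarity is not indexed by the network's diseases")
    n = network.n_lncrnas
    sets = [np.nonzero(network.Y[i])[0] for i in range(n)]
    S = disease_sim.M
    M = np.eye(n)
    defined = np.eye(n, dtype=bool)
    for i in range(n):
        if len(sets[i]) == 0:
            continue
        for j in range(i + 1, n):
            if len(sets[j]) == 0:
                continue
            block = S[np.ix_(sets[i], sets[j])]
            fs = (block.max(axis=1).sum() + block.max(axis=0).sum()) / \
                 (len(sets[i]) + len(sets[j]))
            M[i, j] = M[j, i] = min(fs, 1.0)
            defined[i, j] = defined[j, i] = True
    return SimilarityMatrix(network.lncrna_ids, M, defined)


def fuse(similarity_a: SimilarityMatrix, similarity_b: SimilarityMatrix,
         mask: np.ndarray | None = None) -> SimilarityMatrix:
    """Average two similarity matrices where the second is defined.

    fused(i, j) = (a + b) / 2 where b is defined, else a.  Entity orderings
    must match; the default mask is ``similarity_b.defined``.
    """
    if list(similarity_a.entity_ids) != list(similarity_b.entity_ids):
        raise ValueError("entity orderings differ")
    if similarity_a.M.shape != similarity_b.M.shape:
        raise ValueError("shape mismatch")
    use = similarity_b.defined if mask is None else np.asarray(mask, dtype=bool)
    F = np.where(use, (similarity_a.M + similarity_b.M) / 2.0, similarity_a.M)
    np.fill_diagonal(F, 1.0)
    F = (F + F.T) / 2.0
    return SimilarityMatrix(similarity_a.entity_ids, F)


def build_similarities(network: AssociationNetwork,
                       ontology: DiseaseOntology | None = None,
                       gamma_prime: float = 1.0,
                       decay: float = 0.5) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Construct the fused lncRNA matrix C and disease matrix D for a network.

    Disease side: GIP kernel on columns of Y, fused with ontology semantic
    similarity when an ontology is supplied.  lncRNA side: GIP kernel on rows
    of Y fused with functional similarity computed against the disease-side
    matrix (semantic where available, kernel otherwise).
    """
    gip_d = gaussian_kernel(network.Y.T, network.disease_ids, gamma_prime)
    if ontology is not None:
        sem = disease_semantic_similarity(ontology, network.disease_ids, decay)
        D = fuse(gip_d, sem)
        func_basis = sem
    else:
        D = gip_d
        func_basis = gip_d
    gip_l = gaussian_kernel(network.Y, network.lncrna_ids, gamma_prime)
    func = lncrna_functional_similarity(network, func_basis)
    C = fuse(gip_l, func)
    return C, D
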
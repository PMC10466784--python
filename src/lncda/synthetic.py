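"""Seeded synthetic fixtures: planted low-rank networks and toy ontologies.

The generator emulates the qualitative structure of curated lncRNA-disease
association lists — a sparse binary bipartite matrix whose positives cluster
by latent biology — by thresholding the product of nonnegative low-rank
factors at the quantile matching a target density, then flipping entries
independently with a noise probability.  Nonnegative factors make the
planted structure visible to the interaction-profile kernels, which is what
lets the full pipeline demonstrably recover it.  Ontologies are random
rooted DAGs layered by depth, acyclic by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AssociationNetwork, DiseaseOntology

__all__ = ["PlantedNetwork", "generate_network", "generate_ontology"]


@dataclass
class PlantedNetwork:
    """An association network with its generating latent factors."""

    network: AssociationNetwork
    latent_l: np.ndarray   # n x r
    latent_d: np.ndarray   # m x r
    density: float
    noise: float
    seed: int


def generate_network(n: int = 40, m: int = 60, rank: int = 3,
                     density: float = 0.1, noise: float = 0.0,
                     seed: int = 0) -> PlantedNetwork:
    """Plant a rank-``rank`` bipartite network of size n x m.

    Scores L @ R^T (entries of L, R are absolute Gaussians) are thresholded
    at the (1 - density) quantile, so at noise 0 the positive count equals
    round(density * n * m) up to quantile ties; each entry is then flipped
    independently with probability ``noise``.
    """
    if not (1 <= rank <= min(n, m)):
        raise ValueError("rank must satisfy 1 <= r <= min(n, m)")
    if not (0.0 < density < 1.0):
        raise ValueError("density must lie in (0, 1)")
    if not (0.0 <= noise < 0.5):
        raise ValueError("noise must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    L = np.abs(rng.standard_normal((n, rank)))
    R = np.abs(rng.standard_normal((m, rank)))
    scores = L @ R.T
    k = int(round(density * n * m))
    # threshold at the k-th largest score; continuous scores make ties
    # measure-zero so the positive count is exact in practice
    cutoff = np.partition(scores.ravel(), -k)[-k]
    Y = (scores >= cutoff).astype(np.int8)
    if noise > 0:
        flips = rng.random((n, m)) < noise
        Y = np.where(flips, 1 - Y, Y).astype(np.int8)
    lncrna_ids = [f"l{i:03d}" for i in range(n)]
    disease_ids = [f"d{j:03d}" for j in range(m)]
    network = AssociationNetwork(lncrna_ids, disease_ids, Y)
    return PlantedNetwork(network, L, R, density, noise, seed)


def generate_ontology(n_terms: int = 30, branching: int = 3, depth: int = 4,
                      seed: int = 0, term_ids: list[str] | None = None) -> DiseaseOntology:
    """Random rooted DAG over ``n_terms`` terms, edges child -> earlier level.

    Terms are assigned to levels 0..depth (level 0 is the single root); each
    non-root term gets 1..branching parents drawn from strictly shallower
    levels, so the result is acyclic by construction.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    terms = list(term_ids) if term_ids is not None else \
        [f"t{i:03d}" for i in range(n_terms)]
    if len(terms) != n_terms:
        raise ValueError("term_ids length mismatch")
    levels = np.zeros(n_terms, dtype=int)
    if n_terms > 1:
        levels[1:] = rng.integers(1, max(depth, 1) + 1, size=n_terms - 1)
    edges: list[tuple[str, str]] = []
    for i in range(1, n_terms):
        shallower = np.nonzero(levels < levels[i])[0]
        k = int(rng.integers(1, branching + 1))
        parents = rng.choice(shallower, size=min(k, len(shallower)), replace=False)
        for p in sorted(parents):
            edges.append((terms[i], terms[int(p)]))
    return DiseaseOntology(terms, edges)
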
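"""Core domain types and file I/O for lncRNA-disease association data.

The central object is the binary association matrix ``Y`` (lncRNAs on rows,
diseases on columns) together with its two identifier registries.  Edge
lists, ontologies and prediction tables are plain TSV/CSV; pandas handles
parsing and networkx validates the ontology DAG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationNetwork",
    "DiseaseOntology",
    "PredictionTable",
    "read_edge_list",
    "read_ontology",
    "write_predictions",
    "write_network",
]


@dataclass
class AssociationNetwork:
    """Binary bipartite network of lncRNA-disease associations.

    ``Y[i, j] == 1`` iff lncRNA ``lncrna_ids[i]`` is associated with disease
    ``disease_ids[j]``.  Rows are always lncRNAs and columns diseases.
    """

    lncrna_ids: list[str]
    disease_ids: list[str]
    Y: np.ndarray

    def __post_init__(self):
        self.lncrna_ids = list(self.lncrna_ids)
        self.disease_ids = list(self.disease_ids)
        self.Y = np.asarray(self.Y, dtype=np.int8)
        if len(set(self.lncrna_ids)) != len(self.lncrna_ids):
            raise ValueError("duplicate lncRNA ids")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease ids")
        n, m = len(self.lncrna_ids), len(self.disease_ids)
        if self.Y.shape != (n, m):
            raise ValueError(f"Y shape {self.Y.shape} != ({n}, {m})")
        if n < 2 or m < 2:
            raise ValueError("need at least 2 lncRNAs and 2 diseases")
        if not np.isin(self.Y, (0, 1)).all():
            raise ValueError("Y entries must be 0 or 1")
        if self.Y.sum() == 0:
            raise ValueError("network has no positive associations")

    @property
    def n_lncrnas(self) -> int:
        return len(self.lncrna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_associations(self) -> int:
        return int(self.Y.sum())

    def lncrna_index(self, lncrna: str) -> int:
        return self.lncrna_ids.index(lncrna)

    def disease_index(self, disease: str) -> int:
        return self.disease_ids.index(disease)

    def masked(self, lncrna_rows: Sequence[int] = (),
               disease_cols: Sequence[int] = (),
               pairs: Sequence[tuple[int, int]] = ()) -> "AssociationNetwork":
        """Copy with the given rows/columns/pairs of Y zeroed.

        Used by cross-validation to hide held-out entities or pairs from
        every association-derived quantity (kernels, encoder training).
        """
        Y = self.Y.copy()
        if len(lncrna_rows):
            Y[np.asarray(lncrna_rows, dtype=int), :] = 0
        if len(disease_cols):
            Y[:, np.asarray(disease_cols, dtype=int)] = 0
        for i, j in pairs:
            Y[i, j] = 0
        return AssociationNetwork(self.lncrna_ids, self.disease_ids, Y)


@dataclass
class DiseaseOntology:
    """A DAG of disease terms, edges pointing child -> parent."""

    terms: list[str]
    parent_edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.terms = list(self.terms)
        term_set = set(self.terms)
        if len(term_set) != len(self.terms):
            raise ValueError("duplicate ontology terms")
        for child, parent in self.parent_edges:
            if child == parent:
                raise ValueError(f"self-loop on term {child!r}")
            if child not in term_set or parent not in term_set:
                raise ValueError(f"edge ({child!r}, {parent!r}) uses unregistered term")
        g = nx.DiGraph(self.parent_edges)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise ValueError(f"ontology contains a cycle: {path}")
        self._parents: dict[str, list[str]] = {t: [] for t in self.terms}
        for child, parent in self.parent_edges:
            self._parents[child].append(parent)

    def parents(self, term: str) -> list[str]:
        return self._parents[term]

    def __contains__(self, term: str) -> bool:
        return term in self._parents

    @property
    def roots(self) -> list[str]:
        return [t for t in self.terms if not self._parents[t]]


@dataclass
class PredictionTable:
    """Scored lncRNA-disease pairs with thresholded labels."""

    frame: pd.DataFrame  # columns: lncrna, disease, score, predicted_label[, known_label]

    def __post_init__(self):
        required = {"lncrna", "disease", "score", "predicted_label"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"prediction table missing columns {sorted(missing)}")
        s = self.frame["score"].to_numpy(dtype=float)
        if ((s < 0) | (s > 1)).any():
            raise ValueError("scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.frame)


def _read_two_column_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV with >=2 columns, auto-detecting separator and header."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else None
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, engine="python",
                     comment="#", skip_blank_lines=True)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: rows must have at least 2 fields")
    if df.iloc[:, :2].isna().any().any():
        raise ValueError(f"{path}: a row has fewer than 2 fields")
    # header heuristic: drop a first row that repeats common column labels
    first = [str(v).strip().lower() for v in df.iloc[0, :2]]
    if first[0] in {"lncrna", "lncrna_id", "child", "term"} or \
       first[1] in {"disease", "disease_id", "parent"}:
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"{path} contains a header but no data rows")
    return df


def read_edge_list(path: str | Path,
                   known_lncrnas: Sequence[str] | None = None,
                   known_diseases: Sequence[str] | None = None) -> AssociationNetwork:
    """Load an association edge list (lncRNA id, disease id per row).

    Duplicate edges collapse to a single association (logged).  Identifier
    order follows first appearance in the file unless registries are given,
    in which case every id in the file must be registered.
    """
    df = _read_two_column_table(path)
    lnc = df.iloc[:, 0].str.strip()
    dis = df.iloc[:, 1].str.strip()

    if known_lncrnas is not None:
        lncrna_ids = list(known_lncrnas)
        unknown = set(lnc) - set(lncrna_ids)
        if unknown:
            raise ValueError(f"lncRNA ids not in registry: {sorted(unknown)[:5]}")
    else:
        lncrna_ids = list(dict.fromkeys(lnc))
    if known_diseases is not None:
        disease_ids = list(known_diseases)
        unknown = set(dis) - set(disease_ids)
        if unknown:
            raise ValueError(f"disease ids not in registry: {sorted(unknown)[:5]}")
    else:
        disease_ids = list(dict.fromkeys(dis))

    li = {s: i for i, s in enumerate(lncrna_ids)}
    dj = {s: j for j, s in enumerate(disease_ids)}
    Y = np.zeros((len(lncrna_ids), len(disease_ids)), dtype=np.int8)
    dup = 0
    for a, b in zip(lnc, dis):
        i, j = li[a], dj[b]
        dup += int(Y[i, j])
        Y[i, j] = 1
    if dup:
        logger.info("collapsed %d duplicate edges in %s", dup, path)
    return AssociationNetwork(lncrna_ids, disease_ids, Y)


def read_ontology(path: str | Path) -> DiseaseOntology:
    """Load a disease ontology from a TSV of (child, parent) rows."""
    df = _read_two_column_table(path)
    edges = [(c.strip(), p.strip()) for c, p in zip(df.iloc[:, 0], df.iloc[:, 1])]
    terms = list(dict.fromkeys([t for e in edges for t in e]))
    return DiseaseOntology(terms, edges)


def write_network(network: AssociationNetwork, path: str | Path) -> None:
    """Write the association matrix as an edge list TSV (one pair per row)."""
    rows = [(network.lncrna_ids[i], network.disease_ids[j])
            for i, j in zip(*np.nonzero(network.Y))]
    pd.DataFrame(rows, columns=["lncrna", "disease"]).to_csv(
        path, sep="\t", index=False, header=False)


def write_predictions(table: PredictionTable, path: str | Path,
                      top_k: int | None = None) -> pd.DataFrame:
    """Write predictions as TSV [disease, rank, lncrna, score], score-sorted.

    Within each disease rows are ordered by descending score, ties broken by
    lncRNA id lexicographically; ranks are 1-based.  With ``top_k`` set, known
    positives are dropped first and only the k best novel pairs per disease
    are kept — the ranked-candidate layout used for biomarker screening.
    """
    if len(table) == 0:
        raise ValueError("prediction table is empty")
    df = table.frame.copy()
    if top_k is not None and "known_label" in df.columns:
        df = df[df["known_label"].fillna(0) != 1]
    df = df.sort_values(["disease", "score", "lncrna"],
                        ascending=[True, False, True], kind="mergesort")
    df["rank"] = df.groupby("disease").cumcount() + 1
    if top_k is not None:
        df = df[df["rank"] <= top_k]
    out = df[["disease", "rank", "lncrna", "score"]]
    out.to_csv(path, sep="\t", index=False)
    return out.reset_index(drop=True)
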
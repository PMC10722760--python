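"""Data model and I/O for bipartite microbe-disease association networks.

A binary association matrix ``Y`` (rows = microbes, columns = diseases) encodes
which microbe-disease pairs have a reported association.  Disease terms may
additionally be organised in a rooted ontology DAG (child -> parent edges),
which downstream semantic-similarity computations consume.

The single matrix orientation used everywhere in this package is
rows = microbes, columns = diseases.  Microbe profiles are rows of ``Y``
(length ``n_diseases``); disease profiles are columns (length ``n_microbes``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AssociationNetwork",
    "DiseaseOntologyGraph",
    "DegreeSummary",
    "read_association_edgelist",
    "write_association_edgelist",
    "read_ontology_edges",
    "write_ontology_edges",
    "profiles",
    "degree_summary",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


class ParseError(ValueError):
    """Raised when an input file violates the TSV edge-list contract."""


@dataclass(frozen=True)
class AssociationNetwork:
    """Binary bipartite association network over named microbes and diseases.

    Attributes
    ----------
    microbe_ids : tuple of str
        Unique microbe identifiers, in first-appearance order.
    disease_ids : tuple of str
        Unique disease identifiers, in first-appearance order.
    Y : ndarray of shape (n_microbes, n_diseases)
        Binary adjacency; ``Y[i, j] == 1`` iff microbe *i* is associated with
        disease *j*.
    """

    microbe_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    Y: np.ndarray

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y)
        if Y.ndim != 2:
            raise ValueError("Y must be a 2-D matrix")
        if len(self.microbe_ids) == 0 or len(self.disease_ids) == 0:
            raise ValueError("need at least one microbe and one disease")
        if Y.shape != (len(self.microbe_ids), len(self.disease_ids)):
            raise ValueError(
                f"Y shape {Y.shape} does not match id lists "
                f"({len(self.microbe_ids)} microbes, {len(self.disease_ids)} diseases)"
            )
        if len(set(self.microbe_ids)) != len(self.microbe_ids):
            raise ValueError("duplicate microbe identifiers")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")
        if not np.isin(Y, (0, 1)).all():
            raise ValueError("Y entries must be 0 or 1")
        object.__setattr__(self, "Y", Y.astype(np.int8, copy=False))

    @property
    def n_microbes(self) -> int:
        return len(self.microbe_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_edges(self) -> int:
        return int(self.Y.sum())

    def microbe_index(self, microbe_id: str) -> int:
        try:
            return self.microbe_ids.index(microbe_id)
        except ValueError:
            raise KeyError(f"unknown microbe {microbe_id!r}") from None

    def disease_index(self, disease_id: str) -> int:
        try:
            return self.disease_ids.index(disease_id)
        except ValueError:
            raise KeyError(f"unknown disease {disease_id!r}") from None

    def edges(self) -> list[tuple[int, int]]:
        """Positive pairs as (microbe index, disease index), row-major."""
        return [tuple(p) for p in np.argwhere(self.Y == 1)]

    def with_masked_pairs(self, pairs: Iterable[tuple[int, int]]) -> "AssociationNetwork":
        """Copy of the network with the given (i, j) entries forced to 0."""
        Y = self.Y.copy()
        for i, j in pairs:
            Y[i, j] = 0
        return AssociationNetwork(self.microbe_ids, self.disease_ids, Y)

    def with_masked_disease(self, disease_id: str) -> "AssociationNetwork":
        """Copy of the network with one disease's whole column zeroed."""
        j = self.disease_index(disease_id)
        Y = self.Y.copy()
        Y[:, j] = 0
        return AssociationNetwork(self.microbe_ids, self.disease_ids, Y)


@dataclass(frozen=True)
class DiseaseOntologyGraph:
    """Rooted DAG of disease terms; edges point child -> parent.

    ``terms`` may include internal ontology terms that are not diseases of the
    association network.  The ancestor closure ``T(d)`` used by semantic
    similarity includes ``d`` itself.
    """

    terms: frozenset[str]
    child_to_parents: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for child, parents in self.child_to_parents.items():
            if child not in self.terms:
                raise ValueError(f"child {child!r} not in terms")
            missing = parents - self.terms
            if missing:
                raise ValueError(f"parents {sorted(missing)} of {child!r} not in terms")
        g = self._digraph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology is not a DAG; cycle: {cycle}")

    def _digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parents in self.child_to_parents.items():
            g.add_edges_from((child, p) for p in parents)
        return g

    def parents(self, term: str) -> frozenset[str]:
        return self.child_to_parents.get(term, frozenset())

    def children(self, term: str) -> frozenset[str]:
        return frozenset(
            c for c, ps in self.child_to_parents.items() if term in ps
        )

    def ancestors_and_self(self, term: str) -> frozenset[str]:
        """The set T(d): all terms reachable via parent edges, plus d itself."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        seen: set[str] = {term}
        stack = [term]
        while stack:
            t = stack.pop()
            for p in self.parents(t):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return frozenset(seen)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "DiseaseOntologyGraph":
        terms: set[str] = set()
        c2p: dict[str, set[str]] = {}
        for child, parent in edges:
            terms.add(child)
            terms.add(parent)
            c2p.setdefault(child, set()).add(parent)
        return cls(frozenset(terms), {c: frozenset(p) for c, p in c2p.items()})


@dataclass(frozen=True)
class DegreeSummary:
    """Degree statistics of an association network (Y row/column sums)."""

    n_microbes: int
    n_diseases: int
    n_edges: int
    min_microbe_degree: int
    max_microbe_degree: int
    mean_microbe_degree: float
    min_disease_degree: int
    max_disease_degree: int
    mean_disease_degree: float

    @property
    def mean_microbe_degree_1dp(self) -> float:
        return round(self.mean_microbe_degree, 1)

    @property
    def mean_disease_degree_1dp(self) -> float:
        return round(self.mean_disease_degree, 1)


def _iter_tsv_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_association_edgelist(path: str | Path) -> AssociationNetwork:
    """Read a 2+-column TSV of (microbe_id, disease_id) association edges.

    Blank lines and ``#`` comments are skipped; duplicate edges collapse to
    one; node order is first appearance in the file.

    Raises
    ------
    ParseError
        If a line has fewer than 2 fields (with its line number), or the file
        contains no associations.
    """
    microbes: dict[str, int] = {}
    diseases: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    for lineno, fields in _iter_tsv_rows(path):
        if len(fields) < 2:
            raise ParseError(
                f"{path}: line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        m, d = fields[0].strip(), fields[1].strip()
        if not m or not d:
            raise ParseError(f"{path}: line {lineno}: empty identifier")
        mi = microbes.setdefault(m, len(microbes))
        di = diseases.setdefault(d, len(diseases))
        edges.add((mi, di))
    if not edges:
        raise ParseError(f"{path}: no associations")
    Y = np.zeros((len(microbes), len(diseases)), dtype=np.int8)
    for mi, di in edges:
        Y[mi, di] = 1
    return AssociationNetwork(tuple(microbes), tuple(diseases), Y)


def write_association_edgelist(net: AssociationNetwork, path: str | Path) -> None:
    """Write the network as a (microbe_id, disease_id) TSV, row-major order."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# microbe_id\tdisease_id\n")
        for i, j in np.argwhere(net.Y == 1):
            fh.write(f"{net.microbe_ids[i]}\t{net.disease_ids[j]}\n")


def read_ontology_edges(path: str | Path) -> DiseaseOntologyGraph:
    """Read a (child_term, parent_term) TSV into an ontology DAG.

    An empty file yields an empty graph (semantic similarity then falls back
    to its missing-term convention).  A directed cycle raises ``ValueError``
    naming one cycle.
    """
    edges: list[tuple[str, str]] = []
    for lineno, fields in _iter_tsv_rows(path):
        if len(fields) < 2:
            raise ParseError(
                f"{path}: line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        edges.append((fields[0].strip(), fields[1].strip()))
    return DiseaseOntologyGraph.from_edges(edges)


def write_ontology_edges(dag: DiseaseOntologyGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# child_term\tparent_term\n")
        for child in sorted(dag.child_to_parents):
            for parent in sorted(dag.child_to_parents[child]):
                fh.write(f"{child}\t{parent}\n")


def profiles(net: AssociationNetwork, axis: Literal["microbe", "disease"]) -> np.ndarray:
    """Binary association profiles, one per row.

    Microbe profiles are rows of ``Y`` (length ``n_diseases``); disease
    profiles are columns of ``Y`` (length ``n_microbes``).
    """
    if axis == "microbe":
        return net.Y.astype(float)
    if axis == "disease":
        return net.Y.T.astype(float)
    raise ValueError(f"axis must be 'microbe' or 'disease', got {axis!r}")


def degree_summary(net: AssociationNetwork) -> DegreeSummary:
    """Min/max/mean node degrees and edge total from Y row/column sums."""
    mdeg = net.Y.sum(axis=1)
    ddeg = net.Y.sum(axis=0)
    edges = int(net.Y.sum())
    return DegreeSummary(
        n_microbes=net.n_microbes,
        n_diseases=net.n_diseases,
        n_edges=edges,
        min_microbe_degree=int(mdeg.min()),
        max_microbe_degree=int(mdeg.max()),
        mean_microbe_degree=edges / net.n_microbes,
        min_disease_degree=int(ddeg.min()),
        max_disease_degree=int(ddeg.max()),
        mean_disease_degree=edges / net.n_diseases,
    )


def write_matrix_tsv(
    M: np.ndarray, row_ids: Iterable[str], col_ids: Iterable[str], path: str | Path
) -> None:
    """Export a matrix as headered TSV (row index + named columns)."""
    pd.DataFrame(np.asarray(M), index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t"
    )


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
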
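"""Core labelled-matrix and hierarchy data types.

All matrices are dense NumPy arrays indexed 0-based; string identifiers are
carried alongside and are the only names that ever appear on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np

from .errors import DataError

SYMMETRY_TOL = 1e-9

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "DiseaseDAG",
    "KernelBandwidth",
    "SYMMETRY_TOL",
]


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise DataError(f"duplicate {what} identifiers")
    if len(ids) == 0:
        raise DataError(f"empty {what} identifier list")


@dataclass
class AssociationMatrix:
    """Binary bipartite association matrix with row/column labels.

    ``values[i, j] == 1`` records a known association between row entity
    ``mirna_ids[i]`` and column entity ``disease_ids[j]``; 0 means unknown.
    """

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("association matrix must be 2-dimensional")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise DataError("association matrix entries must be exactly 0 or 1")
        _check_unique(self.mirna_ids, "miRNA")
        _check_unique(self.disease_ids, "disease")
        if self.values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise DataError(
                f"association shape {self.values.shape} does not match "
                f"({len(self.mirna_ids)}, {len(self.disease_ids)}) identifiers"
            )

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.mirna_ids), list(self.disease_ids)
        )


@dataclass
class SimilarityMatrix:
    """Symmetric, unit-diagonal similarity matrix in [0, 1] with labels.

    ``curated_mask`` flags entries taken from a curated source (functional or
    semantic similarity); ``False`` marks the Gaussian interaction-profile
    fallback branch.
    """

    values: np.ndarray
    ids: list[str]
    curated_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.ids, "similarity")
        k = len(self.ids)
        if self.values.shape != (k, k):
            raise DataError("similarity matrix must be square and match its labels")
        if np.abs(self.values - self.values.T).max(initial=0.0) > SYMMETRY_TOL:
            raise DataError("similarity matrix is not symmetric")
        if self.values.min(initial=1.0) < 0.0 or self.values.max(initial=0.0) > 1.0:
            raise DataError("similarity entries must lie in [0, 1]")
        if not np.allclose(np.diag(self.values), 1.0, atol=SYMMETRY_TOL):
            raise DataError("similarity diagonal must equal 1")
        if self.curated_mask is None:
            self.curated_mask = np.zeros((k, k), dtype=bool)
        else:
            self.curated_mask = np.asarray(self.curated_mask, dtype=bool)
            if self.curated_mask.shape != (k, k):
                raise DataError("curated_mask shape mismatch")

    @property
    def size(self) -> int:
        return len(self.ids)


@dataclass
class KernelBandwidth:
    """Strictly positive Gaussian kernel bandwidth."""

    value: float

    def __post_init__(self) -> None:
        if not (self.value > 0):
            raise DataError("kernel bandwidth must be strictly positive")


@dataclass
class DiseaseDAG:
    """MeSH-style hierarchy over disease terms.

    ``parent_edges`` holds (child, parent) pairs; ``disease_roots`` maps each
    covered disease identifier to the DAG node that anchors its ancestor
    closure. ``membership_counts[t]`` is the number of covered diseases whose
    ancestor closure contains term ``t``; it is derived, never supplied.
    """

    nodes: list[str]
    parent_edges: set[tuple[str, str]]
    disease_roots: dict[str, str]
    membership_counts: dict[str, int] = field(init=False)
    total_diseases: int = field(init=False)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for child, parent in self.parent_edges:
            if child not in node_set or parent not in node_set:
                raise DataError(f"edge ({child}, {parent}) references unknown node")
        graph = nx.DiGraph()
        graph.add_nodes_from(self.nodes)
        # direction child -> parent so descendants() walks toward ancestors
        graph.add_edges_from(self.parent_edges)
        if not nx.is_directed_acyclic_graph(graph):
            raise DataError("disease hierarchy contains a cycle")
        self._graph = graph
        self._children: dict[str, list[str]] = {t: [] for t in self.nodes}
        for child, parent in self.parent_edges:
            self._children[parent].append(child)
        for disease, node in self.disease_roots.items():
            if node not in node_set:
                raise DataError(f"disease {disease!r} maps to unknown node {node!r}")
        self.total_diseases = len(self.disease_roots)
        counts: dict[str, int] = {}
        for node in self.disease_roots.values():
            for term in self.ancestor_closure(node):
                counts[term] = counts.get(term, 0) + 1
        self.membership_counts = counts

    def __contains__(self, name: str) -> bool:
        return name in self.disease_roots or name in self._graph

    def resolve(self, name: str) -> str:
        """Map a disease id (or a raw DAG node) to its DAG node."""
        if name in self.disease_roots:
            return self.disease_roots[name]
        if name in self._graph:
            return name
        raise DataError(f"disease {name!r} is not in the hierarchy")

    def ancestor_closure(self, node: str) -> frozenset[str]:
        """N(i): the node itself plus all of its ancestors."""
        return self._closure_cached(self.resolve(node))

    @lru_cache(maxsize=None)
    def _closure_cached(self, node: str) -> frozenset[str]:
        return frozenset(nx.descendants(self._graph, node)) | {node}

    def children_of(self, node: str) -> list[str]:
        return list(self._children[node])

    def __hash__(self) -> int:  # needed for the lru_cache bound method
        return id(self)
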
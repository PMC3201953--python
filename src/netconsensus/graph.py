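"""Partially directed interaction graphs and path-distance queries.

Protein-interaction networks mix directed relations (post-translational
state changes such as phosphorylation, where A -> B is informative about
regulatory direction) with undirected relations (physical binding, where
no direction is implied).  This module models such networks as a
*partially directed graph*: a node set plus two disjoint edge sets, one
of ordered pairs and one of unordered pairs.

Two distance semantics coexist and both are exposed:

* ``undirected_distances`` ignores edge directions entirely; it is used
  for clustering genes that are close on the network.
* ``reachable_within_k`` respects direction: directed edges may only be
  traversed source -> target, undirected edges either way.  It underlies
  the common-ancestor queries used for consensus construction.

Self loops are removed at construction, and a node pair reported both as
directed and undirected resolves to the directed interpretation (the
directed annotation carries strictly more information).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "PartiallyDirectedGraph",
    "DistanceMatrix",
    "SifParseError",
    "read_sif",
    "read_edge_list",
    "write_sif",
    "merge_graphs",
    "undirected_distances",
    "reachable_within_k",
    "map_genes_to_network",
    "DEFAULT_SIF_TYPES",
]

#: Default SIF interaction-type handling: binding-style rows become
#: undirected edges, state-change rows become directed edges.
DEFAULT_SIF_TYPES: dict[str, bool] = {
    "INTERACTS_WITH": False,
    "STATE_CHANGE": True,
}


class SifParseError(ValueError):
    """Raised for malformed interaction-file lines; carries the line number."""


def _normalize_type(label: str) -> str:
    return label.strip().upper().replace("-", "_")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass(frozen=True)
class PartiallyDirectedGraph:
    """Immutable graph with directed and undirected edges over gene IDs.

    ``directed_edges`` holds ordered pairs ``(source, target)``;
    ``undirected_edges`` holds unordered pairs stored as sorted tuples.
    Self loops are dropped and directed/undirected conflicts on the same
    node pair resolve in favour of the directed edge.
    """

    nodes: frozenset[str]
    directed_edges: frozenset[tuple[str, str]]
    undirected_edges: frozenset[tuple[str, str]]
    _views: dict = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def build(
        cls,
        directed: Iterable[tuple[str, str]] = (),
        undirected: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ) -> "PartiallyDirectedGraph":
        dir_edges = {(u, v) for u, v in directed if u != v}
        directed_pairs = {frozenset(e) for e in dir_edges}
        undir_edges = set()
        for u, v in undirected:
            if u == v:
                continue
            if frozenset((u, v)) in directed_pairs:
                continue  # directed wins
            undir_edges.add(tuple(sorted((u, v))))
        node_set = set(nodes)
        for u, v in dir_edges | undir_edges:
            node_set.add(u)
            node_set.add(v)
        return cls(
            nodes=frozenset(node_set),
            directed_edges=frozenset(dir_edges),
            undirected_edges=frozenset(undir_edges),
        )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.directed_edges) + len(self.undirected_edges)

    def undirected_view(self) -> nx.Graph:
        """All edges with directions discarded, as a networkx Graph."""
        if "undirected" not in self._views:
            g = nx.Graph()
            g.add_nodes_from(self.nodes)
            g.add_edges_from(self.directed_edges)
            g.add_edges_from(self.undirected_edges)
            self._views["undirected"] = g
        return self._views["undirected"]

    def directed_view(self) -> nx.DiGraph:
        """Direction-respecting DiGraph: undirected edges appear in both
        orientations, directed edges only source -> target."""
        if "directed" not in self._views:
            g = nx.DiGraph()
            g.add_nodes_from(self.nodes)
            g.add_edges_from(self.directed_edges)
            for u, v in self.undirected_edges:
                g.add_edge(u, v)
                g.add_edge(v, u)
            self._views["directed"] = g
        return self._views["directed"]

    def reversed_view(self) -> nx.DiGraph:
        """Transpose of :meth:`directed_view`; used for ancestor queries."""
        if "reversed" not in self._views:
            self._views["reversed"] = self.directed_view().reverse(copy=True)
        return self._views["reversed"]


@dataclass
class DistanceMatrix:
    """Symmetric hop-count matrix over a fixed label order.

    Unreachable pairs carry the sentinel ``len(graph nodes)`` — strictly
    greater than any finite shortest path, so complete-linkage clustering
    bounded by the maximal finite distance can never merge across
    connected components.
    """

    labels: list[str]
    values: np.ndarray
    sentinel: int

    def __post_init__(self) -> None:
        self.index = {g: i for i, g in enumerate(self.labels)}

    def distance(self, a: str, b: str) -> int:
        return int(self.values[self.index[a], self.index[b]])

    def is_reachable(self, a: str, b: str) -> bool:
        return self.distance(a, b) < self.sentinel

    def max_finite(self) -> int:
        finite = self.values[self.values < self.sentinel]
        return int(finite.max()) if finite.size else 0

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy's condensed order."""
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        return self.values[iu].astype(float)


def read_sif(
    path: str | Path,
    keep_types: Iterable[str] | None = None,
    type_direction: dict[str, bool] | None = None,
) -> PartiallyDirectedGraph:
    """Read a tab-delimited SIF interaction file (source, type, target).

    ``keep_types`` restricts to the given interaction-type labels
    (default: the binding and state-change classes).  ``type_direction``
    maps a normalized type label to True (directed) / False (undirected).
    Hyphen/underscore variants of labels are normalized; self loops are
    dropped; duplicate rows collapse.
    """
    mapping = dict(DEFAULT_SIF_TYPES)
    if type_direction:
        mapping.update({_normalize_type(k): v for k, v in type_direction.items()})
    if keep_types is None:
        keep = set(mapping)
    else:
        keep = {_normalize_type(t) for t in keep_types}

    directed, undirected = [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SifParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}: {line!r}"
                )
            src, kind, tgt = fields[0], _normalize_type(fields[1]), fields[2]
            if kind not in keep:
                continue
            if mapping.get(kind, False):
                directed.append((src, tgt))
            else:
                undirected.append((src, tgt))
    graph = PartiallyDirectedGraph.build(directed, undirected)
    if graph.n_edges == 0:
        warnings.warn(f"{path}: no edges retained; empty graph", stacklevel=2)
    return graph


def read_edge_list(path: str | Path, directed_column: str = "directed") -> PartiallyDirectedGraph:
    """Read a 3-column TSV edge list with a header: source, target, flag.

    The flag column (named by ``directed_column``) must hold a boolean
    token (true/false, yes/no, 1/0).  Self loops are dropped.
    """
    truthy = {"true", "t", "yes", "1"}
    falsy = {"false", "f", "no", "0"}
    directed, undirected = [], []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if directed_column not in header:
            raise SifParseError(
                f"{path}: header {header} lacks required column {directed_column!r}"
            )
        flag_idx = header.index(directed_column)
        col_idx = [i for i in range(len(header)) if i != flag_idx][:2]
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise SifParseError(
                    f"{path}: line {lineno}: expected 3 fields, got {len(fields)}"
                )
            flag = fields[flag_idx].strip().lower()
            if flag in truthy:
                directed.append((fields[col_idx[0]], fields[col_idx[1]]))
            elif flag in falsy:
                undirected.append((fields[col_idx[0]], fields[col_idx[1]]))
            else:
                raise SifParseError(
                    f"{path}: line {lineno}: non-boolean directedness flag {fields[flag_idx]!r}"
                )
    return PartiallyDirectedGraph.build(directed, undirected)


def write_sif(graph: PartiallyDirectedGraph, path: str | Path) -> None:
    """Write the graph back to SIF using the default type labels."""
    with open(path, "wt") as fh:
        for u, v in sorted(graph.undirected_edges):
            fh.write(f"{u}\tINTERACTS_WITH\t{v}\n")
        for u, v in sorted(graph.directed_edges):
            fh.write(f"{u}\tSTATE_CHANGE\t{v}\n")


def merge_graphs(
    g1: PartiallyDirectedGraph, g2: PartiallyDirectedGraph
) -> PartiallyDirectedGraph:
    """Union of two networks over a shared identifier space.

    A pair reported directed in one source and undirected in the other
    keeps only the directed edge.
    """
    return PartiallyDirectedGraph.build(
        directed=set(g1.directed_edges) | set(g2.directed_edges),
        undirected=set(g1.undirected_edges) | set(g2.undirected_edges),
        nodes=set(g1.nodes) | set(g2.nodes),
    )


def undirected_distances(
    graph: PartiallyDirectedGraph, sources: Iterable[str]
) -> DistanceMatrix:
    """Hop-count shortest paths between ``sources``, ignoring directions.

    Labels are sorted lexicographically so the matrix (and everything
    downstream, including clustering tie-breaks) is deterministic.
    """
    labels = sorted(set(sources))
    missing = [g for g in labels if g not in graph.nodes]
    if missing:
        raise KeyError(f"genes not in network: {', '.join(missing)}")
    sentinel = max(graph.n_nodes, 1)
    n = len(labels)
    values = np.full((n, n), sentinel, dtype=np.int64)
    np.fill_diagonal(values, 0)
    view = graph.undirected_view()
    idx = {g: i for i, g in enumerate(labels)}
    wanted = set(labels)
    for gene in labels:
        lengths = nx.single_source_shortest_path_length(view, gene)
        i = idx[gene]
        for other, d in lengths.items():
            if other in wanted:
                values[i, idx[other]] = d
    return DistanceMatrix(labels=labels, values=values, sentinel=sentinel)


def reachable_within_k(
    graph: PartiallyDirectedGraph, source: str, k: int
) -> set[tuple[str, int]]:
    """Nodes reachable from ``source`` within ``k`` hops, respecting
    edge directions; each paired with its shortest such distance.

    Includes ``(source, 0)``.
    """
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    if source not in graph.nodes:
        raise KeyError(f"gene not in network: {source}")
    lengths = nx.single_source_shortest_path_length(
        graph.directed_view(), source, cutoff=k
    )
    return {(node, d) for node, d in lengths.items()}


def ancestors_within_k(graph: PartiallyDirectedGraph, target: str, k: int) -> dict[str, int]:
    """Nodes from which ``target`` is direction-respecting reachable
    within ``k`` hops, mapped to that shortest distance.  BFS on the
    transposed graph; includes ``target`` itself at distance 0."""
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    if target not in graph.nodes:
        raise KeyError(f"gene not in network: {target}")
    return dict(
        nx.single_source_shortest_path_length(graph.reversed_view(), target, cutoff=k)
    )


def map_genes_to_network(
    genes: Iterable[str], graph: PartiallyDirectedGraph
) -> tuple[set[str], set[str]]:
    """Partition genes into (mapped, unmapped) by network membership.

    Genes absent from the network cannot take part in path-based
    analysis; they are reported rather than silently dropped.
    """
    genes = set(genes)
    mapped = genes & graph.nodes
    return mapped, genes - mapped
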
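"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own graph machinery:
they work on plain adjacency dictionaries so that agreement with the
implementation is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest

from netconsensus.graph import PartiallyDirectedGraph


def random_pdg(
    rng: np.random.Generator,
    n_nodes: int,
    p_directed: float = 0.05,
    p_undirected: float = 0.05,
) -> PartiallyDirectedGraph:
    """Random partially directed graph over nodes g0..g{n-1}."""
    nodes = [f"g{i}" for i in range(n_nodes)]
    directed, undirected = [], []
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i == j:
                continue
            r = rng.random()
            if r < p_directed:
                directed.append((nodes[i], nodes[j]))
            elif r < p_directed + p_undirected and i < j:
                undirected.append((nodes[i], nodes[j]))
    return PartiallyDirectedGraph.build(directed, undirected, nodes=nodes)


def directed_adjacency(graph: PartiallyDirectedGraph) -> dict[str, set[str]]:
    """Direction-respecting successor map built from the raw edge sets."""
    adj: dict[str, set[str]] = {v: set() for v in graph.nodes}
    for u, v in graph.directed_edges:
        adj[u].add(v)
    for u, v in graph.undirected_edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def undirected_adjacency(graph: PartiallyDirectedGraph) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {v: set() for v in graph.nodes}
    for u, v in set(graph.directed_edges) | set(graph.undirected_edges):
        adj[u].add(v)
        adj[v].add(u)
    return adj


def brute_force_distances(adj: dict[str, set[str]], inf: float = float("inf")) -> dict[str, dict[str, float]]:
    """Floyd-Warshall all-pairs hop counts on an adjacency map."""
    nodes = sorted(adj)
    dist = {u: {v: (0 if u == v else (1 if v in adj[u] else inf)) for v in nodes} for u in nodes}
    for k in nodes:
        for i in nodes:
            dik = dist[i][k]
            if dik == inf:
                continue
            row_k = dist[k]
            row_i = dist[i]
            for j in nodes:
                alt = dik + row_k[j]
                if alt < row_i[j]:
                    row_i[j] = alt
    return dist


def brute_force_lca(
    graph: PartiallyDirectedGraph, targets: set[str], k: int
) -> tuple[dict[str, float], set[str]]:
    """Exhaustive k-common-ancestor / LCA search over every node,
    using Floyd-Warshall on the direction-respecting adjacency."""
    dist = brute_force_distances(directed_adjacency(graph))
    cas: dict[str, float] = {}
    for a in graph.nodes:
        ds = [dist[a][t] for t in targets]
        if all(d <= k for d in ds):
            cas[a] = sum(ds) / len(ds)
    if not cas:
        return {}, set()
    best = min(cas.values())
    return cas, {a for a, d in cas.items() if d == best}


@pytest.fixture
def toy_fanout() -> PartiallyDirectedGraph:
    """The worked example: A regulates B and C by directed edges."""
    return PartiallyDirectedGraph.build(directed=[("A", "B"), ("A", "C")])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210)
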
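"""Consensus-signature construction on a protein-interaction network.

Published gene signatures for the same clinical question often share
almost no genes, yet their members tend to sit close together on the
protein-interaction network, frequently downstream of shared regulators.
The consensus algorithm implemented here exploits that:

1. The *majority signature* — genes present in strictly more than a
   given fraction (default half) of the input signatures — seeds the
   consensus.  It is frequently empty.
2. All remaining signature genes that map to the network become
   *candidates*.  Their pairwise shortest-path hop distances, ignoring
   edge directions, feed a complete-linkage clustering tree, whose
   compact clusters bound the within-cluster network diameter.
3. Sweeping the cut height h = 1 .. max finite candidate distance, every
   cluster covering at least two distinct signatures is handed to the
   common-ancestor search: a *k-common ancestor* (k-CA) of a cluster is
   a node from which every cluster member is reachable within k hops,
   traversing directed edges only with their direction.  The *lowest*
   common ancestors (LCAs) are the k-CAs with minimal average
   direction-respecting distance to the cluster; ties are all kept, and
   the LCA may be empty.
4. The consensus is the union of the majority signature with every LCA
   found during the sweep, with provenance recording which cluster at
   which height produced each LCA gene.

The default path-distance cutoff is k = 2: an ancestor more than two
hops upstream is unlikely to exert a specific regulatory influence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .graph import (
    DistanceMatrix,
    PartiallyDirectedGraph,
    ancestors_within_k,
    map_genes_to_network,
    undirected_distances,
)

__all__ = [
    "SignatureCollection",
    "ConsensusConfig",
    "LinkageTree",
    "ClusterSet",
    "LcaProvenance",
    "ConsensusResult",
    "majority_signature",
    "build_candidates",
    "complete_linkage_tree",
    "cut_tree",
    "multi_signature_clusters",
    "k_common_ancestors",
    "lowest_common_ancestors",
    "build_consensus",
]


class EmptyCandidateError(ValueError):
    """No signature gene maps to the network outside the majority set."""


@dataclass
class SignatureCollection:
    """Ordered, uniquely named gene signatures; genes may recur across
    signatures."""

    signatures: dict[str, set[str]]

    def __post_init__(self) -> None:
        for name, genes in self.signatures.items():
            if not genes:
                raise ValueError(f"signature {name!r} is empty")

    @classmethod
    def from_gmt(cls, path) -> "SignatureCollection":
        from .io import read_gmt

        return cls(read_gmt(path))

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures.items())

    def names(self) -> list[str]:
        return list(self.signatures)

    def union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.signatures.values():
            out |= genes
        return out

    def membership_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for genes in self.signatures.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        return counts

    def signatures_of(self, gene: str) -> set[str]:
        return {name for name, genes in self.signatures.items() if gene in genes}

    def subset(self, names: Sequence[str]) -> "SignatureCollection":
        return SignatureCollection({n: set(self.signatures[n]) for n in names})


@dataclass(frozen=True)
class ConsensusConfig:
    """Tunables of the consensus algorithm.

    ``k`` is the path-distance cutoff for the ancestor search (hops);
    ``majority_fraction`` is the strict threshold for the majority
    signature: a gene qualifies only if its membership count exceeds
    ``majority_fraction * n_signatures``.
    """

    k: int = 2
    majority_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if not 0.0 < self.majority_fraction < 1.0:
            raise ValueError("majority_fraction must lie strictly in (0, 1)")


@dataclass
class LinkageTree:
    """Complete-linkage dendrogram over a fixed, sorted leaf order.

    ``merges`` is the scipy linkage matrix: row i joins clusters
    ``merges[i, 0]`` and ``merges[i, 1]`` at height ``merges[i, 2]``.
    Complete linkage on a metric yields non-decreasing merge heights.
    """

    leaves: list[str]
    merges: np.ndarray  # shape (n-1, 4), scipy convention

    @property
    def root_height(self) -> float:
        return float(self.merges[-1, 2]) if len(self.merges) else 0.0


@dataclass
class ClusterSet:
    """A partition of the candidate genes with per-cluster signature
    coverage (the set of signature names whose genes it contains)."""

    clusters: list[set[str]]
    coverage: list[set[str]]


@dataclass(frozen=True)
class LcaProvenance:
    """One cluster that produced an LCA gene during the height sweep."""

    height: int
    cluster: frozenset[str]
    average_distance: float


@dataclass
class ConsensusResult:
    """Output of the consensus algorithm.

    ``consensus`` is ``majority_genes | lca_genes``.  ``provenance``
    maps each LCA gene to every (height, cluster, average distance)
    record that produced it; ``unmapped_genes`` lists signature genes
    absent from the network and therefore excluded from the analysis.
    """

    majority_genes: set[str]
    lca_genes: set[str]
    provenance: dict[str, list[LcaProvenance]]
    unmapped_genes: set[str]

    @property
    def consensus(self) -> set[str]:
        return self.majority_genes | self.lca_genes


def majority_signature(
    sigs: SignatureCollection, fraction: float = 0.5
) -> set[str]:
    """Genes present in strictly more than ``fraction`` of the signatures.

    With the default 0.5 and six signatures a gene needs at least four
    memberships (4 > 3); exactly half never qualifies.  The result is
    often empty for disparate published signatures.
    """
    if len(sigs) < 1:
        raise ValueError("need at least one signature")
    threshold = fraction * len(sigs)
    return {g for g, c in sigs.membership_counts().items() if c > threshold}


def build_candidates(
    sigs: SignatureCollection,
    majority: set[str],
    graph: PartiallyDirectedGraph,
) -> tuple[set[str], set[str]]:
    """Network-mapped signature genes outside the majority set.

    Returns ``(candidates, unmapped)``; raises
    :class:`EmptyCandidateError` when nothing remains, which usually
    signals an identifier-space mismatch between signatures and network.
    """
    pool = sigs.union() - majority
    mapped, unmapped = map_genes_to_network(pool, graph)
    if not mapped and pool:
        raise EmptyCandidateError(
            "no candidate gene maps to the network; check that signatures "
            "and network share one identifier space"
        )
    return mapped, unmapped


def complete_linkage_tree(dmat: DistanceMatrix) -> LinkageTree:
    """Agglomerative complete-linkage tree over the distance matrix.

    Merge heights equal the maximum pairwise distance between the joined
    clusters.  Equal-height ties resolve deterministically because leaf
    labels are lexicographically sorted upstream; cluster memberships at
    any cut are invariant to that choice.
    """
    n = len(dmat.labels)
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        return LinkageTree(leaves=list(dmat.labels), merges=np.empty((0, 4)))
    merges = linkage(dmat.condensed(), method="complete")
    return LinkageTree(leaves=list(dmat.labels), merges=merges)


def cut_tree(tree: LinkageTree, h: float) -> list[set[str]]:
    """Clusters formed by all merges of cophenetic height <= h.

    The comparison is non-strict: hop distances are integers and the
    consensus sweep runs over integer heights, so a strict cut would
    skip every merge sitting exactly at h.  ``h = 0`` yields singletons.
    """
    if h < 0:
        raise ValueError("cut height must be non-negative")
    if len(tree.leaves) == 1:
        return [set(tree.leaves)]
    assignments = fcluster(tree.merges, t=h, criterion="distance")
    groups: dict[int, set[str]] = {}
    for leaf, cid in zip(tree.leaves, assignments):
        groups.setdefault(cid, set()).add(leaf)
    return sorted(groups.values(), key=lambda s: sorted(s)[0])


def multi_signature_clusters(
    clusters: Iterable[set[str]], sigs: SignatureCollection
) -> ClusterSet:
    """Clusters whose genes collectively cover >= 2 signature names.

    Coverage counts signature memberships, not distinct genes: a
    singleton cluster whose gene belongs to two signatures already links
    those signatures and is retained.
    """
    kept: list[set[str]] = []
    coverage: list[set[str]] = []
    for cluster in clusters:
        names: set[str] = set()
        for g in cluster:
            names |= sigs.signatures_of(g)
        if len(names) >= 2:
            kept.append(set(cluster))
            coverage.append(names)
    return ClusterSet(clusters=kept, coverage=coverage)


def k_common_ancestors(
    graph: PartiallyDirectedGraph, targets: Iterable[str], k: int
) -> dict[str, float]:
    """Nodes from which every target is reachable within k hops,
    respecting directions, mapped to their average distance to targets.

    Computed by breadth-first search from each target on the transposed
    graph and intersecting the ancestor sets.  Targets are their own
    ancestors at distance 0, so cluster members are eligible.  May be
    empty.
    """
    targets = sorted(set(targets))
    if not targets:
        raise ValueError("targets must be non-empty")
    totals: dict[str, float] | None = None
    for t in targets:
        dists = ancestors_within_k(graph, t, k)
        if totals is None:
            totals = {a: float(d) for a, d in dists.items()}
        else:
            totals = {
                a: totals[a] + d for a, d in dists.items() if a in totals
            }
        if not totals:
            return {}
    assert totals is not None
    m = len(targets)
    return {a: s / m for a, s in totals.items()}


def lowest_common_ancestors(
    graph: PartiallyDirectedGraph, targets: Iterable[str], k: int
) -> set[str]:
    """The k-common ancestors with minimal average direction-respecting
    distance to the targets; all ties returned, possibly empty."""
    cas = k_common_ancestors(graph, targets, k)
    if not cas:
        return set()
    best = min(cas.values())
    return {a for a, d in cas.items() if d == best}


def build_consensus(
    sigs: SignatureCollection,
    graph: PartiallyDirectedGraph,
    cfg: ConsensusConfig = ConsensusConfig(),
) -> ConsensusResult:
    """Run the full consensus algorithm; deterministic given its inputs.

    Majority genes seed the consensus; the remaining mapped signature
    genes are clustered by undirected hop distance with complete
    linkage, and for every cut height from 1 to the maximal finite
    candidate distance, each multi-signature cluster contributes its
    LCAs.  Repeated discoveries of the same ancestor collapse by set
    union, with provenance keeping every producing cluster.
    """
    if len(sigs) < 2:
        raise ValueError("consensus needs at least two signatures")
    majority = majority_signature(sigs, cfg.majority_fraction)
    try:
        candidates, unmapped = build_candidates(sigs, majority, graph)
    except EmptyCandidateError:
        if majority:
            return ConsensusResult(
                majority_genes=majority,
                lca_genes=set(),
                provenance={},
                unmapped_genes=sigs.union() - majority - graph.nodes,
            )
        raise

    lca_genes: set[str] = set()
    provenance: dict[str, list[LcaProvenance]] = {}
    if candidates:
        dmat = undirected_distances(graph, candidates)
        tree = complete_linkage_tree(dmat)
        seen_clusters: set[frozenset[str]] = set()
        max_h = dmat.max_finite()
        for h in range(1, max_h + 1):
            cset = multi_signature_clusters(cut_tree(tree, h), sigs)
            for cluster in cset.clusters:
                key = frozenset(cluster)
                if key in seen_clusters:
                    continue
                seen_clusters.add(key)
                cas = k_common_ancestors(graph, cluster, cfg.k)
                if not cas:
                    continue
                best = min(cas.values())
                for anc, avg in cas.items():
                    if avg == best:
                        lca_genes.add(anc)
                        provenance.setdefault(anc, []).append(
                            LcaProvenance(height=h, cluster=key, average_distance=avg)
                        )
    if not majority and not lca_genes:
        warnings.warn("consensus is empty: no majority gene and no common ancestor found")
    return ConsensusResult(
        majority_genes=majority,
        lca_genes=lca_genes,
        provenance=provenance,
        unmapped_genes=unmapped,
    )


def write_consensus_tsv(result: ConsensusResult, path) -> None:
    """TSV with columns gene, source (majority|LCA), provenance."""
    with open(path, "wt") as fh:
        fh.write("gene\tsource\tprovenance\n")
        for g in sorted(result.majority_genes):
            fh.write(f"{g}\tmajority\t\n")
        for g in sorted(result.lca_genes):
            recs = result.provenance.get(g, [])
            desc = ";".join(
                f"h={r.height},cluster={'|'.join(sorted(r.cluster))},avg_dist={r.average_distance:g}"
                for r in recs
            )
            fh.write(f"{g}\tLCA\t{desc}\n")
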
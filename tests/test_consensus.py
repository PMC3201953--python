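"""Consensus algorithm: majority signature, clustering, common
ancestors, and the full assembly."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netconsensus.consensus import (
    ConsensusConfig,
    EmptyCandidateError,
    SignatureCollection,
    build_candidates,
    build_consensus,
    complete_linkage_tree,
    cut_tree,
    k_common_ancestors,
    lowest_common_ancestors,
    majority_signature,
    multi_signature_clusters,
)
from netconsensus.graph import DistanceMatrix, PartiallyDirectedGraph

from conftest import brute_force_lca, random_pdg


def _sigs(**kwargs) -> SignatureCollection:
    return SignatureCollection({k: set(v) for k, v in kwargs.items()})


def _dmat(labels, pairs, sentinel=100) -> DistanceMatrix:
    n = len(labels)
    values = np.zeros((n, n), dtype=np.int64)
    idx = {l: i for i, l in enumerate(labels)}
    for (a, b), d in pairs.items():
        values[idx[a], idx[b]] = d
        values[idx[b], idx[a]] = d
    return DistanceMatrix(labels=list(labels), values=values, sentinel=sentinel)


class TestMajoritySignature:
    def test_strictly_more_than_half(self):
        sigs = _sigs(**{f"S{i}": {"g"} if i < 4 else {"x"} for i in range(6)})
        assert "g" in majority_signature(sigs)  # 4 of 6 > 3

    def test_exactly_half_excluded(self):
        sigs = _sigs(**{f"S{i}": {"g"} if i < 3 else {"x"} for i in range(6)})
        assert "g" not in majority_signature(sigs)  # 3 of 6 is not > 3

    def test_disjoint_pair_empty(self):
        assert majority_signature(_sigs(S1={"a"}, S2={"b"})) == set()

    @given(
        st.dictionaries(
            st.text(alphabet="ABCDEFGH", min_size=1, max_size=2),
            st.integers(min_value=1, max_value=12),
            min_size=1,
            max_size=8,
        ),
        st.integers(min_value=2, max_value=12),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_membership_threshold_is_strict(self, gene_counts, n_sigs):
        # build signatures realising the requested membership counts
        sigs = {
            f"S{i}": {g for g, c in gene_counts.items() if min(c, n_sigs) > i}
            | {f"pad{i}"}
            for i in range(n_sigs)
        }
        result = majority_signature(SignatureCollection(sigs))
        for gene, count in gene_counts.items():
            assert (gene in result) == (min(count, n_sigs) > n_sigs / 2)

    def test_never_at_exactly_threshold(self):
        # a gene in exactly half the signatures never qualifies, for any
        # even signature count
        for n in (2, 4, 8):
            sigs = _sigs(**{f"S{i}": {"g"} if i < n // 2 else {f"x{i}"} for i in range(n)})
            assert majority_signature(sigs) == set()


class TestBuildCandidates:
    def test_union_minus_majority(self):
        g = PartiallyDirectedGraph.build(undirected=[("B", "C")])
        cand, unmapped = build_candidates(_sigs(S1={"B"}, S2={"C"}), set(), g)
        assert cand == {"B", "C"} and unmapped == set()

    def test_majority_excluded(self):
        g = PartiallyDirectedGraph.build(undirected=[("B", "C")])
        cand, _ = build_candidates(_sigs(S1={"B", "C"}, S2={"C"}), {"C"}, g)
        assert cand == {"B"}

    def test_unmapped_reported(self):
        g = PartiallyDirectedGraph.build(undirected=[("B", "C")])
        cand, unmapped = build_candidates(_sigs(S1={"B"}, S2={"Z"}), set(), g)
        assert cand == {"B"} and unmapped == {"Z"}

    def test_nothing_maps_errors(self):
        g = PartiallyDirectedGraph.build(undirected=[("B", "C")])
        with pytest.raises(EmptyCandidateError, match="identifier space"):
            build_candidates(_sigs(S1={"X"}, S2={"Y"}), set(), g)


class TestCompleteLinkage:
    def test_two_points(self):
        tree = complete_linkage_tree(_dmat(["B", "C"], {("B", "C"): 2}))
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == 2

    def test_three_point_hand_run(self):
        # d(x,y)=1, d(x,z)=d(y,z)=5: merge {x,y} at 1, then all at 5
        tree = complete_linkage_tree(
            _dmat(["x", "y", "z"], {("x", "y"): 1, ("x", "z"): 5, ("y", "z"): 5})
        )
        assert list(tree.merges[:, 2]) == [1, 5]

    def test_single_leaf_degenerate(self):
        tree = complete_linkage_tree(_dmat(["x"], {}))
        assert tree.leaves == ["x"] and len(tree.merges) == 0

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_naive_agglomerative_oracle(self, trial, rng):
        # brute-force complete linkage: repeatedly merge the pair of
        # clusters with the smallest maximum inter-point distance
        n = int(rng.integers(3, 13))
        labels = [f"g{i}" for i in range(n)]
        # continuous distances: distinct values make the merge order
        # unambiguous, so the oracle comparison is well-defined
        raw = rng.random((n, n)) * 9 + 1
        values = np.triu(raw, 1) + np.triu(raw, 1).T
        dmat = DistanceMatrix(labels=labels, values=values, sentinel=1000)
        tree = complete_linkage_tree(dmat)

        clusters = [{i} for i in range(n)]
        heights = []
        while len(clusters) > 1:
            best = None
            for a, b in itertools.combinations(range(len(clusters)), 2):
                h = max(values[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or h < best[0]:
                    best = (h, a, b)
            h, a, b = best
            heights.append(h)
            clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [
                clusters[a] | clusters[b]
            ]
        assert np.allclose(np.sort(tree.merges[:, 2]), np.sort(heights))

    def test_merge_heights_non_decreasing(self, rng):
        for _ in range(5):
            n = int(rng.integers(3, 10))
            raw = rng.integers(1, 8, size=(n, n))
            values = np.triu(raw, 1) + np.triu(raw, 1).T
            tree = complete_linkage_tree(
                DistanceMatrix(labels=[f"g{i}" for i in range(n)], values=values, sentinel=1000)
            )
            h = tree.merges[:, 2]
            assert np.all(np.diff(h) >= 0)


class TestCutTree:
    @pytest.fixture
    def three_point_tree(self):
        return complete_linkage_tree(
            _dmat(["x", "y", "z"], {("x", "y"): 1, ("x", "z"): 5, ("y", "z"): 5})
        )

    def test_intermediate_cut(self, three_point_tree):
        assert cut_tree(three_point_tree, 1) == [{"x", "y"}, {"z"}]

    def test_zero_cut_is_singletons(self, three_point_tree):
        assert cut_tree(three_point_tree, 0) == [{"x"}, {"y"}, {"z"}]

    def test_root_cut_is_one_cluster(self, three_point_tree):
        assert cut_tree(three_point_tree, 5) == [{"x", "y", "z"}]

    def test_cut_is_non_strict_at_height(self, three_point_tree):
        # merge sitting exactly at the cut height is included
        clusters = cut_tree(three_point_tree, 1)
        assert {"x", "y"} in clusters

    def test_nesting_refinement(self, rng):
        for _ in range(5):
            n = int(rng.integers(4, 12))
            raw = rng.integers(1, 8, size=(n, n))
            values = np.triu(raw, 1) + np.triu(raw, 1).T
            tree = complete_linkage_tree(
                DistanceMatrix(labels=[f"g{i}" for i in range(n)], values=values, sentinel=1000)
            )
            for h in range(0, 8):
                fine = cut_tree(tree, h)
                coarse = cut_tree(tree, h + 1)
                for c in fine:
                    assert any(c <= d for d in coarse)


class TestMultiSignatureClusters:
    def test_cross_signature_cluster_kept(self):
        cs = multi_signature_clusters([{"B", "C"}], _sigs(S1={"B"}, S2={"C"}))
        assert cs.clusters == [{"B", "C"}]
        assert cs.coverage == [{"S1", "S2"}]

    def test_single_signature_cluster_dropped(self):
        cs = multi_signature_clusters([{"B", "B2"}], _sigs(S1={"B", "B2"}, S2={"C"}))
        assert cs.clusters == []

    def test_multi_membership_singleton_kept(self):
        cs = multi_signature_clusters([{"g"}], _sigs(S1={"g"}, S2={"g"}))
        assert cs.clusters == [{"g"}]


class TestCommonAncestors:
    def test_hub_is_unique_ancestor(self, toy_fanout):
        assert k_common_ancestors(toy_fanout, {"B", "C"}, 2) == {"A": 1.0}

    def test_undirected_edge_targets_are_mutual_ancestors(self):
        g = PartiallyDirectedGraph.build(undirected=[("B", "C")])
        assert k_common_ancestors(g, {"B", "C"}, 2) == {"B": 0.5, "C": 0.5}

    def test_separate_components_empty(self):
        g = PartiallyDirectedGraph.build(nodes=["B", "C"])
        assert k_common_ancestors(g, {"B", "C"}, 5) == {}

    def test_lca_argmin(self):
        # A one hop from both targets; Z two hops (through A)
        g = PartiallyDirectedGraph.build(
            directed=[("A", "B"), ("A", "C"), ("Z", "A")]
        )
        cas = k_common_ancestors(g, {"B", "C"}, 2)
        assert cas == {"A": 1.0, "Z": 2.0}
        assert lowest_common_ancestors(g, {"B", "C"}, 2) == {"A"}

    def test_lca_ties_all_returned(self):
        g = PartiallyDirectedGraph.build(undirected=[("B", "C")])
        assert lowest_common_ancestors(g, {"B", "C"}, 2) == {"B", "C"}

    def test_lca_empty_when_no_ancestor(self):
        g = PartiallyDirectedGraph.build(nodes=["B", "C"])
        assert lowest_common_ancestors(g, {"B", "C"}, 3) == set()

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_exhaustive_search(self, k, rng):
        for _ in range(15):
            g = random_pdg(rng, int(rng.integers(5, 41)), 0.08, 0.08)
            nodes = sorted(g.nodes)
            targets = set(rng.choice(nodes, size=int(rng.integers(2, 5)), replace=False))
            cas_expected, lca_expected = brute_force_lca(g, targets, k)
            assert k_common_ancestors(g, targets, k) == cas_expected
            assert lowest_common_ancestors(g, targets, k) == lca_expected


class TestBuildConsensus:
    def test_worked_fanout_example(self, toy_fanout):
        result = build_consensus(
            _sigs(S1={"B"}, S2={"C"}), toy_fanout, ConsensusConfig(k=2)
        )
        assert result.consensus == {"A"}
        assert result.majority_genes == set()
        assert result.lca_genes == {"A"}
        assert result.provenance["A"][0].cluster == frozenset({"B", "C"})
        assert result.provenance["A"][0].average_distance == 1.0

    def test_worked_fanout_k0_empty(self, toy_fanout):
        with pytest.warns(UserWarning, match="empty"):
            result = build_consensus(
                _sigs(S1={"B"}, S2={"C"}), toy_fanout, ConsensusConfig(k=0)
            )
        assert result.consensus == set()

    def test_identical_signatures_majority_only(self):
        g = PartiallyDirectedGraph.build(undirected=[("B", "X")])
        result = build_consensus(_sigs(S1={"B"}, S2={"B"}), g)
        assert result.majority_genes == {"B"}
        assert result.consensus == {"B"}

    def test_disconnected_no_ancestor(self):
        g = PartiallyDirectedGraph.build(nodes=["B", "C"])
        with pytest.warns(UserWarning, match="empty"):
            result = build_consensus(_sigs(S1={"B"}, S2={"C"}), g)
        assert result.consensus == set()

    def test_unmapped_reported_not_dropped_silently(self, toy_fanout):
        result = build_consensus(_sigs(S1={"B", "ZZZ"}, S2={"C"}), toy_fanout)
        assert result.unmapped_genes == {"ZZZ"}

    def test_invariant_to_signature_and_gene_order(self, rng):
        g = random_pdg(rng, 30, 0.1, 0.1)
        nodes = sorted(g.nodes)
        sig_sets = [set(rng.choice(nodes, size=5, replace=False)) for _ in range(3)]
        base = build_consensus(
            SignatureCollection({f"S{i}": s for i, s in enumerate(sig_sets)}), g
        )
        flipped = build_consensus(
            SignatureCollection(
                {f"S{i}": set(sorted(s, reverse=True)) for i, s in enumerate(reversed(sig_sets))}
            ),
            g,
        )
        assert base.consensus == flipped.consensus

    def test_planted_regulator_recovered(self):
        # hub with directed edges to 2m mutually non-adjacent targets,
        # split evenly between two signatures
        m = 3
        targets = [f"T{i}" for i in range(2 * m)]
        g = PartiallyDirectedGraph.build(directed=[("HUB", t) for t in targets])
        sigs = _sigs(S1=set(targets[:m]), S2=set(targets[m:]))
        result = build_consensus(sigs, g, ConsensusConfig(k=2))
        assert "HUB" in result.consensus

    def test_requires_two_signatures(self, toy_fanout):
        with pytest.raises(ValueError):
            build_consensus(_sigs(S1={"B"}), toy_fanout)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [{"k": -1}, {"majority_fraction": 0.0}, {"majority_fraction": 1.0}])
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ConsensusConfig(**kwargs)
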
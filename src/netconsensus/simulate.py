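"""Synthetic data generators and the performance-study driver.

Two generators supply a download-free test surface with known ground
truth:

* **Planted-regulator networks** — a directed Erdős–Rényi background
  graph (with a stated fraction of edges converted to undirected) plus
  a set of hub nodes, each wired hub -> target to its own targets.  The
  targets are split across signatures (round-robin by default), so no
  hub's downstream genes sit in a single signature; a consensus
  algorithm that searches for shared upstream regulators should recover
  the hubs.
* **Two-group expression matrices** — unit-variance Gaussian noise with
  a mean shift (in SD units) applied to a designated differential
  feature set in class 2, which can be confined to a prior feature set.
  This is the regime in which prior-restricted selection shows its
  stability advantage.

``performance_study`` subsamples signatures (2, 3, ..., S of them),
reruns the consensus per draw, and tracks annotation enrichment and
majority-signature existence per subset size.
``random_signature_stability`` contrasts the pairwise overlap of random
signatures drawn from the whole array against draws from a prior set
(expected overlap of two uniform size-n draws from N features is
n^2/N).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .biomarker import ExpressionDataset
from .consensus import (
    ConsensusConfig,
    SignatureCollection,
    build_consensus,
)
from .enrichment import hypergeometric_enrichment
from .graph import PartiallyDirectedGraph

__all__ = [
    "PlantedNetworkSpec",
    "ExpressionSimSpec",
    "generate_planted_network",
    "generate_expression",
    "performance_study",
    "random_signature_stability",
]


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Parameters of the planted-regulator network generator."""

    n_background: int = 200
    n_regulators: int = 4
    targets_per_regulator: int = 12
    n_signatures: int = 6
    background_edge_p: float = 0.01
    undirected_fraction: float = 0.3
    assignment: str = "round_robin"  # or "random"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.background_edge_p <= 1:
            raise ValueError("background_edge_p must lie in [0, 1]")
        if not 0 <= self.undirected_fraction <= 1:
            raise ValueError("undirected_fraction must lie in [0, 1]")
        if self.n_background < 0 or self.n_regulators < 0:
            raise ValueError("counts must be non-negative")
        if self.n_regulators > 0 and self.targets_per_regulator < 1:
            raise ValueError("each regulator needs at least one target")
        if self.n_signatures < 2:
            raise ValueError("need at least two signatures")
        if self.assignment not in ("round_robin", "random"):
            raise ValueError("assignment must be 'round_robin' or 'random'")


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Parameters of the two-group expression generator.

    ``effect_size`` is the class-2 mean shift in SD units of the
    unit-variance Gaussian noise.  ``prior_size`` features form the
    prior set; ``frac_differential_in_prior`` of the differential
    features are placed inside it (1.0 = all signal inside the prior).
    """

    n_features: int = 1000
    n_per_class: int = 20
    n_differential: int = 50
    effect_size: float = 1.0
    prior_size: int = 100
    frac_differential_in_prior: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_differential > self.n_features:
            raise ValueError("n_differential exceeds n_features")
        if self.prior_size > self.n_features:
            raise ValueError("prior_size exceeds n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0 <= self.frac_differential_in_prior <= 1:
            raise ValueError("frac_differential_in_prior must lie in [0, 1]")
        n_inside = round(self.n_differential * self.frac_differential_in_prior)
        if n_inside > self.prior_size:
            raise ValueError("more in-prior differential features than prior slots")


def generate_planted_network(
    spec: PlantedNetworkSpec,
) -> tuple[PartiallyDirectedGraph, SignatureCollection, set[str]]:
    """Build a planted-regulator network with matching signatures.

    Returns ``(graph, signatures, hubs)`` where every hub has directed
    edges to its targets and each hub's targets are spread over the
    signatures (round-robin keeps the spread even; 'random' assigns
    uniformly).  Bit-reproducible given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    hubs = [f"HUB{i}" for i in range(spec.n_regulators)]
    targets = [
        f"T{i}_{j}"
        for i in range(spec.n_regulators)
        for j in range(spec.targets_per_regulator)
    ]
    background = [f"BG{i}" for i in range(spec.n_background)]
    all_nodes = hubs + targets + background

    directed: set[tuple[str, str]] = set()
    undirected: set[tuple[str, str]] = set()
    for i, hub in enumerate(hubs):
        for j in range(spec.targets_per_regulator):
            directed.add((hub, f"T{i}_{j}"))

    if spec.background_edge_p > 0 and len(all_nodes) > 1:
        n = len(all_nodes)
        # directed ER over ordered pairs; a stated fraction made undirected
        mask = rng.random((n, n)) < spec.background_edge_p
        np.fill_diagonal(mask, False)
        for a, b in zip(*np.nonzero(mask)):
            u, v = all_nodes[a], all_nodes[b]
            if rng.random() < spec.undirected_fraction:
                undirected.add(tuple(sorted((u, v))))
            else:
                directed.add((u, v))

    graph = PartiallyDirectedGraph.build(directed, undirected, nodes=all_nodes)

    sigs: dict[str, set[str]] = {f"S{i}": set() for i in range(spec.n_signatures)}
    names = list(sigs)
    for i in range(spec.n_regulators):
        for j in range(spec.targets_per_regulator):
            if spec.assignment == "round_robin":
                # offset by hub index so hubs cover different signature
                # subsets when targets_per_regulator < n_signatures
                sig = names[(i + j) % spec.n_signatures]
            else:
                sig = names[rng.integers(spec.n_signatures)]
            sigs[sig].add(f"T{i}_{j}")
    for name in names:  # keep every signature non-empty
        if not sigs[name]:
            sigs[name].add(background[rng.integers(len(background))] if background else hubs[0])
    return graph, SignatureCollection(sigs), set(hubs)


def generate_expression(
    spec: ExpressionSimSpec,
) -> tuple[ExpressionDataset, set[str], set[str]]:
    """Two-group Gaussian expression with a planted differential set.

    Returns ``(dataset, differential_features, prior_features)``.
    Class 1 features are N(0,1); differential features get a mean shift
    of ``effect_size`` in class 2.  Feature IDs double as gene IDs.
    """
    rng = np.random.default_rng(spec.seed)
    features = [f"F{i}" for i in range(spec.n_features)]
    n = 2 * spec.n_per_class
    X = rng.standard_normal((spec.n_features, n))
    labels = np.array([0] * spec.n_per_class + [1] * spec.n_per_class)

    n_inside = round(spec.n_differential * spec.frac_differential_in_prior)
    n_outside = spec.n_differential - n_inside
    prior = set(features[: spec.prior_size])
    diff = set(features[:n_inside])
    outside_pool = features[spec.prior_size :]
    diff |= set(outside_pool[:n_outside])

    diff_idx = [i for i, f in enumerate(features) if f in diff]
    X[np.ix_(diff_idx, np.flatnonzero(labels == 1))] += spec.effect_size

    data = ExpressionDataset(
        values=X,
        feature_ids=features,
        sample_ids=[f"sample{i}" for i in range(n)],
        labels=labels,
    )
    return data, diff, prior


def performance_study(
    sigs: SignatureCollection,
    graph: PartiallyDirectedGraph,
    annotations: dict[str, set[str]],
    subset_sizes: Sequence[int] | None = None,
    reps: int = 100,
    seed: int | None = None,
    cfg: ConsensusConfig = ConsensusConfig(),
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Subsample signatures, rebuild the consensus, track enrichment.

    For every subset size and repetition, ``size`` signatures are drawn
    without replacement, the consensus is rebuilt, and each annotation
    set's hypergeometric enrichment p in the consensus is recorded along
    with whether a (non-empty) majority signature existed.  The universe
    defaults to the network's node set.  Returns a tidy frame with
    columns size, rep, annotation, p, majority_exists, consensus_size.
    """
    names = sigs.names()
    if subset_sizes is None:
        subset_sizes = range(2, len(names) + 1)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    uni = set(universe) if universe is not None else set(graph.nodes)
    rng = np.random.default_rng(seed)
    rows = []
    for size in subset_sizes:
        if size > len(names):
            raise ValueError(f"subset size {size} exceeds {len(names)} signatures")
        for rep in range(reps):
            chosen = list(rng.choice(names, size=size, replace=False))
            sub = sigs.subset(chosen)
            try:
                result = build_consensus(sub, graph, cfg)
                consensus = result.consensus
                majority_exists = bool(result.majority_genes)
            except ValueError:
                consensus, majority_exists = set(), False
            for ann_name, ann_genes in annotations.items():
                if consensus:
                    res = hypergeometric_enrichment(
                        consensus, {ann_name: set(ann_genes)}, universe=uni
                    )
                    p = res.records[0].p_raw
                else:
                    p = 1.0
                rows.append(
                    {
                        "size": size,
                        "rep": rep,
                        "annotation": ann_name,
                        "p": p,
                        "majority_exists": majority_exists,
                        "consensus_size": len(consensus),
                    }
                )
    return pd.DataFrame(rows)


def selection_stability_comparison(
    spec: ExpressionSimSpec,
    n_replicates: int = 50,
    R: int = 5,
    F: int = 5,
    q_cutoff: float = 0.05,
    B: int = 100,
    seed: int | None = None,
    fit_classifier: bool = False,
) -> pd.DataFrame:
    """Prior-restricted vs all-features selection stability.

    Each replicate draws a fresh expression matrix from ``spec`` (with
    the differential signal confined to the prior when the spec says
    so) and runs the repeated cross-validated selection pipeline twice:
    once restricted to the prior set, once over all features.  Returns
    one row per replicate with the constancy fraction of each arm (and
    mean AUCs when ``fit_classifier``).  Restricting selection to an
    informative prior is expected to raise the constancy fraction.
    """
    import warnings

    from .biomarker import SvmConfig, repeated_cv_evaluate

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    children = ss.generate_state(3 * n_replicates).tolist()
    rows = []
    cfg = SvmConfig()
    for rep in range(n_replicates):
        data_seed = children[3 * rep] % (2**31)
        cv_seed_prior = children[3 * rep + 1] % (2**31)
        cv_seed_all = children[3 * rep + 2] % (2**31)
        rep_spec = ExpressionSimSpec(**{**spec.__dict__, "seed": data_seed})
        data, _, prior = generate_expression(rep_spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aucs_prior, prof_prior = repeated_cv_evaluate(
                data, prior, cfg, R=R, F=F, seed=cv_seed_prior,
                q_cutoff=q_cutoff, B=B, fit_classifier=fit_classifier,
            )
            aucs_all, prof_all = repeated_cv_evaluate(
                data, None, cfg, R=R, F=F, seed=cv_seed_all,
                q_cutoff=q_cutoff, B=B, fit_classifier=fit_classifier,
            )
        rows.append(
            {
                "replicate": rep,
                "constancy_prior": prof_prior.constancy_fraction,
                "constancy_all": prof_all.constancy_fraction,
                "mean_auc_prior": float(np.mean(aucs_prior)) if aucs_prior else np.nan,
                "mean_auc_all": float(np.mean(aucs_all)) if aucs_all else np.nan,
            }
        )
    return pd.DataFrame(rows)


def random_signature_stability(
    data: ExpressionDataset,
    prior: set[str],
    sig_size: int,
    reps: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Overlap of random signature pairs: whole array vs prior set.

    Per repetition and regime, two signatures of ``sig_size`` features
    are drawn uniformly without replacement (from all of the dataset's
    features, or from the ``prior`` feature set only) and their overlap
    is recorded.  Under uniform sampling from a pool of N the expected
    overlap is n^2 / N, so the prior regime's expected overlap is larger
    by the factor (number of features) / |prior|.  Returns a frame with
    columns regime ('whole' | 'prior') and overlap.
    """
    whole = np.asarray(data.feature_ids)
    prior_arr = np.asarray(sorted(set(prior) & set(data.feature_ids)))
    if not sig_size <= prior_arr.size <= whole.size:
        raise ValueError("need sig_size <= |prior| <= number of features")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for regime, pool in (("whole", whole), ("prior", prior_arr)):
        for _ in range(reps):
            a = rng.choice(pool, size=sig_size, replace=False)
            b = rng.choice(pool, size=sig_size, replace=False)
            rows.append(
                {"regime": regime, "overlap": int(np.intersect1d(a, b).size)}
            )
    return pd.DataFrame(rows)
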
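"""Gene-set enrichment tests and the signature-overlap permutation test.

Over-representation is always tested one-sided (upper tail): with a
universe of N genes, a query of n genes and an annotation set of K
genes sharing x members, the hypergeometric p-value is P(X >= x).  The
one-sided Fisher exact test on the equivalent 2x2 table is identical;
both are exposed because both conventions occur in enrichment tooling.

Multiple-testing corrections are Bonferroni (family-wise) and
Benjamini-Yekutieli (FDR under arbitrary dependence, with the harmonic
factor c(m) = sum_{j<=m} 1/j).

The overlap permutation test asks whether a set of signatures shares
more genes than expected by chance: random signatures of the original
sizes are drawn uniformly without replacement from the universe (e.g.
all genes on the chip), and the exceedance count b over m draws yields
the exact permutation p-value (b + 1) / (m + 1), which is never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "OverlapTestResult",
    "hypergeometric_enrichment",
    "fisher_enrichment",
    "bonferroni_adjust",
    "benjamini_yekutieli_adjust",
    "overlap_permutation_test",
    "phipson_smyth_p",
]


@dataclass
class GeneSetCollection:
    """Named annotation gene sets (disease terms, pathways, drug-target
    lists) over a stated universe.  Sets are restricted to the universe;
    the universe defaults to the union of the sets."""

    sets: dict[str, set[str]]
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        if self.universe is None:
            u: set[str] = set()
            for s in self.sets.values():
                u |= s
            self.universe = u
        else:
            self.universe = set(self.universe)
            self.sets = {n: s & self.universe for n, s in self.sets.items()}

    @classmethod
    def from_gmt(cls, path, universe: set[str] | None = None) -> "GeneSetCollection":
        from .io import read_gmt

        return cls(read_gmt(path), universe=universe)


@dataclass
class EnrichmentRecord:
    name: str
    overlap: int          # x
    set_size: int         # K
    query_size: int       # n
    universe_size: int    # N
    p_raw: float
    p_adjusted: float = np.nan


@dataclass
class EnrichmentResult:
    records: list[EnrichmentRecord]
    method: str
    adjustment: str | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "name": r.name,
                    "x": r.overlap,
                    "K": r.set_size,
                    "n": r.query_size,
                    "N": r.universe_size,
                    "p_raw": r.p_raw,
                    "p_adj": r.p_adjusted,
                    "method": self.method,
                }
                for r in self.records
            ]
        )
        return df.sort_values("p_adj" if self.adjustment else "p_raw").reset_index(drop=True)

    def adjust(self, method: str = "bonferroni") -> "EnrichmentResult":
        """Attach adjusted p-values: 'bonferroni' or 'by'."""
        pvals = [r.p_raw for r in self.records]
        if method == "bonferroni":
            adj = bonferroni_adjust(pvals)
        elif method in ("by", "benjamini-yekutieli"):
            adj = benjamini_yekutieli_adjust(pvals)
        else:
            raise ValueError(f"unknown adjustment {method!r}")
        for r, a in zip(self.records, adj):
            r.p_adjusted = a
        self.adjustment = method
        return self


@dataclass
class OverlapTestResult:
    """Permutation test outcome: observed total overlap, exceedance
    count b over m random draws, and the exact p-value (b+1)/(m+1)."""

    observed: int
    m: int
    b: int
    p_value: float
    seed: int | None = None
    statistic: str = "intersection"


def _restrict_query(query: set[str], universe: set[str]) -> set[str]:
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query gene set")
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped",
            stacklevel=3,
        )
    restricted = query & universe
    if not restricted:
        raise ValueError("no query gene lies in the universe")
    return restricted


def hypergeometric_enrichment(
    query: Iterable[str],
    sets: GeneSetCollection | Mapping[str, set[str]],
    universe: Iterable[str] | None = None,
) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation test per gene set.

    p = P(X >= x) with X ~ Hypergeometric(N, K, n).
    """
    if not isinstance(sets, GeneSetCollection):
        sets = GeneSetCollection(
            dict(sets), universe=set(universe) if universe is not None else None
        )
    elif universe is not None:
        sets = GeneSetCollection(dict(sets.sets), universe=set(universe))
    uni = sets.universe
    assert uni is not None
    query = _restrict_query(set(query), uni)
    N, n = len(uni), len(query)
    records = []
    for name, genes in sets.sets.items():
        K = len(genes)
        x = len(query & genes)
        # sf(x-1) = P(X >= x)
        p = float(stats.hypergeom.sf(x - 1, N, K, n))
        records.append(
            EnrichmentRecord(name=name, overlap=x, set_size=K, query_size=n,
                             universe_size=N, p_raw=min(p, 1.0))
        )
    return EnrichmentResult(records=records, method="hypergeometric")


def fisher_enrichment(
    query: Iterable[str],
    targets: Iterable[str],
    universe: Iterable[str],
) -> EnrichmentResult:
    """One-sided (greater) Fisher exact test for over-representation of
    ``targets`` within ``query``, given the universe.

    The 2x2 table crosses membership in the query with membership in the
    target list; the one-sided p equals the hypergeometric upper tail on
    the same margins.
    """
    uni = set(universe)
    query = _restrict_query(set(query), uni)
    targets = set(targets) & uni
    x = len(query & targets)
    table = [
        [x, len(targets - query)],
        [len(query - targets), len(uni - query - targets)],
    ]
    _, p = stats.fisher_exact(table, alternative="greater")
    records = [
        EnrichmentRecord(
            name="targets",
            overlap=x,
            set_size=len(targets),
            query_size=len(query),
            universe_size=len(uni),
            p_raw=float(min(p, 1.0)),
        )
    ]
    return EnrichmentResult(records=records, method="fisher")


def _check_pvals(pvals: Sequence[float]) -> np.ndarray:
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value list")
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return arr


def bonferroni_adjust(pvals: Sequence[float]) -> list[float]:
    """Family-wise correction: min(1, p * m)."""
    arr = _check_pvals(pvals)
    return list(np.minimum(arr * arr.size, 1.0))


def benjamini_yekutieli_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Yekutieli step-up FDR adjustment, valid under arbitrary
    dependence; returned in input order."""
    arr = _check_pvals(pvals)
    _, adj, _, _ = multipletests(arr, method="fdr_by")
    return list(adj)


def phipson_smyth_p(b: int, m: int) -> float:
    """Exact p-value for a randomly drawn permutation test: (b+1)/(m+1).

    b exceedances over m draws; the +1 accounts for the observed
    arrangement itself, so the p-value is never zero.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 <= b <= m:
        raise ValueError(f"exceedance count b={b} outside [0, m={m}]")
    return (b + 1) / (m + 1)


def overlap_permutation_test(
    sigs: Sequence[set[str]],
    universe: Iterable[str],
    m: int = 100_000,
    seed: int | None = None,
    statistic: str = "intersection",
) -> OverlapTestResult:
    """Permutation test for the overlap among a set of gene signatures.

    ``statistic='intersection'`` (default) scores the size of the total
    intersection of all signatures; ``'pairwise'`` scores the mean
    pairwise intersection size.  Each of the ``m`` draws samples
    signatures of the original sizes uniformly without replacement from
    the universe.  Reproducible given ``seed``.
    """
    universe = np.asarray(sorted(set(universe)))
    N = universe.size
    if N == 0:
        raise ValueError("empty universe")
    sizes = [len(s) for s in sigs]
    if len(sizes) < 2:
        raise ValueError("need at least two signatures")
    for s in sizes:
        if s > N:
            raise ValueError(f"signature of size {s} exceeds universe size {N}")
    if m < 1:
        raise ValueError("m must be >= 1")

    def score(sets: Sequence[set]) -> float:
        if statistic == "intersection":
            return float(len(set.intersection(*map(set, sets))))
        if statistic == "pairwise":
            k = len(sets)
            pairs = [
                len(set(sets[i]) & set(sets[j]))
                for i in range(k)
                for j in range(i + 1, k)
            ]
            return float(np.mean(pairs))
        raise ValueError(f"unknown statistic {statistic!r}")

    observed = score(list(sigs))
    rng = np.random.default_rng(seed)
    b = 0
    idx = np.arange(N)
    for _ in range(m):
        draws = []
        for size in sizes:
            take = rng.choice(idx, size=size, replace=False)
            draws.append(set(take.tolist()))
        if score(draws) >= observed:
            b += 1
    return OverlapTestResult(
        observed=int(observed) if statistic == "intersection" else observed,
        m=m,
        b=b,
        p_value=phipson_smyth_p(b, m),
        seed=seed,
        statistic=statistic,
    )
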
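# Methods

## The consensus model

The package assumes that disparate gene signatures for one phenotype
are noisy samples from a common dysregulated neighbourhood of the
protein-interaction network, and that the biologically meaningful
representatives of that neighbourhood are *common upstream regulators*
of signature genes rather than the (unstable) signature genes
themselves.

The interaction network is a partially directed graph: directed edges
encode relations with a known regulatory direction (state changes such
as phosphorylation), undirected edges encode direction-free physical
interaction. Two distance semantics follow:

* **Clustering distance** ignores directions. Genes are grouped by
  complete-linkage agglomerative clustering of undirected hop
  distances, which bounds the network diameter of every cluster by the
  cut height and therefore favours compact groups for which a nearby
  ancestor plausibly exists.
* **Ancestor distance** respects directions: directed edges may only be
  traversed source → target. A *k-common ancestor* of a cluster is a
  node from which every cluster gene is reachable within `k` hops this
  way; the *lowest* common ancestors additionally minimise the average
  such distance, with all ties kept. The set may be empty, and becomes
  empty more often as clusters spread out.

The consensus sweeps the cut height `h` from 1 to the largest finite
pairwise distance among candidate genes; clusters covering at least two
signatures contribute their LCAs, and the majority signature (genes in
strictly more than half of the signatures) is added unconditionally.

### Numerical and tie-break choices

* Unreachable pairs in the distance matrix carry the sentinel value
  `|V|` (the node count), strictly above any finite hop distance, so
  the height sweep — bounded by the largest *finite* distance — can
  never merge genes across connected components.
* Cluster cuts are non-strict (merges at height exactly `h` are
  included): hop distances are integers and the sweep runs over integer
  heights, so a strict cut would skip every merge sitting exactly at
  the cut.
* The height-loop upper bound is the maximum finite entry of the
  candidate distance matrix, not the graph diameter; larger cuts cannot
  change the clustering of candidates.
* A node pair reported both directed and undirected (e.g. by two source
  databases) keeps only the directed edge, which carries strictly more
  information.
* Candidate leaves are sorted lexicographically before clustering, so
  equal-height merge ties resolve deterministically; cluster
  memberships at any cut are invariant to this choice.
* Every node reaches itself at distance 0, so cluster members are
  eligible ancestors of their own cluster; a singleton cluster whose
  gene belongs to two signatures counts as multi-signature (coverage is
  counted over signature memberships, not distinct genes) and
  contributes itself as its own LCA. Both conventions are the
  permissive reading; the stricter alternatives would only shrink the
  consensus.
* The LCA ranking uses the direction-respecting distances (the same
  paths as the reachability definition), not the undirected clustering
  distances.

### Key parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 2 | ancestor path-distance cutoff (hops); beyond two hops an upstream node is unlikely to exert specific regulatory influence |
| `majority_fraction` | 0.5 | strict threshold for the majority signature; a gene in exactly half the signatures never qualifies |

## Enrichment statistics

Over-representation is always the upper tail: `p = P(X ≥ x)` under
`X ~ Hypergeometric(N, K, n)`; the one-sided Fisher exact test on the
same margins is mathematically identical and exposed for interface
parity. Corrections: Bonferroni (`min(1, p·m)`) and Benjamini–Yekutieli
(step-up with the harmonic factor `c(m) = Σ 1/j`, valid under arbitrary
dependence). The universe defaults to the union of the annotation
collection; analyses against array data should pass the chip's gene
universe explicitly.

The signature-overlap permutation test draws, `m` times, random
signatures of the observed sizes uniformly without replacement from the
universe and counts draws whose total intersection reaches the observed
one. The reported p-value is `(b+1)/(m+1)` — the exact p-value for a
randomly drawn permutation null, never zero. `m` defaults to 100,000;
a mean-pairwise-overlap statistic is available for signature sets whose
total intersection is degenerate.

## Biomarker pipeline

The moderated statistic is the two-class unpaired form
`d_i = (x̄₂ − x̄₁) / (s_i + s₀)` with the equal-variance pooled scatter
`s_i = sqrt(a(SS₁+SS₂))`, `a = (1/n₁+1/n₂)/(n₁+n₂−2)`; at `s₀ = 0` it
is exactly the pooled t statistic. The fudge factor `s₀` is chosen from
the percentiles {0, 5, …, 100} of the scatter distribution by
minimising the coefficient of variation of the median absolute `d`
across scatter-percentile windows, which suppresses the inflated
statistics of low-variance features; ties break to the smallest
candidate.

q-values come from label permutations (default `B = 200`, exhaustive
enumeration whenever fewer distinct label arrangements exist, which
also makes small-sample runs seed-independent): the permutation-mean
ordered null statistic defines, for each threshold Δ, asymmetric
cut-points and a called set; the estimated FDR at Δ is the median
per-permutation null exceedance count scaled by the null-proportion
estimate π̂₀ (from the fraction of observed `d` inside the null
interquartile range), divided by the called count; a feature's q-value
is the smallest FDR at which it is called, made monotone non-increasing
in `|d|`.

Classification uses a linear-kernel SVM with cost `C` tuned over
{10⁻⁴ … 10²} by stratified inner 5-fold cross-validation maximising
AUC (accuracy optional); ties prefer the smallest cost, i.e. the widest
margin. Outer evaluation is `R×F` repeated, class-stratified
cross-validation — stratification is a deliberate choice to keep both
classes in every fold at the sample sizes typical here; all fold
assignments and permutations derive from one root seed. Feature
selection runs strictly inside each training fold; the held-out fold
cannot influence it, which the test suite asserts by scrambling
held-out labels. AUC is the rank-based (Mann–Whitney) form with ties
counted one half. Per-feature selection counts across all `R·F` runs
form the stability profile; the *constancy fraction* is the share of
ever-selected features selected in every run, and the per-count
histogram uses ever-selected features as its denominator. Paired AUC
lists are compared by the two-sided Wilcoxon signed-rank test with zero
differences dropped.

## Synthetic data: what it emulates and what it does not

`generate_planted_network` builds a directed Erdős–Rényi background
graph (a stated fraction of edges converted to undirected) plus hub
nodes wired hub → target; each hub's targets are assigned to signatures
round-robin with a per-hub offset, so different hubs cover different
signature subsets and a hub only becomes recoverable once at least two
of its covered signatures are sampled. This captures the one structural
feature the consensus algorithm is designed to exploit — shared
upstream regulators of genes scattered across signatures — but not
realistic interactome topology (no scale-free degree distribution, no
modularity), so passing tests demonstrate algorithmic correctness and
qualitative behaviour, not performance on real interactomes.

`generate_expression` produces unit-variance Gaussian features with a
mean shift (in SD units) applied to a designated differential set in
class 2, optionally confined to a prior feature set. It omits probe-
level noise, correlation between features, and batch structure; it is
the cleanest setting in which prior-restricted selection should show a
stability advantage, and results on it bound from above what real
arrays would show.

## Problem sizes used by the validation experiments

Chosen once as realistic desk-scale study conditions:

* Ancestor-search oracle: 200 random mixed-edge graphs of 5–40 nodes,
  `k ∈ {1,2,3}`, compared exactly against Floyd–Warshall-based
  exhaustive enumeration.
* Permutation-test calibration: 3 null signatures of 20 genes from a
  10,000-gene universe, `m = 999`, 500 replicate tests.
* Moderated-statistic calibration: 500 features, 10 vs 10 samples,
  20 seeds (null); 50 of 500 features shifted 3 SD (recall).
* Stability comparison: 5,000 features, 100-feature prior, 50
  differential features at 1.0 SD, 15 samples per class, 5×5-fold CV,
  `B = 100` permutations, 50 replicates. Classifier fitting is skipped
  here because selection counts do not depend on it.
* Subsampling trend: 12 hubs × 2 targets over 6 signatures with 200
  background nodes at edge probability 0.005; with 2 targets per hub a
  hub is recovered only when both of its signatures are drawn
  (probability `s(s−1)/30` at subset size `s`), so hub capture — and
  with it the enrichment of hubs in the consensus — grows over the
  whole 2…6 range instead of saturating early.

## Known limitations

* Hop counts ignore interaction confidence; a weighted variant is out
  of scope.
* The q-value estimator's median-based false-call count is conservative
  on pure-null data (empirical false-call fractions near zero rather
  than near the nominal 5 %).
* The overlap permutation test's total-intersection statistic is blunt
  for many signatures with pairwise-only sharing; the pairwise mode is
  a summary, not an inferential fix.
* Identifier spaces are opaque strings: no ID conversion is performed,
  and unmapped genes are reported, never dropped silently.
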
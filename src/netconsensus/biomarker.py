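"""Differential-expression-driven biomarker selection with stability
profiling.

The pipeline mirrors common practice in prognostic signature building
from two-group expression matrices:

* a moderated difference statistic per feature (probeset),
  d_i = (mean2 - mean1) / (s_i + s0), where s_i is the pooled standard
  error and the "fudge factor" s0 damps the inflated statistics of
  low-variance features;
* permutation-based q-values: label permutations give the null
  distribution of ordered statistics, a sliding threshold Delta defines
  called sets, and the estimated FDR at each Delta (median null
  exceedance count, scaled by the null-proportion estimate pi0) is
  converted into per-feature q-values;
* feature selection restricted to a prior gene set (for instance a
  network consensus signature), keeping features with q below a cutoff;
* a linear support-vector machine with cost C tuned on an inner
  cross-validation grid, scored by AUC;
* repeated, class-stratified outer cross-validation in which selection
  happens inside each training fold only, accumulating per-feature
  selection counts into a stability profile.

The *constancy fraction* — among features ever selected, the share
selected in every one of the R x F runs — quantifies selection
stability; restricting selection to a sound prior raises it markedly.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ExpressionDataset",
    "SamResult",
    "SvmConfig",
    "StabilityProfile",
    "sam_statistic",
    "choose_s0",
    "sam_qvalues",
    "select_features",
    "train_classifier",
    "repeated_cv_evaluate",
    "auc",
    "compare_auc_paired",
]

DEFAULT_COST_GRID: tuple[float, ...] = tuple(10.0 ** e for e in range(-4, 3))


@dataclass
class ExpressionDataset:
    """Expression matrix (features x samples) with binary labels.

    ``feature_to_gene`` maps probeset IDs to gene IDs (many-to-one
    allowed); when absent, feature IDs double as gene IDs.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    feature_to_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match feature/sample IDs")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature IDs must be unique")
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("one label per sample required")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present")

    def gene_of(self, feature: str) -> str:
        if self.feature_to_gene is None:
            return feature
        return self.feature_to_gene.get(feature, feature)

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionDataset":
        idx = list(idx)
        return ExpressionDataset(
            values=self.values[:, idx],
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
            feature_to_gene=self.feature_to_gene,
        )

    def subset_features(self, features: Sequence[str]) -> "ExpressionDataset":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        keep = [pos[f] for f in features]
        return ExpressionDataset(
            values=self.values[keep, :],
            feature_ids=list(features),
            sample_ids=list(self.sample_ids),
            labels=self.labels,
            feature_to_gene=self.feature_to_gene,
        )


@dataclass
class SamResult:
    """Per-feature moderated statistics and q-values from one run."""

    feature_ids: list[str]
    d: np.ndarray
    s: np.ndarray
    s0: float
    q: np.ndarray
    pi0: float
    n_permutations: int
    seed: int | None

    def significant(self, q_cutoff: float = 0.05) -> list[str]:
        return [f for f, qv in zip(self.feature_ids, self.q) if qv < q_cutoff]


@dataclass(frozen=True)
class SvmConfig:
    """Linear-SVM training configuration: cost grid tuned by inner
    cross-validation (AUC by default; accuracy optional)."""

    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    inner_folds: int = 5
    tuning_metric: str = "auc"

    def __post_init__(self) -> None:
        if not self.cost_grid or any(c <= 0 for c in self.cost_grid):
            raise ValueError("cost grid must be non-empty and positive")
        if self.tuning_metric not in ("auc", "accuracy"):
            raise ValueError("tuning_metric must be 'auc' or 'accuracy'")


@dataclass
class StabilityProfile:
    """Selection counts per feature over R x F cross-validation runs."""

    counts: dict[str, int]
    total_runs: int

    def ever_selected(self) -> list[str]:
        return [f for f, c in self.counts.items() if c > 0]

    @property
    def constancy_fraction(self) -> float:
        """Among ever-selected features, the fraction selected in every
        run; 0.0 when nothing was ever selected."""
        ever = [c for c in self.counts.values() if c > 0]
        if not ever:
            return 0.0
        return sum(c == self.total_runs for c in ever) / len(ever)

    def histogram(self) -> dict[int, float]:
        """Fraction of ever-selected features per selection count."""
        ever = [c for c in self.counts.values() if c > 0]
        if not ever:
            return {}
        return {
            c: sum(v == c for v in ever) / len(ever)
            for c in sorted(set(ever))
        }


def _group_moments(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (mean2 - mean1, pooled scatter s) for binary labels."""
    mask1, mask2 = y == 0, y == 1
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two samples per class")
    m1 = X[:, mask1].mean(axis=1)
    m2 = X[:, mask2].mean(axis=1)
    ss1 = ((X[:, mask1] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((X[:, mask2] - m2[:, None]) ** 2).sum(axis=1)
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    s = np.sqrt(a * (ss1 + ss2))
    return m2 - m1, s


def sam_statistic(data: ExpressionDataset, s0: float = 0.0) -> np.ndarray:
    """Moderated two-class difference statistic per feature.

    d_i = (mean2 - mean1) / (s_i + s0) with the equal-variance pooled
    scatter s_i = sqrt(a (SS1 + SS2)), a = (1/n1 + 1/n2)/(n1 + n2 - 2).
    At s0 = 0 this is exactly the pooled two-sample t statistic.
    """
    r, s = _group_moments(data.values, data.labels)
    if s0 == 0.0 and np.any(s == 0):
        bad = [data.feature_ids[i] for i in np.flatnonzero(s == 0)[:5]]
        raise ValueError(
            f"zero within-class variance with s0=0 makes d undefined for "
            f"features {bad}; use a positive s0"
        )
    return r / (s + s0)


def choose_s0(r: np.ndarray, s: np.ndarray, n_windows: int = 100) -> float:
    """Select the fudge factor s0 from the scatter distribution.

    Candidates are the percentiles {0, 5, ..., 100} of {s_i}.  For each
    candidate the features are binned into windows by s-percentile and
    the median absolute moderated statistic is computed per window; the
    candidate minimizing the coefficient of variation of those window
    medians wins, ties going to the smallest candidate.  This penalizes
    s0 values that leave |d| systematically inflated in low-scatter
    windows.
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if r.size < 2:
        warnings.warn("fewer than 2 features; defaulting s0 to 0")
        return 0.0
    candidates = np.percentile(s, np.arange(0, 101, 5))
    candidates = np.unique(candidates)
    n_windows = max(2, min(n_windows, r.size // 2))
    edges = np.percentile(s, np.linspace(0, 100, n_windows + 1))
    bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_windows - 1)
    best_cv, best_s0 = np.inf, float(candidates[0])
    for cand in candidates:
        d = r / (s + cand)
        meds = np.array([
            np.median(np.abs(d[bins == w]))
            for w in range(n_windows)
            if np.any(bins == w)
        ])
        mean = meds.mean()
        cv = np.inf if mean == 0 else meds.std() / mean
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(cand)
    return best_s0


def _null_statistics(
    X: np.ndarray, y: np.ndarray, B: int, s0: float, rng: np.random.Generator
) -> np.ndarray:
    """Null d matrix (features x permutations) from label permutations.

    When the number of distinct label arrangements with the observed
    class sizes is <= B, all of them are enumerated instead of sampled.
    """
    n = y.size
    n2 = int((y == 1).sum())
    n1 = n - n2
    n_arrangements = math.comb(n, n2)
    if n_arrangements <= B:
        combos = itertools.combinations(range(n), n2)
        Y = np.zeros((n, n_arrangements))
        for j, combo in enumerate(combos):
            Y[list(combo), j] = 1.0
    else:
        Y = np.zeros((n, B))
        for j in range(B):
            Y[rng.permutation(n)[:n2], j] = 1.0
    # vectorized group moments across all permutation columns
    S1 = X @ Y                       # per-perm class-2 sums
    Stot = X.sum(axis=1, keepdims=True)
    M2 = S1 / n2
    M1 = (Stot - S1) / n1
    Xsq = X**2
    Q2 = Xsq @ Y
    Qtot = Xsq.sum(axis=1, keepdims=True)
    SS2 = Q2 - n2 * M2**2
    SS1 = (Qtot - Q2) - n1 * M1**2
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    S = np.sqrt(np.clip(a * (SS1 + SS2), 0.0, None))
    return (M2 - M1) / (S + s0)


def sam_qvalues(
    data: ExpressionDataset,
    B: int = 200,
    seed: int | None = None,
    s0: float | None = None,
    n_delta: int = 300,
) -> SamResult:
    """Permutation-based q-values for the moderated statistic.

    For each threshold Delta, the called set consists of features whose
    ordered statistic deviates from the permutation-average ordered null
    statistic by at least Delta; asymmetric cut-points (smallest called
    d above, largest called d below) translate the call into the null
    matrix, whose median per-permutation exceedance count, scaled by the
    null-proportion estimate pi0, gives the estimated FDR.  Each
    feature's q-value is the smallest FDR at which it is called, made
    monotone in |d|.  Reproducible given ``seed``; exhaustive label
    enumeration replaces sampling when fewer than B distinct
    arrangements exist.
    """
    if B < 50:
        raise ValueError("B must be >= 50 for a usable null")
    rng = np.random.default_rng(seed)
    X, y = data.values, data.labels
    r, s = _group_moments(X, y)
    if s0 is None:
        s0 = choose_s0(r, s)
    if s0 == 0.0 and np.any(s == 0):
        s0 = float(np.percentile(s[s > 0], 5)) if np.any(s > 0) else 1.0
    d = r / (s + s0)
    null = _null_statistics(X, y, B, s0, rng)
    B_eff = null.shape[1]

    order = np.argsort(d)
    d_sorted = d[order]
    null_sorted_rows = np.sort(null, axis=0)          # order stats per perm
    dbar = null_sorted_rows.mean(axis=1)              # expected order stats

    # pi0 from the proportion of observed d inside the null interquartile range
    q25, q75 = np.percentile(null, [25, 75])
    pi0 = min(1.0, np.mean((d > q25) & (d < q75)) / 0.5) if q75 > q25 else 1.0

    dev = d_sorted - dbar
    deltas = np.unique(np.abs(dev))
    deltas = deltas[deltas > 0]
    if deltas.size > n_delta:
        deltas = np.quantile(deltas, np.linspace(0, 1, n_delta))

    n_feat = d.size
    # cut-points per Delta
    cutup = np.full(deltas.size, np.inf)
    cutlow = np.full(deltas.size, -np.inf)
    for j, delta in enumerate(deltas):
        up = d_sorted[dev >= delta]
        if up.size:
            cutup[j] = up.min()
        low = d_sorted[-dev >= delta]
        if low.size:
            cutlow[j] = low.max()

    # called counts among observed features (sorted d -> searchsorted)
    called_up = n_feat - np.searchsorted(d_sorted, cutup, side="left")
    called_low = np.searchsorted(d_sorted, cutlow, side="right")
    n_called = called_up + called_low

    # median per-permutation null exceedance count, via sorted columns
    false_counts = np.empty((B_eff, deltas.size))
    for bcol in range(B_eff):
        col = null_sorted_rows[:, bcol]
        false_counts[bcol] = (
            n_feat - np.searchsorted(col, cutup, side="left")
        ) + np.searchsorted(col, cutlow, side="right")
    median_false = np.median(false_counts, axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_called > 0, np.minimum(1.0, median_false * pi0 / n_called), 1.0)

    # per-feature q: smallest FDR over the Deltas at which it is called
    called_matrix = (d[:, None] >= cutup[None, :]) | (d[:, None] <= cutlow[None, :])
    q = np.where(called_matrix, fdr[None, :], np.inf).min(axis=1)
    q = np.where(np.isfinite(q), q, 1.0)

    # enforce monotone non-increase of q in |d|
    rank = np.argsort(-np.abs(d))
    q_sorted = np.maximum.accumulate(q[rank])
    q_final = np.empty_like(q)
    q_final[rank] = q_sorted

    return SamResult(
        feature_ids=list(data.feature_ids),
        d=d,
        s=s,
        s0=float(s0),
        q=q_final,
        pi0=float(pi0),
        n_permutations=B_eff,
        seed=seed,
    )


def select_features(
    data: ExpressionDataset,
    prior: set[str] | None,
    q_cutoff: float = 0.05,
    B: int = 200,
    seed: int | None = None,
    s0: float | None = None,
) -> list[str]:
    """Differentially expressed features at q < cutoff, restricted to a
    prior gene set when one is given.

    The prior is a set of gene IDs; features inherit membership through
    the probeset-to-gene mapping.  ``prior=None`` (or empty) uses every
    feature.  Returns the selected feature IDs (possibly empty).
    """
    if not 0.0 < q_cutoff < 1.0:
        raise ValueError("q_cutoff must lie in (0, 1)")
    if prior:
        keep = [f for f in data.feature_ids if data.gene_of(f) in prior]
        if not keep:
            raise ValueError(
                "no feature maps to the prior gene set; check the "
                "feature-to-gene mapping and identifier space"
            )
        data = data.subset_features(keep)
    result = sam_qvalues(data, B=B, seed=seed, s0=s0)
    selected = result.significant(q_cutoff)
    if not selected:
        warnings.warn(f"no feature passed q < {q_cutoff}")
    return selected


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve in its rank (Mann-Whitney) form: the
    probability a random positive outscores a random negative, ties
    counting one half.  Invariant under monotone score transforms."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def train_classifier(
    data: ExpressionDataset,
    cfg: SvmConfig = SvmConfig(),
    seed: int | None = None,
) -> SVC:
    """Linear-kernel SVM with cost C tuned by inner stratified CV.

    The grid winner maximizes the tuning metric (AUC by default); ties
    break to the smallest C, i.e. the widest margin.  With a singleton
    grid no tuning is performed.  Returns the fitted classifier; its
    ``decision_function`` is the real-valued score.
    """
    X = data.values.T  # samples x features for sklearn
    y = data.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least two samples per class to train")
    if X.shape[1] < 1:
        raise ValueError("no features to train on")
    grid = cfg.cost_grid
    if len(grid) == 1:
        best_c = grid[0]
    else:
        folds = min(cfg.inner_folds, int(counts.min()))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=_as_state(seed))
        scores = []
        splits = list(skf.split(X, y))
        for c in grid:
            fold_scores = []
            for tr, te in splits:
                clf = SVC(kernel="linear", C=c)
                clf.fit(X[tr], y[tr])
                if len(np.unique(y[te])) < 2:
                    continue
                if cfg.tuning_metric == "auc":
                    fold_scores.append(auc(clf.decision_function(X[te]), y[te]))
                else:
                    fold_scores.append(float(np.mean(clf.predict(X[te]) == y[te])))
            scores.append(np.mean(fold_scores) if fold_scores else 0.5)
        best_c = grid[int(np.argmax(scores))]  # argmax: first (smallest C) wins ties
    clf = SVC(kernel="linear", C=best_c)
    clf.fit(X, y)
    return clf


def _as_state(seed: int | None) -> int | None:
    if seed is None:
        return None
    return int(seed) % (2**31 - 1)


def repeated_cv_evaluate(
    data: ExpressionDataset,
    prior: set[str] | None,
    cfg: SvmConfig = SvmConfig(),
    R: int = 10,
    F: int = 10,
    seed: int | None = None,
    q_cutoff: float = 0.05,
    B: int = 200,
    fit_classifier: bool = True,
) -> tuple[list[float], StabilityProfile]:
    """R-times-repeated, F-fold, class-stratified cross-validation.

    Within each outer training fold, feature selection (moderated
    statistic at q < cutoff, restricted to the prior) runs on training
    samples only — the test fold never influences selection — then an
    SVM is tuned and fit on the selected features and scored on the held
    -out fold by AUC.  Selection counts over all R x F folds form the
    stability profile.  Folds in which no feature is selected contribute
    no AUC.  ``fit_classifier=False`` profiles selection stability only.
    """
    if R < 1 or F < 2:
        raise ValueError("need R >= 1 repeats and F >= 2 folds")
    counts = np.bincount(data.labels, minlength=2)
    if counts.min() < F:
        raise ValueError(
            f"cannot stratify {F} folds with minority class of {counts.min()}"
        )
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    child_seeds = ss.generate_state(R * F * 2 + R).tolist()
    aucs: list[float] = []
    sel_counts: dict[str, int] = {f: 0 for f in data.feature_ids}
    run = 0
    for rep in range(R):
        skf = StratifiedKFold(
            n_splits=F, shuffle=True, random_state=_as_state(child_seeds[rep])
        )
        X = data.values.T
        for tr, te in skf.split(X, data.labels):
            train = data.subset_samples(tr)
            sam_seed = child_seeds[R + 2 * run] % (2**31)
            svm_seed = child_seeds[R + 2 * run + 1] % (2**31)
            run += 1
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                selected = select_features(
                    train, prior, q_cutoff=q_cutoff, B=B, seed=sam_seed
                )
            for f in selected:
                sel_counts[f] += 1
            if not selected or not fit_classifier:
                continue
            clf = train_classifier(train.subset_features(selected), cfg, seed=svm_seed)
            test = data.subset_samples(te).subset_features(selected)
            if len(np.unique(test.labels)) < 2:
                continue
            aucs.append(auc(clf.decision_function(test.values.T), test.labels))
    profile = StabilityProfile(counts=sel_counts, total_runs=R * F)
    return aucs, profile


def compare_auc_paired(aucs_a: Sequence[float], aucs_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-run AUCs.

    Zero differences are dropped; if every difference is zero the test
    has no resolution and p = 1 is returned with a warning.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("AUC lists must be paired (equal length)")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        warnings.warn("all paired AUC differences are zero; p = 1")
        return 1.0
    if nonzero.size < 2:
        return 1.0
    _, p = stats.wilcoxon(nonzero, alternative="two-sided", method="auto")
    return float(p)
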
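"""Data-driven selection of the number of clusters.

Three methods are implemented, all comparing the observed clustering against
reference datasets drawn from a single-cluster null (a uniform box aligned
with the principal components of the data): the gap statistic, the weighted
gap statistic (within-cluster dispersion normalised by ``n_r - 1``), and
Clest (cross-partition classification error on observed versus reference
splits).  A consensus helper reports the modal choice across methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .spkmeans import ClusterSolution, SparseKMeansConfig, assign_to_centers, sparse_kmeans

__all__ = [
    "GapCurve",
    "ClestReport",
    "reference_sample",
    "gap_statistic",
    "gap_curves",
    "choose_k_one_se",
    "clest",
    "select_k_consensus",
    "make_sparse_clusterer",
]

Clusterer = Callable[[np.ndarray, int, np.random.Generator], ClusterSolution]


@dataclass
class GapCurve:
    """Gap values and reference standard errors over a contiguous k range."""

    k_values: list
    gap: np.ndarray
    se: np.ndarray
    weighted: bool = False
    chosen_k: int | None = None


@dataclass
class ClestReport:
    """Observed vs reference classification error rates per k."""

    k_values: list
    t_obs: dict = field(default_factory=dict)
    t_ref: dict = field(default_factory=dict)  # k -> array of reference medians
    d: dict = field(default_factory=dict)
    p: dict = field(default_factory=dict)
    chosen_k: int | None = None


def make_sparse_clusterer(
    l: float | None = None, n_start: int = 20, max_iter: int = 10
) -> Clusterer:
    """Factory for the analysis clusterer used throughout k selection."""

    def clusterer(X: np.ndarray, k: int, rng: np.random.Generator) -> ClusterSolution:
        cfg = SparseKMeansConfig(k=k, l=l, n_start=n_start, max_iter=max_iter, seed=rng)
        return sparse_kmeans(X, cfg)

    return clusterer


def reference_sample(matrix: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one reference dataset from the PCA-aligned uniform box.

    Columns are centered, rotated onto the right singular vectors, drawn
    uniformly over each rotated coordinate's observed range, back-rotated and
    re-centered.  Zero-range coordinates come out constant.  Requires a
    complete matrix.
    """
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("reference_sample requires a complete matrix")
    mu = X.mean(axis=0)
    Xc = X - mu
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Z = Xc @ Vt.T
    lo, hi = Z.min(axis=0), Z.max(axis=0)
    Zstar = rng.uniform(lo, hi, size=Z.shape)
    return Zstar @ Vt + mu


def _pooled_dispersions(
    X: np.ndarray, solution: ClusterSolution
) -> tuple[float, float]:
    """(W_k, Wbar_k): weighted within-cluster dispersion, plain and size-normalised.

    ``W_k = sum_r D_r / (2 n_r)`` equals the weighted within-cluster sum of
    squared distances to centroids; the weighted-gap variant divides each
    cluster's term additionally by ``n_r - 1``.  Both are normalised by the
    weight total ``sum_j w_j`` so dispersions stay comparable across solutions
    whose weight vectors concentrate differently (the L2-normalised weights of
    sparse k-means leave the dissimilarity scale otherwise arbitrary).
    """
    X = np.asarray(X, dtype=float)
    mask = np.isfinite(X)
    X0 = np.where(mask, X, 0.0)
    p = X.shape[1]
    scale = p / np.maximum(mask.sum(axis=1), 1)
    sw = np.sqrt(solution.weights)
    W = 0.0
    Wbar = 0.0
    for c in range(solution.k):
        rows = solution.labels == c
        n_r = int(rows.sum())
        if n_r == 0:
            continue
        sub = X0[rows] * sw
        m = mask[rows]
        cnt = m.sum(axis=0)
        mu = np.where(cnt > 0, sub.sum(axis=0) / np.maximum(cnt, 1), 0.0)
        d2 = (((sub - mu) ** 2) * m).sum(axis=1) * scale[rows]
        W += d2.sum()
        if n_r > 1:
            Wbar += d2.sum() / (n_r - 1)
    wsum = float(solution.weights.sum())
    if wsum > 0:
        W /= wsum
        Wbar /= wsum
    return W, Wbar


def gap_curves(
    matrix: np.ndarray,
    k_range: Sequence[int],
    B_ref: int,
    clusterer: Clusterer,
    seed: int | np.random.Generator | None = None,
) -> tuple[GapCurve, GapCurve]:
    """Plain and weighted gap curves from a shared set of reference datasets."""
    if B_ref < 2:
        raise ValueError("B_ref must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(matrix, dtype=float)
    complete = ~np.isnan(X).any(axis=1)
    Xc = X[complete]
    k_values = list(k_range)
    n = X.shape[0]

    logW_obs = np.empty(len(k_values))
    logWbar_obs = np.empty(len(k_values))
    for i, k in enumerate(k_values):
        if k >= n:
            raise ValueError("k must be smaller than the number of rows")
        sol = clusterer(X, k, rng)
        W, Wbar = _pooled_dispersions(X, sol)
        if W <= 0 or Wbar <= 0:
            raise ValueError(f"degenerate dispersion at k={k}")
        logW_obs[i] = np.log(W)
        logWbar_obs[i] = np.log(Wbar)

    logW_ref = np.empty((B_ref, len(k_values)))
    logWbar_ref = np.empty((B_ref, len(k_values)))
    for b in range(B_ref):
        R = reference_sample(Xc, rng)
        for i, k in enumerate(k_values):
            sol = clusterer(R, k, rng)
            W, Wbar = _pooled_dispersions(R, sol)
            logW_ref[b, i] = np.log(max(W, 1e-300))
            logWbar_ref[b, i] = np.log(max(Wbar, 1e-300))

    infl = np.sqrt(1.0 + 1.0 / B_ref)
    gap = GapCurve(
        k_values=k_values,
        gap=logW_ref.mean(axis=0) - logW_obs,
        se=logW_ref.std(axis=0, ddof=1) * infl,
        weighted=False,
    )
    wgap = GapCurve(
        k_values=k_values,
        gap=logWbar_ref.mean(axis=0) - logWbar_obs,
        se=logWbar_ref.std(axis=0, ddof=1) * infl,
        weighted=True,
    )
    gap.chosen_k = choose_k_one_se(gap)
    wgap.chosen_k = choose_k_one_se(wgap)
    return gap, wgap


def gap_statistic(
    matrix: np.ndarray,
    k_range: Sequence[int],
    B_ref: int,
    clusterer: Clusterer,
    weighted: bool = False,
    seed: int | np.random.Generator | None = None,
) -> GapCurve:
    gap, wgap = gap_curves(matrix, k_range, B_ref, clusterer, seed=seed)
    return wgap if weighted else gap


def choose_k_one_se(curve: GapCurve) -> int | None:
    """Smallest k with ``gap(k) > gap(k+1) - se(k+1)``; None if no k qualifies."""
    ks = list(curve.k_values)
    for i in range(len(ks) - 1):
        if ks[i + 1] != ks[i] + 1:
            raise ValueError("k range must be contiguous")
        if curve.gap[i] > curve.gap[i + 1] - curve.se[i + 1]:
            return ks[i]
    return None


def classification_error_rate(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Misassignment fraction under Hungarian-optimal cluster matching."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    ua, ub = np.unique(a), np.unique(b)
    C = np.zeros((ua.size, ub.size))
    for i, g in enumerate(ua):
        for j, h in enumerate(ub):
            C[i, j] = np.sum((a == g) & (b == h))
    r, c = linear_sum_assignment(-C)
    return 1.0 - C[r, c].sum() / a.size


def _split_error(
    X: np.ndarray,
    k: int,
    clusterer: Clusterer,
    train_fraction: float,
    rng: np.random.Generator,
    max_redraw: int = 20,
) -> float:
    n = X.shape[0]
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, k + 1), n - k - 1)
    for _ in range(max_redraw):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        try:
            learn = clusterer(X[train], k, rng)
            test_sol = clusterer(X[test], k, rng)
        except ValueError:
            continue
        if np.unique(learn.labels).size < k or np.unique(test_sol.labels).size < k:
            continue
        predicted = assign_to_centers(X[test], learn.centers, learn.weights)
        return classification_error_rate(predicted, test_sol.labels)
    raise RuntimeError("could not draw a split without empty clusters")


def clest(
    matrix: np.ndarray,
    k_range: Sequence[int],
    clusterer: Clusterer,
    B_obs: int = 200,
    B_ref: int = 100,
    B_ref_splits: int = 100,
    train_fraction: float = 2.0 / 3.0,
    seed: int | np.random.Generator | None = None,
) -> ClestReport:
    """Clest: observed vs reference cross-partition classification error.

    Per split the learning set is clustered, the test set classified to the
    nearest weighted learning center and independently clustered, and the two
    test partitions compared by optimally matched classification error.
    ``t_k`` is the median error over ``B_obs`` observed splits; the same
    statistic on each reference dataset yields the adjusted statistic
    ``d_k = (mean(t0) - t_k) / sd(t0)`` and ``p_k = #{t0 <= t_k} / B_ref``.
    The chosen k maximises ``d_k`` among ``{k : p_k < 0.05, d_k > 0}``.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(matrix, dtype=float)
    complete = ~np.isnan(X).any(axis=1)
    Xc = X[complete]
    report = ClestReport(k_values=list(k_range))

    for k in report.k_values:
        errs = np.array(
            [_split_error(X, k, clusterer, train_fraction, rng) for _ in range(B_obs)]
        )
        report.t_obs[k] = float(np.median(errs))

    for k in report.k_values:
        t0 = np.empty(B_ref)
        for b in range(B_ref):
            R = reference_sample(Xc, rng)
            errs = np.array(
                [
                    _split_error(R, k, clusterer, train_fraction, rng)
                    for _ in range(B_ref_splits)
                ]
            )
            t0[b] = np.median(errs)
        report.t_ref[k] = t0
        sd = t0.std(ddof=1)
        diff = t0.mean() - report.t_obs[k]
        if sd > 0:
            report.d[k] = float(diff / sd)
        else:
            report.d[k] = float(np.inf if diff > 0 else -np.inf)
        report.p[k] = float(np.mean(t0 <= report.t_obs[k]))

    eligible = [k for k in report.k_values if report.p[k] < 0.05 and report.d[k] > 0]
    if eligible:
        report.chosen_k = max(eligible, key=lambda k: report.d[k])
    return report


def select_k_consensus(
    gap: GapCurve, wgap: GapCurve, clest_report: ClestReport
) -> dict:
    """Modal choice across the three methods; ties are reported, not resolved."""
    if not (list(gap.k_values) == list(wgap.k_values) == list(clest_report.k_values)):
        raise ValueError("method reports cover different k ranges")
    votes = {
        "gap": gap.chosen_k,
        "weighted_gap": wgap.chosen_k,
        "clest": clest_report.chosen_k,
    }
    valid = [v for v in votes.values() if v is not None]
    counts: dict[int, int] = {}
    for v in valid:
        counts[v] = counts.get(v, 0) + 1
    if not counts:
        return {"chosen_k": None, "votes": votes, "consensus": "none"}
    top = max(counts.values())
    winners = [k for k, c in counts.items() if c == top]
    if len(winners) > 1 or top < 2:
        return {"chosen_k": None, "votes": votes, "consensus": "disagreement"}
    label = "unanimous" if top == 3 else "2-of-3"
    return {"chosen_k": winners[0], "votes": votes, "consensus": label}
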
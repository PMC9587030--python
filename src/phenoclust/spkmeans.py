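"""Sparse k-means clustering with lasso-type feature weighting.

The algorithm alternates two steps: (i) weighted k-means on the feature-rescaled
data and (ii) an L1/L2-constrained update of the non-negative feature weights
``w`` that maximises the weighted between-cluster sum of squares
``sum_j w_j * BCSS_j`` subject to ``||w||_2 = 1`` and ``||w||_1 <= l``.
Missing cells are tolerated: squared distances are computed over mutually
observed coordinates and rescaled by ``p / n_observed`` so that rows with
block-missing task data remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SparseKMeansConfig",
    "ClusterSolution",
    "per_feature_bcss",
    "update_weights",
    "sparse_kmeans",
    "tune_sparsity",
    "assign_to_centers",
]


@dataclass
class SparseKMeansConfig:
    """Configuration of one sparse k-means run.

    Parameters
    ----------
    k : int
        Number of clusters.
    l : float or None
        L1 bound on the weight vector, in ``(1, sqrt(p)]``.  ``None`` means the
        non-binding value ``sqrt(p)`` (no sparsity constraint).
    alpha : float
        Trimming proportion of the robust variant.  Only ``0`` is supported:
        with no trimming the algorithm is plain sparse k-means.
    n_start : int
        Number of random center initialisations evaluated at each k-means step.
    max_iter : int
        Cap on weight/partition alternations.
    tol : float
        Relative L1 change in ``w`` below which the alternation stops.
    seed : int or numpy Generator, optional
        Source of randomness; an int seeds a fresh ``default_rng``.
    """

    k: int
    l: float | None = None
    alpha: float = 0.0
    n_start: int = 1000
    max_iter: int = 20
    tol: float = 1e-4
    seed: int | np.random.Generator | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.alpha != 0.0:
            raise ValueError("trimming is not supported; alpha must be 0")
        if self.n_start < 1:
            raise ValueError("n_start must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    def resolve_l(self, p: int) -> float:
        l = float(np.sqrt(p)) if self.l is None else float(self.l)
        if not (1.0 < l <= np.sqrt(p) + 1e-9):
            raise ValueError(f"l must lie in (1, sqrt(p)] = (1, {np.sqrt(p):.4f}]")
        return l

    def rng(self) -> np.random.Generator:
        if isinstance(self.seed, np.random.Generator):
            return self.seed
        return np.random.default_rng(self.seed)


@dataclass
class ClusterSolution:
    """Result of a sparse k-means run."""

    labels: np.ndarray
    weights: np.ndarray
    centers: np.ndarray
    objective: float
    k: int
    l: float
    alpha: float = 0.0
    n_iter: int = 0
    converged: bool = False
    objective_trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels.tolist(),
            "weights": self.weights.tolist(),
            "centers": self.centers.tolist(),
            "objective": self.objective,
            "k": self.k,
            "l": self.l,
            "alpha": self.alpha,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# building blocks


def _as_masked(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (X with NaN replaced by 0, boolean observed mask)."""
    X = np.asarray(X, dtype=float)
    mask = np.isfinite(X)
    X0 = np.where(mask, X, 0.0)
    return X0, mask


def per_feature_bcss(X: np.ndarray, labels: Sequence[int]) -> np.ndarray:
    """Per-feature between-cluster sum of squares.

    ``BCSS_j = totalSS_j - withinSS_j`` computed over the non-missing entries
    of column ``j``.  Requires at least two non-empty clusters.
    """
    X0, mask = _as_masked(X)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("per_feature_bcss requires at least two clusters")
    n_obs = mask.sum(axis=0)
    col_mean = np.where(n_obs > 0, X0.sum(axis=0) / np.maximum(n_obs, 1), 0.0)
    total = ((X0 - col_mean) ** 2 * mask).sum(axis=0)
    within = np.zeros_like(total)
    for g in uniq:
        rows = labels == g
        m = mask[rows]
        cnt = m.sum(axis=0)
        s = X0[rows].sum(axis=0)
        mu = np.where(cnt > 0, s / np.maximum(cnt, 1), 0.0)
        within += ((X0[rows] - mu) ** 2 * m).sum(axis=0)
    bcss = total - within
    # numerical floor: BCSS is non-negative up to round-off
    return np.maximum(bcss, 0.0)


def update_weights(a: np.ndarray, l: float, tol: float = 1e-8) -> np.ndarray:
    """Solve ``max_w <w, a>`` s.t. ``||w||_2 <= 1, ||w||_1 <= l, w >= 0``.

    The solution is a soft-thresholded, L2-normalised copy of ``a``; the
    threshold is 0 if the L1 constraint is slack, otherwise the unique positive
    root found by bisection.
    """
    a = np.maximum(np.asarray(a, dtype=float), 0.0)
    if not np.any(a > 0):
        raise ValueError("all between-cluster sums of squares are zero")
    a = a / a.max()  # scale-invariant direction; guards against underflow

    def w_of(delta: float) -> np.ndarray:
        s = np.maximum(a - delta, 0.0)
        if not np.any(s > 0):
            return s
        s = s / s.max()  # underflow guard; direction is what matters
        return s / np.linalg.norm(s)

    w = w_of(0.0)
    if w.sum() <= l + tol:
        return w
    lo, hi = 0.0, float(a.max())
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        s1 = w_of(mid).sum()
        if abs(s1 - l) < tol:
            return w_of(mid)
        if s1 > l:
            lo = mid
        else:
            hi = mid
    w = w_of(0.5 * (lo + hi))
    if w.sum() <= l + tol:
        return w
    # exactly tied maxima: ||w||_1 of the normalised family cannot go below
    # sqrt(m); the KKT optimum then spreads l/m over the tied coordinates
    # (||w||_2 < 1 is optimal in this degenerate case)
    tied = a >= a.max() * (1.0 - 1e-12)
    out = np.zeros_like(a)
    out[tied] = l / tied.sum()
    return out


def _weighted_distances(
    Xw0: np.ndarray, mask: np.ndarray, centers: np.ndarray, scale: np.ndarray
) -> np.ndarray:
    """Squared distances (n, k) in weight-rescaled space, missing-scaled.

    ``Xw0``: data with missing entries zeroed; ``centers`` are complete.
    ``scale`` is the per-row ``p / n_observed`` factor.
    """
    # sum_j m_ij (x_ij - c_kj)^2 = sum_j m x^2 + sum_j m c^2 - 2 sum_j m x c
    x2 = (Xw0**2 * mask).sum(axis=1)
    c2 = mask @ (centers**2).T
    xc = Xw0 @ centers.T
    d2 = x2[:, None] + c2 - 2.0 * xc
    return np.maximum(d2, 0.0) * scale[:, None]


def _multi_lloyd(
    Xw0: np.ndarray,
    mask: np.ndarray,
    k: int,
    init_centers: np.ndarray,
    scale: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Run Lloyd's algorithm from many starts in lock-step.

    ``init_centers`` has shape (S, k, p).  Returns the labels, centers and
    inertia of the best start (lowest weighted within-cluster inertia).
    Empty clusters are repaired by re-seeding the empty center at the point
    farthest from its assigned center.
    """
    S, _, p = init_centers.shape
    n = Xw0.shape[0]
    centers = init_centers.copy()
    maskf = mask.astype(float)
    col_cnt = mask.sum(axis=0)
    col_mean = np.where(col_cnt > 0, Xw0.sum(axis=0) / np.maximum(col_cnt, 1), 0.0)
    x2 = (Xw0**2 * mask).sum(axis=1)
    labels = np.full((S, n), -1, dtype=np.intp)
    inertia = np.full(S, np.inf)
    active = np.arange(S)
    for _ in range(max_iter):
        C = centers[active]
        d2 = (
            x2[None, :, None]
            + np.einsum("nj,skj->snk", maskf, C**2)
            - 2.0 * np.einsum("nj,skj->snk", Xw0, C)
        )
        d2 = np.maximum(d2, 0.0) * scale[None, :, None]
        new_labels = d2.argmin(axis=2)
        inertia[active] = np.take_along_axis(d2, new_labels[:, :, None], axis=2)[
            :, :, 0
        ].sum(axis=1)
        changed = (new_labels != labels[active]).any(axis=1)
        labels[active] = new_labels
        if not changed.any():
            break
        # recompute centers only for starts whose assignment moved
        active = active[changed]
        sub = new_labels[changed]
        onehot = (sub[:, :, None] == np.arange(k)[None, None, :]).astype(float)
        sums = np.einsum("snk,nj->skj", onehot, Xw0)
        cnts = np.einsum("snk,nj->skj", onehot, maskf)
        with np.errstate(invalid="ignore", divide="ignore"):
            new_centers = np.where(cnts > 0, sums / np.maximum(cnts, 1e-300), col_mean)
        members = onehot.sum(axis=1)  # (n_active, k)
        if (members == 0).any():
            far = np.take_along_axis(
                d2[changed], sub[:, :, None], axis=2
            )[:, :, 0]
            for s_idx, c_idx in zip(*np.nonzero(members == 0)):
                i_far = int(np.argmax(far[s_idx]))
                new_centers[s_idx, c_idx] = np.where(mask[i_far], Xw0[i_far], col_mean)
        centers[active] = new_centers
    best = int(np.argmin(inertia))
    return labels[best], centers[best], float(inertia[best])


def _random_centers(
    X0: np.ndarray, mask: np.ndarray, k: int, n_start: int, rng: np.random.Generator
) -> np.ndarray:
    n, p = X0.shape
    col_cnt = mask.sum(axis=0)
    col_mean = np.where(col_cnt > 0, X0.sum(axis=0) / np.maximum(col_cnt, 1), 0.0)
    idx = np.empty((n_start, k), dtype=np.intp)
    for s in range(n_start):
        idx[s] = rng.choice(n, size=k, replace=False)
    centers = np.where(mask[idx], X0[idx], col_mean)
    return centers


def sparse_kmeans(X: np.ndarray, config: SparseKMeansConfig) -> ClusterSolution:
    """Run sparse k-means and return the best multi-start solution.

    The alternation stops when the relative L1 change of the weight vector
    drops below ``config.tol``.  The weighted between-cluster objective is
    non-decreasing across alternations and is recorded in
    ``solution.objective_trace``.
    """
    X0, mask = _as_masked(X)
    n, p = X0.shape
    if n <= config.k:
        raise ValueError("need more rows than clusters")
    l = config.resolve_l(p)
    rng = config.rng()
    scale = p / np.maximum(mask.sum(axis=1), 1)

    w = np.full(p, 1.0 / np.sqrt(p))
    labels = None
    centers_w = None
    trace: list[float] = []
    n_iter = 0
    converged = False
    for it in range(1, config.max_iter + 1):
        n_iter = it
        sw = np.sqrt(w)
        Xw0 = X0 * sw
        init = _random_centers(Xw0, mask, config.k, config.n_start, rng)
        if labels is not None:
            # warm start: carry the previous partition's centers forward
            onehot = labels[:, None] == np.arange(config.k)[None, :]
            sums = onehot.T @ Xw0
            cnts = onehot.T.astype(float) @ mask
            col_mean = Xw0.sum(axis=0) / np.maximum(mask.sum(axis=0), 1)
            warm = np.where(cnts > 0, sums / np.maximum(cnts, 1e-300), col_mean)
            init = np.concatenate([warm[None], init], axis=0)
        labels, centers_w, _ = _multi_lloyd(Xw0, mask, config.k, init, scale)
        a = per_feature_bcss(X0 + np.where(mask, 0.0, np.nan), labels)
        w_new = update_weights(a, l)
        trace.append(float(w_new @ a))
        rel = np.abs(w_new - w).sum() / max(np.abs(w).sum(), 1e-300)
        w = w_new
        if rel < config.tol:
            converged = True
            break
    a = per_feature_bcss(X0 + np.where(mask, 0.0, np.nan), labels)
    objective = float(w @ a)
    # centers reported as cluster means in the input (standardized) space;
    # the weights enter assignment through the dissimilarity, not the centers
    onehot = labels[:, None] == np.arange(config.k)[None, :]
    sums = onehot.T.astype(float) @ X0
    cnts = onehot.T.astype(float) @ mask
    col_mean = X0.sum(axis=0) / np.maximum(mask.sum(axis=0), 1)
    centers = np.where(cnts > 0, sums / np.maximum(cnts, 1e-300), col_mean)
    return ClusterSolution(
        labels=labels.copy(),
        weights=w,
        centers=centers,
        objective=objective,
        k=config.k,
        l=l,
        n_iter=n_iter,
        converged=converged,
        objective_trace=trace,
    )


def assign_to_centers(
    rows: np.ndarray, centers: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Assign rows to the cluster minimising ``sum_j w_j (x_j - c_j)^2``.

    ``centers`` are cluster means in the same (standardized) space as the
    rows; a zero-weight column therefore cannot change any assignment.
    Missing coordinates are skipped with the same ``p / n_observed`` scaling
    used during clustering.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    centers = np.asarray(centers, dtype=float)
    if rows.shape[1] != centers.shape[1]:
        raise ValueError("dimension mismatch between rows and centers")
    X0, mask = _as_masked(rows)
    p = rows.shape[1]
    sw = np.sqrt(np.asarray(weights, dtype=float))
    scale = p / np.maximum(mask.sum(axis=1), 1)
    d2 = _weighted_distances(X0 * sw, mask, centers * sw, scale)
    return d2.argmin(axis=1)


def tune_sparsity(
    X: np.ndarray,
    k: int,
    l_grid: Sequence[float],
    n_perm: int = 2000,
    n_start: int = 20,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Permutation-based selection of the sparsity bound ``l``.

    For each candidate ``l``, ``Gap(l) = log O(l) - mean_b log O_b(l)`` where
    ``O`` is the weighted between-cluster objective and each permuted dataset
    independently shuffles every column.  Returns the grid, the gap curve with
    standard errors, the maximising ``l`` and whether the non-binding
    ``l = sqrt(p)`` lies within one standard error of the maximum.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be at least 2")
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("tune_sparsity expects a complete matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = X.shape[1]
    l_grid = [float(l) for l in l_grid]
    for l in l_grid:
        if not (1.0 < l <= np.sqrt(p) + 1e-9):
            raise ValueError("l_grid values must lie in (1, sqrt(p)]")

    def objectives(M: np.ndarray, sub_rng: np.random.Generator) -> np.ndarray:
        out = np.empty(len(l_grid))
        for i, l in enumerate(l_grid):
            cfg = SparseKMeansConfig(k=k, l=l, n_start=n_start, seed=sub_rng)
            out[i] = sparse_kmeans(M, cfg).objective
        return out

    obs = objectives(X, rng)
    null_logs = np.empty((n_perm, len(l_grid)))
    for b in range(n_perm):
        Xp = np.column_stack([rng.permutation(X[:, j]) for j in range(p)])
        null_logs[b] = np.log(np.maximum(objectives(Xp, rng), 1e-300))
    gaps = np.log(np.maximum(obs, 1e-300)) - null_logs.mean(axis=0)
    se = null_logs.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / n_perm)
    best = int(np.argmax(gaps))
    l_max = max(l_grid)
    i_unconstrained = int(np.argmax(l_grid))
    unconstrained_ok = bool(
        abs(l_grid[i_unconstrained] - np.sqrt(p)) < 1e-6
        and gaps[i_unconstrained] >= gaps[best] - se[best]
    )
    return {
        "l_grid": l_grid,
        "gap": gaps,
        "se": se,
        "chosen_l": l_grid[best],
        "l_max": l_max,
        "unconstrained_within_1se": unconstrained_ok,
    }
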
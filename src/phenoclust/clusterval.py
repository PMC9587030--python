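"""Cluster stability and partition agreement.

Stability follows the bootstrap scheme of resampling rows with replacement,
dropping duplicated points, reclustering with the original configuration, and
scoring each original cluster by its best Jaccard match among the new
clusters (restricted to rows present in the resample).  Mean Jaccard above
0.85 marks a highly stable cluster, above 0.75 a stable one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .spkmeans import ClusterSolution, SparseKMeansConfig, sparse_kmeans

__all__ = [
    "StabilityReport",
    "PartitionComparison",
    "jaccard",
    "stability_label",
    "bootstrap_stability",
    "compare_partitions",
    "variation_of_information",
]

HIGH_STABLE = 0.85
STABLE = 0.75


@dataclass
class StabilityReport:
    """Per-cluster mean Jaccard stability over B bootstrap reclusterings."""

    mean_jaccard: np.ndarray
    labels: list
    dissolved: np.ndarray  # per-cluster count of resamples with Jaccard < 0.5
    B: int

    def to_dict(self) -> dict:
        return {
            "mean_jaccard": self.mean_jaccard.tolist(),
            "labels": list(self.labels),
            "dissolved": self.dissolved.tolist(),
            "B": self.B,
        }


@dataclass
class PartitionComparison:
    cer: float
    vi: float


def jaccard(a: set, b: set) -> float:
    """Jaccard similarity of two index sets; empty-vs-empty counts as 0."""
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def stability_label(gamma: float) -> str:
    if gamma > HIGH_STABLE:
        return "highly stable"
    if gamma > STABLE:
        return "stable"
    return "unstable"


def bootstrap_stability(
    matrix: np.ndarray,
    solution: ClusterSolution,
    B: int = 2000,
    seed: int | np.random.Generator | None = None,
    n_start: int = 20,
) -> StabilityReport:
    """Cluster-wise Jaccard stability over B deduplicated bootstrap resamples."""
    if B < 1:
        raise ValueError("B must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    k = solution.k
    orig_sets = [set(np.nonzero(solution.labels == c)[0]) for c in range(k)]
    sums = np.zeros(k)
    counts = np.zeros(k)
    dissolved = np.zeros(k, dtype=int)
    for _ in range(B):
        for _attempt in range(20):
            idx = np.unique(rng.choice(n, size=n, replace=True))
            if idx.size > k:
                break
        else:
            raise RuntimeError("could not draw a resample with enough distinct rows")
        cfg = SparseKMeansConfig(
            k=k, l=solution.l, n_start=n_start, seed=rng
        )
        new = sparse_kmeans(X[idx], cfg)
        new_sets = [set(idx[new.labels == c]) for c in range(k)]
        present = set(idx.tolist())
        for c in range(k):
            restricted = orig_sets[c] & present
            if not restricted:
                continue
            best = max(jaccard(restricted, s) for s in new_sets)
            sums[c] += best
            counts[c] += 1
            if best < 0.5:
                dissolved[c] += 1
    gamma = sums / np.maximum(counts, 1)
    return StabilityReport(
        mean_jaccard=gamma,
        labels=[stability_label(g) for g in gamma],
        dissolved=dissolved,
        B=B,
    )


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ua, ub = np.unique(a), np.unique(b)
    C = np.zeros((ua.size, ub.size))
    for i, g in enumerate(ua):
        for j, h in enumerate(ub):
            C[i, j] = np.sum((a == g) & (b == h))
    return C


def variation_of_information(labels_a, labels_b) -> float:
    """VI = H(A|B) + H(B|A) in natural-log units; 0 iff identical partitions."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    n = a.size
    C = _contingency(a, b) / n
    pa = C.sum(axis=1)
    pb = C.sum(axis=0)
    nz = C > 0
    h_ab = -np.sum(C[nz] * (np.log(C[nz]) - np.log(np.broadcast_to(pb, C.shape)[nz])))
    h_ba = -np.sum(C[nz] * (np.log(C[nz]) - np.log(np.broadcast_to(pa[:, None], C.shape)[nz])))
    return float(max(h_ab + h_ba, 0.0))


def compare_partitions(labels_a, labels_b) -> PartitionComparison:
    """Classification error rate (Hungarian matching) and variation of information."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    C = _contingency(a, b)
    r, c = linear_sum_assignment(-C)
    cer = 1.0 - C[r, c].sum() / a.size
    return PartitionComparison(cer=float(cer), vi=variation_of_information(a, b))
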
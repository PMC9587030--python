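"""Cluster-wise inference.

One-way ANOVA with a cluster-stratified bootstrap null (between-cluster mean
differences nullified before resampling), two-way diagnosis-by-cluster
interaction tests with a residual bootstrap, and BCa pairwise contrasts with
Bonferroni-widened confidence levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .groupstats import PermTestResult

__all__ = [
    "ContrastResult",
    "boot_oneway_anova",
    "boot_twoway_interaction",
    "bca_interval",
    "bca_pairwise_contrasts",
    "within_cluster_group_contrasts",
]


@dataclass
class ContrastResult:
    pair: tuple
    delta_mean: float
    ci: tuple
    level: float
    ci_adjusted: tuple
    level_adjusted: float
    significant: bool
    significant_adjusted: bool
    B: int
    degenerate: bool = False


def _oneway_f(y: np.ndarray, groups: list[np.ndarray]) -> float:
    """Textbook one-way ANOVA F from index groups (y may be 2-D: draws x n)."""
    k = len(groups)
    n = sum(g.size for g in groups)
    grand = y[..., np.concatenate(groups)].mean(axis=-1)
    ssb = np.zeros_like(grand)
    sse = np.zeros_like(grand)
    for g in groups:
        m = y[..., g].mean(axis=-1)
        ssb = ssb + g.size * (m - grand) ** 2
        sse = sse + ((y[..., g] - m[..., None]) ** 2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ssb / (k - 1)) / (sse / (n - k))


def boot_oneway_anova(
    y: Sequence[float],
    labels: Sequence,
    B: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> PermTestResult:
    """One-way ANOVA with cluster-stratified bootstrap null F distribution.

    The null population nullifies between-cluster mean differences (each
    cluster centered, grand mean restored — within-cluster distributions are
    preserved exactly); draws resample with replacement within each cluster,
    keeping cluster sizes.  ``P_boot = (1 + #{F* >= F}) / (1 + B)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float).ravel()
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two clusters")
    groups = [np.nonzero(labels == g)[0] for g in uniq]
    if any(g.size < 2 for g in groups):
        raise ValueError("a cluster of size 1 cannot be resampled")
    F_obs = float(_oneway_f(y, groups))
    dfh, dfe = uniq.size - 1, y.size - uniq.size
    null = y.copy()
    for g in groups:
        null[g] = y[g] - y[g].mean()
    null += y.mean()
    # resample within each cluster, preserving sizes, B draws at once
    Ystar = np.empty((B, y.size))
    for g in groups:
        draws = rng.choice(null[g], size=(B, g.size), replace=True)
        Ystar[:, g] = draws
    F_star = _oneway_f(Ystar, groups)
    p_boot = float((1 + np.sum(F_star >= F_obs)) / (1 + B))
    return PermTestResult(
        statistic="F",
        value=F_obs,
        df=(dfh, dfe),
        p_parametric=float(stats.f.sf(F_obs, dfh, dfe)),
        p_empirical=p_boot,
        n_resamples=B,
    )


def _twoway_designs(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Full (with interaction) and reduced (main effects) design matrices."""
    ua, ub = np.unique(a), np.unique(b)
    cols = [np.ones(a.size)]
    cols += [(a == g).astype(float) for g in ua[1:]]
    cols += [(b == h).astype(float) for h in ub[1:]]
    reduced = np.column_stack(cols)
    inter = [
        (a == g).astype(float) * (b == h).astype(float)
        for g in ua[1:]
        for h in ub[1:]
    ]
    full = np.column_stack(cols + inter)
    return full, reduced, len(inter)


def boot_twoway_interaction(
    y: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    B: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> PermTestResult:
    """Interaction F with a cell-stratified residual-bootstrap null.

    Null responses sum the reduced-model (main effects only) fitted values and
    full-model residuals resampled with replacement within each cell.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float).ravel()
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    cells = [
        np.nonzero((a == g) & (b == h))[0]
        for g in np.unique(a)
        for h in np.unique(b)
    ]
    if any(c.size == 0 for c in cells):
        raise ValueError("every factor cell must be non-empty")
    full, reduced, df_int = _twoway_designs(a, b)
    n = y.size
    Qf, _ = np.linalg.qr(full)
    Qr, _ = np.linalg.qr(reduced)
    Pf, Pr = Qf @ Qf.T, Qr @ Qr.T
    M_int = Pf - Pr
    M_err = np.eye(n) - Pf
    dfe = n - np.linalg.matrix_rank(full)

    def f_stat(v: np.ndarray) -> np.ndarray:
        num = np.einsum("...i,ij,...j->...", v, M_int, v) / df_int
        den = np.einsum("...i,ij,...j->...", v, M_err, v) / dfe
        return num / np.maximum(den, 1e-300)

    F_obs = float(f_stat(y))
    fitted_red = Pr @ y
    resid_full = y - Pf @ y
    Ystar = np.empty((B, n))
    for c in cells:
        Ystar[:, c] = rng.choice(resid_full[c], size=(B, c.size), replace=True)
    Ystar += fitted_red
    F_star = f_stat(Ystar)
    p_boot = float((1 + np.sum(F_star >= F_obs)) / (1 + B))
    return PermTestResult(
        statistic="F",
        value=F_obs,
        df=(df_int, dfe),
        p_parametric=float(stats.f.sf(F_obs, df_int, dfe)),
        p_empirical=p_boot,
        n_resamples=B,
    )


def _quantile(sorted_draws: np.ndarray, q: float) -> float:
    return float(np.quantile(sorted_draws, np.clip(q, 0.0, 1.0), method="linear"))


def bca_interval(
    x: np.ndarray,
    y: np.ndarray,
    level: float,
    B: int,
    rng: np.random.Generator,
) -> tuple[float, tuple, bool]:
    """BCa interval for the mean difference ``mean(x) - mean(y)``.

    Bias correction ``z0`` comes from the bootstrap CDF at the observed
    difference; acceleration ``a`` from the jackknife skewness over the pooled
    sample with group labels fixed.  Group-stratified resampling.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    delta = float(x.mean() - y.mean())
    bx = rng.choice(x, size=(B, x.size), replace=True).mean(axis=1)
    by = rng.choice(y, size=(B, y.size), replace=True).mean(axis=1)
    draws = bx - by
    if np.allclose(draws, draws[0]):
        return delta, (delta, delta), True
    prop = np.mean(draws < delta)
    prop = min(max(prop, 1.0 / (2 * B)), 1.0 - 1.0 / (2 * B))
    z0 = stats.norm.ppf(prop)
    # leave-one-out over the pooled sample, labels fixed
    jack = np.empty(x.size + y.size)
    sx, sy = x.sum(), y.sum()
    for i in range(x.size):
        jack[i] = (sx - x[i]) / (x.size - 1) - y.mean()
    for i in range(y.size):
        jack[x.size + i] = x.mean() - (sy - y[i]) / (y.size - 1)
    jm = jack.mean()
    num = ((jm - jack) ** 3).sum()
    den = 6.0 * (((jm - jack) ** 2).sum()) ** 1.5
    a = num / den if den > 0 else 0.0
    alpha = (1.0 - level) / 2.0
    z_lo, z_hi = stats.norm.ppf(alpha), stats.norm.ppf(1.0 - alpha)
    q_lo = stats.norm.cdf(z0 + (z0 + z_lo) / (1.0 - a * (z0 + z_lo)))
    q_hi = stats.norm.cdf(z0 + (z0 + z_hi) / (1.0 - a * (z0 + z_hi)))
    lo = _quantile(draws, q_lo)
    hi = _quantile(draws, q_hi)
    return delta, (lo, hi), False


def bca_pairwise_contrasts(
    y: Sequence[float],
    labels: Sequence,
    level: float = 0.95,
    m_corrections: int | None = None,
    B: int = 10000,
    seed: int | np.random.Generator | None = None,
    pairs: Sequence[tuple] | None = None,
) -> list[ContrastResult]:
    """Pairwise mean-difference BCa contrasts at nominal and Bonferroni levels.

    Each contrast is ``mean(first) - mean(second)``; the Bonferroni-widened
    level is ``1 - (1 - level)/m`` (e.g. 98.3% for m = 3).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float).ravel()
    labels = np.asarray(labels)
    uniq = list(np.unique(labels))
    if pairs is None:
        pairs = list(combinations(uniq, 2))
    m = m_corrections if m_corrections is not None else len(pairs)
    level_adj = 1.0 - (1.0 - level) / max(m, 1)
    out: list[ContrastResult] = []
    for g1, g2 in pairs:
        x1 = y[labels == g1]
        x2 = y[labels == g2]
        if x1.size < 2 or x2.size < 2:
            raise ValueError(f"pair ({g1}, {g2}) needs >= 2 members per group")
        # one resampling stream per pair; both levels read the same draws
        sub = np.random.default_rng(rng.integers(2**31))
        draws_seed = sub.bit_generator.state
        d1, ci, degen = bca_interval(x1, x2, level, B, sub)
        sub.bit_generator.state = draws_seed
        _, ci_adj, _ = bca_interval(x1, x2, level_adj, B, sub)
        out.append(
            ContrastResult(
                pair=(g1, g2),
                delta_mean=d1,
                ci=ci,
                level=level,
                ci_adjusted=ci_adj,
                level_adjusted=level_adj,
                significant=not (ci[0] <= 0.0 <= ci[1]),
                significant_adjusted=not (ci_adj[0] <= 0.0 <= ci_adj[1]),
                B=B,
                degenerate=degen,
            )
        )
    return out


def within_cluster_group_contrasts(
    y: Sequence[float],
    diagnosis: Sequence,
    cluster: Sequence,
    level: float = 0.95,
    B: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> list[ContrastResult]:
    """One SZ-minus-HC BCa contrast per cluster, Bonferroni m = #clusters."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float).ravel()
    dx = np.asarray(diagnosis)
    cl = np.asarray(cluster)
    clusters = list(np.unique(cl))
    out: list[ContrastResult] = []
    for c in clusters:
        rows = cl == c
        if np.unique(dx[rows]).size < 2:
            raise ValueError(f"cluster {c!r} lacks one diagnostic group")
        res = bca_pairwise_contrasts(
            y[rows],
            dx[rows],
            level=level,
            m_corrections=len(clusters),
            B=B,
            seed=rng,
            pairs=[("SZ", "HC")],
        )[0]
        res.pair = (c, "SZ-HC")
        out.append(res)
    return out
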
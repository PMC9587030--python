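"""Diagnostic-group inference.

Rank tests, minimum-likelihood exact contingency tests with conditional-MLE
odds ratios, Pillai-trace MAN(C)OVA with a parametric F approximation, and
Freedman-Lane permutation p-values that preserve covariate structure by
permuting reduced-model residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "PermTestResult",
    "ExactTableResult",
    "wilcoxon_mw",
    "fisher_exact",
    "odds_ratio_cmle",
    "pillai_manova",
    "freedman_lane_p",
    "univariate_followup",
]


@dataclass
class PermTestResult:
    statistic: str  # "pillai_V" | "F"
    value: float
    df: tuple
    p_parametric: float
    p_empirical: float | None = None
    n_resamples: int = 0
    eta_sq: float | None = None
    partial_eta_sq: float | None = None
    seed: int | None = None


@dataclass
class ExactTableResult:
    table: np.ndarray
    p_value: float
    odds_ratio: float | None = None
    ci: tuple | None = None
    level: float = 0.95


# ---------------------------------------------------------------------------
# rank test


def wilcoxon_mw(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Exact null distribution when the pooled sample is small (<= 20) and free
    of ties, otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    exact = (pooled.size <= 20) and (np.unique(pooled).size == pooled.size)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# exact contingency tests (minimum-likelihood two-sided)


def _log_table_prob(row1: np.ndarray, colsums: np.ndarray, n: int, r1: int) -> float:
    """log multivariate hypergeometric probability of first-row counts."""
    out = -(lgamma(n + 1) - lgamma(r1 + 1) - lgamma(n - r1 + 1))
    for a, cj in zip(row1, colsums):
        out += lgamma(cj + 1) - lgamma(a + 1) - lgamma(cj - a + 1)
    return out


def _enumerate_first_rows(colsums: np.ndarray, r1: int):
    """Yield all first rows consistent with the margins."""
    C = len(colsums)

    def rec(j: int, remaining: int, prefix: list):
        if j == C - 1:
            if 0 <= remaining <= colsums[j]:
                yield prefix + [remaining]
            return
        tail = int(colsums[j + 1 :].sum())
        lo = max(0, remaining - tail)
        hi = min(colsums[j], remaining)
        for a in range(lo, hi + 1):
            yield from rec(j + 1, remaining - a, prefix + [a])

    yield from rec(0, r1, [])


def fisher_exact(table: Sequence[Sequence[int]]) -> ExactTableResult:
    """Minimum-likelihood two-sided Fisher exact test for a 2 x C table.

    All tables with the observed margins are enumerated; the p-value sums the
    (multivariate) hypergeometric probabilities of tables no more likely than
    the observed one (with a small relative slack against round-off).
    """
    T = np.asarray(table, dtype=int)
    if T.ndim != 2 or T.shape[0] != 2:
        raise ValueError("table must be 2 x C")
    if (T < 0).any():
        raise ValueError("counts must be non-negative")
    colsums = T.sum(axis=0)
    r1 = int(T[0].sum())
    n = int(T.sum())
    if (colsums == 0).any() or r1 == 0 or n - r1 == 0:
        raise ValueError("all margins must be positive")
    lp_obs = _log_table_prob(T[0], colsums, n, r1)
    total = 0.0
    for row1 in _enumerate_first_rows(colsums, r1):
        lp = _log_table_prob(np.asarray(row1), colsums, n, r1)
        if lp <= lp_obs + 1e-7:
            total += np.exp(lp)
    return ExactTableResult(table=T, p_value=float(min(total, 1.0)))


def _nchg_logpmf(support: np.ndarray, c1: int, c2: int, r1: int, log_psi: float) -> np.ndarray:
    """Unnormalised log pmf of Fisher's noncentral hypergeometric."""
    lg = np.vectorize(lgamma)
    out = (
        lg(c1 + 1) - lg(support + 1) - lg(c1 - support + 1)
        + lg(c2 + 1) - lg(r1 - support + 1) - lg(c2 - (r1 - support) + 1)
        + support * log_psi
    )
    return out


def _nchg_pmf(support: np.ndarray, c1: int, c2: int, r1: int, log_psi: float) -> np.ndarray:
    lp = _nchg_logpmf(support, c1, c2, r1, log_psi)
    lp -= lp.max()
    p = np.exp(lp)
    return p / p.sum()


def _minlike_p(a_obs: int, c1: int, c2: int, r1: int, log_psi: float) -> float:
    lo = max(0, r1 - c2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = _nchg_pmf(support, c1, c2, r1, log_psi)
    p_obs = pmf[a_obs - lo]
    return float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())


def odds_ratio_cmle(
    table: Sequence[Sequence[int]], level: float = 0.95
) -> ExactTableResult:
    """Conditional-MLE odds ratio with exact minimum-likelihood CI for 2 x 2.

    The point estimate solves ``E_psi[a | margins] = a``; the interval inverts
    the two-sided minimum-likelihood exact test at the requested level (the
    interval is the hull of the non-rejected odds-ratio values).
    """
    T = np.asarray(table, dtype=int)
    if T.shape != (2, 2):
        raise ValueError("table must be 2 x 2")
    a = int(T[0, 0])
    c1, c2 = int(T[:, 0].sum()), int(T[:, 1].sum())
    r1 = int(T[0].sum())
    lo = max(0, r1 - c2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)

    def mean_minus_a(log_psi: float) -> float:
        pmf = _nchg_pmf(support, c1, c2, r1, log_psi)
        return float((support * pmf).sum() - a)

    if a == hi:
        psi_hat = np.inf
    elif a == lo:
        psi_hat = 0.0
    else:
        log_psi_hat = brentq(mean_minus_a, -50.0, 50.0, xtol=1e-12)
        psi_hat = float(np.exp(log_psi_hat))

    alpha = 1.0 - level
    grid = np.linspace(-14.0, 14.0, 4001)
    pvals = np.array([_minlike_p(a, c1, c2, r1, g) for g in grid])
    accept = pvals > alpha
    if not accept.any():
        ci = (psi_hat, psi_hat)
    else:
        i_lo = int(np.argmax(accept))
        i_hi = int(len(accept) - 1 - np.argmax(accept[::-1]))

        def p_minus_alpha(g: float) -> float:
            return _minlike_p(a, c1, c2, r1, g) - alpha

        if i_lo == 0 or a == lo:
            lower = 0.0
        else:
            lower = float(np.exp(brentq(p_minus_alpha, grid[i_lo - 1], grid[i_lo], xtol=1e-10)))
        if i_hi == len(grid) - 1 or a == hi:
            upper = np.inf
        else:
            upper = float(np.exp(brentq(p_minus_alpha, grid[i_hi], grid[i_hi + 1], xtol=1e-10)))
        ci = (lower, upper)
    p = _minlike_p(a, c1, c2, r1, 0.0)
    return ExactTableResult(table=T, p_value=p, odds_ratio=psi_hat, ci=ci, level=level)


# ---------------------------------------------------------------------------
# multivariate / univariate linear-model inference


def _design_matrices(
    n: int, group: np.ndarray, covariates: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, int]:
    """(full, reduced) design matrices and the group-term df."""
    cols = [np.ones(n)]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        cols.extend(C[:, j] for j in range(C.shape[1]))
    reduced = np.column_stack(cols)
    levels = np.unique(group)
    dummies = [(group == g).astype(float) for g in levels[1:]]
    full = np.column_stack(cols + dummies)
    return full, reduced, len(dummies)


def _proj(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


def pillai_trace_stat(
    Y: np.ndarray, group: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, tuple, float, int, int]:
    """Pillai's V for the group term, with its F approximation.

    Returns ``(V, (df1, df2), F, dfh, dfe)``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != len(group):
        Y = Y.T
    n, q = Y.shape
    full, reduced, dfh = _design_matrices(n, np.asarray(group), covariates)
    if n <= full.shape[1] + q:
        raise ValueError("too few rows for the requested model")
    Pf, Pr = _proj(full), _proj(reduced)
    H = Y.T @ (Pf - Pr) @ Y
    E = Y.T @ (np.eye(n) - Pf) @ Y
    HE = H + E
    try:
        V = float(np.trace(np.linalg.solve(HE, H)))
    except np.linalg.LinAlgError as err:
        raise ValueError("singular H + E matrix") from err
    dfe = n - np.linalg.matrix_rank(full)
    s = min(q, dfh)
    m = (abs(dfh - q) - 1) / 2.0
    nn = (dfe - q - 1) / 2.0
    F = ((2 * nn + s + 1) / (2 * m + s + 1)) * (V / (s - V)) if V < s else np.inf
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    return V, (df1, df2), F, dfh, dfe


def pillai_manova(
    Y: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
) -> PermTestResult:
    """Parametric Pillai-trace MANOVA/MANCOVA for a group term."""
    V, (df1, df2), F, _, _ = pillai_trace_stat(Y, group, covariates)
    p = float(stats.f.sf(F, df1, df2))
    return PermTestResult(statistic="pillai_V", value=V, df=(df1, df2), p_parametric=p)


def freedman_lane_p(
    Y: np.ndarray,
    statistic_fn: Callable[[np.ndarray], float],
    reduced_design: np.ndarray,
    n_perm: int = 50000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Freedman-Lane permutation p-value for a linear-model term.

    The reduced (covariates-only) model is fitted once; each permuted response
    is its fitted values plus a permutation of its residuals, and the caller's
    statistic is recomputed.  ``P = (1 + #{stat* >= stat_obs}) / (1 + n_perm)``
    — never zero.  With no covariates this reduces to permuting raw responses.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != reduced_design.shape[0]:
        Y = Y.T
    n = Y.shape[0]
    Pr = _proj(np.asarray(reduced_design, dtype=float))
    fitted = Pr @ Y
    resid = Y - fitted
    obs = statistic_fn(Y)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Ystar = fitted + resid[perm]
        if statistic_fn(Ystar) >= obs:
            count += 1
    return float((1 + count) / (1 + n_perm)), float(obs)


def pillai_manova_perm(
    Y: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 50000,
    seed: int | np.random.Generator | None = None,
) -> PermTestResult:
    """Pillai MANCOVA with a Freedman-Lane empirical p-value."""
    group = np.asarray(group)
    res = pillai_manova(Y, group, covariates)
    n = len(group)
    _, reduced, _ = _design_matrices(n, group, covariates)

    def stat(Ystar: np.ndarray) -> float:
        return pillai_trace_stat(Ystar, group, covariates)[0]

    p_emp, _ = freedman_lane_p(Y, stat, reduced, n_perm=n_perm, seed=seed)
    res.p_empirical = p_emp
    res.n_resamples = n_perm
    return res


def univariate_followup(
    y: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 0,
    seed: int | np.random.Generator | None = None,
) -> PermTestResult:
    """AN(C)OVA F for the group term with eta-squared effect sizes.

    ``eta^2 = SS_group / SS_total`` (no covariates) and ``eta_p^2 =
    SS_group / (SS_group + SS_error)``; the two coincide when the covariate
    list is empty.  ``n_perm > 0`` adds a Freedman-Lane empirical p-value.
    """
    y = np.asarray(y, dtype=float).ravel()
    group = np.asarray(group)
    n = y.size
    full, reduced, dfh = _design_matrices(n, group, covariates)
    Pf, Pr = _proj(full), _proj(reduced)
    yc = y - y.mean()
    ss_total = float(yc @ yc)
    ss_group = float(y @ (Pf - Pr) @ y)
    ss_error = float(y @ (np.eye(n) - Pf) @ y)
    dfe = n - np.linalg.matrix_rank(full)
    F = (ss_group / dfh) / (ss_error / dfe)
    p = float(stats.f.sf(F, dfh, dfe))
    res = PermTestResult(
        statistic="F",
        value=float(F),
        df=(dfh, dfe),
        p_parametric=p,
        eta_sq=ss_group / ss_total if ss_total > 0 else np.nan,
        partial_eta_sq=ss_group / (ss_group + ss_error)
        if (ss_group + ss_error) > 0
        else np.nan,
    )
    if n_perm > 0:
        M = Pf - Pr
        E = np.eye(n) - Pf

        def stat(Ystar: np.ndarray) -> float:
            v = Ystar.ravel()
            return float((v @ M @ v) / dfh / max(v @ E @ v / dfe, 1e-300))

        res.p_empirical, _ = freedman_lane_p(y, stat, reduced, n_perm=n_perm, seed=seed)
        res.n_resamples = n_perm
    return res
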
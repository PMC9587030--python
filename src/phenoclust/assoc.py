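"""Correlation screens.

Spearman correlations on pairwise-complete observations, Storey-style
q-values with the bootstrap pi0 estimator, and partial Spearman correlations
(rank-transform, then residualise on the controls).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrResult",
    "spearman_matrix",
    "qvalues",
    "partial_spearman",
]


@dataclass
class CorrResult:
    x: str
    y: str
    rho: float
    n: int
    p: float
    q: float | None = None
    controls: tuple = ()


def _spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    xs, ys = x[ok], y[ok]
    if np.unique(xs).size < 2 or np.unique(ys).size < 2:
        return np.nan, n, np.nan
    rho, p = stats.spearmanr(xs, ys)
    return float(rho), n, float(p)


def spearman_matrix(
    X_block: pd.DataFrame, Y_block: pd.DataFrame, with_q: bool = True
) -> list[CorrResult]:
    """All X-by-Y Spearman correlations on pairwise-complete data.

    Ranks use midranks for ties; p-values come from the t approximation.  One
    q-value family spans the whole matrix.  Constant variables yield NaN rho
    (flagged missing) and are excluded from the q-value family.
    """
    results: list[CorrResult] = []
    for xc in X_block.columns:
        for yc in Y_block.columns:
            rho, n, p = _spearman_pair(
                X_block[xc].to_numpy(dtype=float), Y_block[yc].to_numpy(dtype=float)
            )
            results.append(CorrResult(x=str(xc), y=str(yc), rho=rho, n=n, p=p))
    if with_q:
        ps = [r.p for r in results if np.isfinite(r.p)]
        if ps:
            qs, _ = qvalues(ps)
            it = iter(qs)
            for r in results:
                if np.isfinite(r.p):
                    r.q = float(next(it))
    return results


def estimate_pi0_bootstrap(
    p: np.ndarray,
    lambdas: np.ndarray | None = None,
    n_boot: int = 100,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """Storey's bootstrap pi0: the lambda minimising bootstrap MSE.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))``; the MSE of each
    candidate is estimated against the minimum pi0 over the grid.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.asarray(p, dtype=float)
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_hat = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    pi0_min = pi0_hat.min()
    mse = np.zeros(lambdas.size)
    for _ in range(n_boot):
        pb = rng.choice(p, size=m, replace=True)
        pi0_b = np.array([np.mean(pb > lam) / (1.0 - lam) for lam in lambdas])
        mse += (pi0_b - pi0_min) ** 2
    best = int(np.argmin(mse))
    return float(np.clip(pi0_hat[best], 1.0 / m if m else 0.0, 1.0))


def qvalues(
    p_list, pi0: float | None = None, n_boot: int = 100, seed: int = 0
) -> tuple[np.ndarray, float]:
    """q-values with the bootstrap pi0 estimate (pass ``pi0`` to override).

    ``q_i = pi0 * min_{p_j >= p_i} (p_j * m / rank_j)`` — Benjamini-Hochberg
    scaled by pi0, monotonised from the largest p downward.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0_bootstrap(p, n_boot=n_boot, seed=seed) if p.size > 1 else 1.0
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out, float(pi0)


def fdr_at_threshold(p_list, q_list, threshold: float = 0.05) -> dict:
    """The two reporting modes: FDR incurred at P < t, and hits with q < t."""
    p = np.asarray(p_list, dtype=float)
    q = np.asarray(q_list, dtype=float)
    sig_p = p < threshold
    return {
        "n_p_significant": int(sig_p.sum()),
        "fdr_at_p_threshold": float(q[sig_p].max()) if sig_p.any() else 0.0,
        "n_q_significant": int((q < threshold).sum()),
    }


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def partial_spearman(x, y, controls) -> CorrResult:
    """Partial Spearman correlation of x and y given control variables.

    All variables are rank-transformed (midranks), x and y are residualised
    on the controls by least squares, and the residuals correlated; the
    p-value uses the t reference with ``df = n - 2 - k``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(controls, dtype=float))
    if Z.shape[0] != x.size:
        Z = Z.T
    k = Z.shape[1]
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(Z).any(axis=1))
    n = int(ok.sum())
    if n < k + 4:
        raise ValueError("need at least k + 4 complete cases")
    rx, ry = _rank(x[ok]), _rank(y[ok])
    RZ = np.column_stack([np.ones(n)] + [_rank(Z[ok, j]) for j in range(k)])
    if np.linalg.matrix_rank(RZ) < RZ.shape[1]:
        raise ValueError("singular control design")
    bx, *_ = np.linalg.lstsq(RZ, rx, rcond=None)
    by, *_ = np.linalg.lstsq(RZ, ry, rcond=None)
    ex, ey = rx - RZ @ bx, ry - RZ @ by
    # residuals indistinguishable from zero (a control explains x or y
    # exactly): the partial correlation is 0 by convention, not noise
    tiny = 1e-10 * n
    if (ex @ ex) < tiny or (ey @ ey) < tiny:
        rho = 0.0
    else:
        rho = float(ex @ ey / np.sqrt((ex @ ex) * (ey @ ey)))
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrResult(x="x", y="y", rho=rho, n=n, p=p, controls=tuple(range(k)))
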
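"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (pair counting, double loops, exhaustive
enumeration) kept separate from the package code paths they check.
"""

import itertools
from math import comb, lgamma

import numpy as np


def adjusted_rand_index(labels_a, labels_b) -> float:
    """ARI by brute-force pair counting over all unordered row pairs."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = a.size
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        if same_a and same_b:
            ss += 1
        elif same_a:
            sd += 1
        elif same_b:
            ds += 1
        else:
            dd += 1
    total = comb(n, 2)
    index = ss
    expected = (ss + sd) * (ss + ds) / total
    maximum = 0.5 * ((ss + sd) + (ss + ds))
    if maximum == expected:
        return 1.0
    return (index - expected) / (maximum - expected)


def bcss_double_loop(X, labels) -> np.ndarray:
    """Per-feature BCSS: total minus within sums of squares, plain loops."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    p = X.shape[1]
    out = np.zeros(p)
    for j in range(p):
        col = X[:, j]
        obs = ~np.isnan(col)
        mu = col[obs].mean()
        total = sum((v - mu) ** 2 for v in col[obs])
        within = 0.0
        for g in np.unique(labels):
            sub = col[(labels == g) & obs]
            if sub.size:
                within += sum((v - sub.mean()) ** 2 for v in sub)
        out[j] = total - within
    return out


def vi_contingency(labels_a, labels_b) -> float:
    """Variation of information from an explicitly built contingency table."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = a.size
    ua, ub = np.unique(a), np.unique(b)
    P = np.array([[np.sum((a == g) & (b == h)) / n for h in ub] for g in ua])
    pa, pb = P.sum(axis=1), P.sum(axis=0)
    h_a = -sum(p * np.log(p) for p in pa if p > 0)
    h_b = -sum(p * np.log(p) for p in pb if p > 0)
    mi = 0.0
    for i in range(len(ua)):
        for j in range(len(ub)):
            if P[i, j] > 0:
                mi += P[i, j] * np.log(P[i, j] / (pa[i] * pb[j]))
    return h_a + h_b - 2 * mi


def hypergeom_minlike_p(a, b, c, d) -> float:
    """Two-sided minimum-likelihood Fisher p for a 2x2 table, directly.

    Enumerates the hypergeometric support and sums probabilities no larger
    than the observed table's.
    """
    r1, c1 = a + b, a + c
    n = a + b + c + d

    def logp(x):
        return (
            lgamma(c1 + 1) - lgamma(x + 1) - lgamma(c1 - x + 1)
            + lgamma(n - c1 + 1) - lgamma(r1 - x + 1) - lgamma(n - c1 - (r1 - x) + 1)
            - (lgamma(n + 1) - lgamma(r1 + 1) - lgamma(n - r1 + 1))
        )

    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    probs = {x: np.exp(logp(x)) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)), 1.0)


def spearman_brute(x, y) -> float:
    """Spearman rho as Pearson on midranks, computed longhand."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def midrank(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(v.size)
        i = 0
        sv = v[order]
        while i < v.size:
            j = i
            while j + 1 < v.size and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midrank(x), midrank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def twoway_interaction_f_balanced(y, a, b) -> float:
    """Textbook interaction F for a balanced two-way layout (cell means)."""
    y = np.asarray(y, dtype=float)
    a = np.asarray(a)
    b = np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    r = len(ua)
    c = len(ub)
    nc = y.size // (r * c)
    grand = y.mean()
    cell = np.array([[y[(a == g) & (b == h)].mean() for h in ub] for g in ua])
    am = np.array([y[a == g].mean() for g in ua])
    bm = np.array([y[b == h].mean() for h in ub])
    ss_int = nc * sum(
        (cell[i, j] - am[i] - bm[j] + grand) ** 2
        for i in range(r)
        for j in range(c)
    )
    ss_err = sum(
        ((y[(a == g) & (b == h)] - cell[i, j]) ** 2).sum()
        for i, g in enumerate(ua)
        for j, h in enumerate(ub)
    )
    df_int = (r - 1) * (c - 1)
    df_err = y.size - r * c
    return (ss_int / df_int) / (ss_err / df_err)
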
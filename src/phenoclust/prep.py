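"""Task-data preparation.

Raw behavioural measures are positively skewed and live on disparate physical
scales, so before clustering each variable is (1) 95%-winsorized if it can
contain infinite sentinels, (2) power-transformed toward normality (Box-Cox
when strictly positive, Yeo-Johnson otherwise), and (3) centered and scaled.
An optional covariate-adjusted path replaces step (3) with residualisation on
diagnosis-by-covariate interaction terms before standardisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

TASK_COLUMNS = [
    "net_distance",
    "net_spatial_d",
    "net_visobj_count",
    "net_visobj_time",
    "net_tacobj_count",
    "net_tacobj_time",
    "apt_active_time",
    "apt_switches",
    "apt_active_intensity",
    "apt_active_persistence",
]

__all__ = [
    "TASK_COLUMNS",
    "TransformSpec",
    "PreparedMatrix",
    "winsorize",
    "fit_power_transform",
    "apply_power_transform",
    "standardize",
    "knn_impute",
    "covariate_adjust",
    "prepare_task_matrix",
]


@dataclass
class TransformSpec:
    """Per-variable power transform and standardisation parameters."""

    name: str
    family: str  # "box_cox" | "yeo_johnson"
    lmbda: float
    center: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("box_cox", "yeo_johnson"):
            raise ValueError(f"unknown transform family {self.family!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class PreparedMatrix:
    """Transformed, standardized n x p task matrix with its metadata."""

    values: np.ndarray  # NaN marks missing
    columns: list
    specs: list  # list[TransformSpec]
    row_ids: list
    adjusted: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.columns)

    def specs_json(self) -> str:
        return json.dumps([asdict(s) for s in self.specs], indent=2)


# ---------------------------------------------------------------------------


def winsorize(values: Sequence[float], coverage: float = 0.95) -> np.ndarray:
    """95% winsorization tolerant of ±infinity sentinels.

    Infinite entries are first replaced by one unit beyond the extreme finite
    order statistics so they possess a defined rank, then every value is
    clipped to the ``[(1-coverage)/2, 1-(1-coverage)/2]`` linear-interpolation
    (type 7) quantiles of the resulting vector.  NaNs pass through untouched.
    """
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must lie in (0, 1)")
    x = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("winsorize needs at least 3 finite values")
    hi, lo = x[finite].max(), x[finite].min()
    x[np.isposinf(x)] = hi + 1.0
    x[np.isneginf(x)] = lo - 1.0
    obs = ~np.isnan(x)
    q = (1.0 - coverage) / 2.0
    lo_b, hi_b = np.quantile(x[obs], [q, 1.0 - q], method="linear")
    x[obs] = np.clip(x[obs], lo_b, hi_b)
    return x


def _boxcox(y: np.ndarray, lmbda: float) -> np.ndarray:
    if abs(lmbda) < 1e-12:
        return np.log(y)
    return (np.power(y, lmbda) - 1.0) / lmbda


def _yeojohnson(y: np.ndarray, lmbda: float) -> np.ndarray:
    out = np.empty_like(y, dtype=float)
    pos = y >= 0
    if abs(lmbda) < 1e-12:
        out[pos] = np.log1p(y[pos])
    else:
        out[pos] = (np.power(y[pos] + 1.0, lmbda) - 1.0) / lmbda
    if abs(lmbda - 2.0) < 1e-12:
        out[~pos] = -np.log1p(-y[~pos])
    else:
        out[~pos] = -(np.power(1.0 - y[~pos], 2.0 - lmbda) - 1.0) / (2.0 - lmbda)
    return out


def apply_power_transform(values: Sequence[float], spec: TransformSpec) -> np.ndarray:
    """Apply a fitted power transform; NaN entries pass through."""
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    obs = ~np.isnan(x)
    f = _boxcox if spec.family == "box_cox" else _yeojohnson
    out[obs] = f(x[obs], spec.lmbda)
    return out


def _profile_negloglik(
    lmbda: float, y: np.ndarray, design: np.ndarray | None, family: str
) -> float:
    """Negative profile log-likelihood of the transformed-response linear model.

    The transformation parameter aims to normalise the residuals of the
    regression of the transformed response on the predictors; with no
    predictors the model is intercept-only.
    """
    n = y.size
    z = _boxcox(y, lmbda) if family == "box_cox" else _yeojohnson(y, lmbda)
    X = np.ones((n, 1)) if design is None else design
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    rss = float(np.sum((z - X @ beta) ** 2))
    if rss <= 0:
        rss = 1e-300
    ll = -0.5 * n * np.log(rss / n)
    if family == "box_cox":
        ll += (lmbda - 1.0) * np.sum(np.log(y))
    else:
        ll += (lmbda - 1.0) * np.sum(np.sign(y) * np.log1p(np.abs(y)))
    return -ll


def fit_power_transform(
    values: Sequence[float],
    design: np.ndarray | None = None,
    name: str = "",
    family: str | None = None,
    bounds: tuple[float, float] = (-2.0, 2.0),
) -> TransformSpec:
    """Estimate the power-transform parameter by profile maximum likelihood.

    ``family=None`` selects Box-Cox when all training values are strictly
    positive, Yeo-Johnson otherwise.  ``design`` is an optional full design
    matrix (including intercept); the likelihood then targets normality of the
    regression residuals.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    if not np.isfinite(x[obs]).all():
        raise ValueError("winsorize infinite values before transforming")
    y = x[obs]
    if y.size < 10:
        raise ValueError("need at least 10 non-missing values")
    if family is None:
        family = "box_cox" if np.all(y > 0) else "yeo_johnson"
    if family == "box_cox" and not np.all(y > 0):
        raise ValueError("Box-Cox requires strictly positive values")
    D = None
    if design is not None:
        D = np.asarray(design, dtype=float)[obs]
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError("singular covariate design")
    res = minimize_scalar(
        _profile_negloglik,
        bounds=bounds,
        args=(y, D, family),
        method="bounded",
        options={"xatol": 1e-5},
    )
    return TransformSpec(name=name, family=family, lmbda=float(res.x))


def standardize(
    matrix: np.ndarray,
    columns: Sequence[str] | None = None,
    specs: Sequence[TransformSpec] | None = None,
    row_ids: Sequence | None = None,
    adjusted: bool = False,
) -> PreparedMatrix:
    """Center/scale columns over their non-missing entries (sample SD, n-1).

    When ``specs`` is given their ``center``/``scale`` slots are filled in so
    the same affine map can be reused on reference or bootstrap data.
    """
    M = np.asarray(matrix, dtype=float).copy()
    n, p = M.shape
    columns = list(columns) if columns is not None else [f"x{j}" for j in range(p)]
    if specs is None:
        specs = [TransformSpec(name=c, family="yeo_johnson", lmbda=1.0) for c in columns]
    specs = list(specs)
    for j in range(p):
        col = M[:, j]
        obs = ~np.isnan(col)
        mu = col[obs].mean()
        sd = col[obs].std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"zero-variance column {columns[j]!r}")
        M[obs, j] = (col[obs] - mu) / sd
        specs[j].center = float(mu)
        specs[j].scale = float(sd)
    ids = list(row_ids) if row_ids is not None else list(range(n))
    return PreparedMatrix(values=M, columns=columns, specs=specs, row_ids=ids, adjusted=adjusted)


def knn_impute(matrix: np.ndarray, k: int = 5) -> np.ndarray:
    """Distance-weighted k-nearest-neighbour imputation from complete rows.

    Distances are Euclidean over the mutually observed columns; neighbour
    weights are ``exp(-d)``.  Used only for the sparsity-tuning permutation
    path — the main clustering input keeps its missing cells.
    """
    M = np.asarray(matrix, dtype=float).copy()
    miss = np.isnan(M)
    if not miss.any():
        return M
    complete = ~miss.any(axis=1)
    if not complete.any():
        raise ValueError("kNN imputation needs at least one complete row")
    if k > complete.sum():
        raise ValueError("k exceeds the number of complete rows")
    C = M[complete]
    for i in np.nonzero(miss.any(axis=1))[0]:
        obs = ~miss[i]
        if not obs.any():
            raise ValueError("row with no observed cells")
        d = np.sqrt(((C[:, obs] - M[i, obs]) ** 2).sum(axis=1))
        nn = np.argsort(d, kind="stable")[:k]
        w = np.exp(-d[nn])
        if w.sum() <= 0:
            w = np.ones_like(w)
        for j in np.nonzero(miss[i])[0]:
            M[i, j] = float(np.average(C[nn, j], weights=w))
    return M


def interaction_design(
    diagnosis: Sequence[str], covariate_table: pd.DataFrame
) -> tuple[np.ndarray, list]:
    """Common intercept + diagnosis-by-covariate interaction columns.

    Group-specific slopes are estimated with no diagnosis main effect;
    covariates measured only in one group are zero-filled in the other before
    the model fit, so the all-zero interaction column is dropped.
    """
    dx = np.asarray(diagnosis)
    cols: list[np.ndarray] = [np.ones(len(dx))]
    names = ["intercept"]
    for name in covariate_table.columns:
        v = covariate_table[name].to_numpy(dtype=float)
        if np.isnan(v[dx == "SZ"]).any():
            raise ValueError(f"covariate {name!r} missing for an SZ row")
        v = np.where(np.isnan(v), 0.0, v)
        for g in ("SZ", "HC"):
            col = v * (dx == g)
            if np.any(col != 0):
                cols.append(col)
                names.append(f"{name}:{g}")
    D = np.column_stack(cols)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("collinear covariate design")
    return D, names


def covariate_adjust(
    table: pd.DataFrame,
    covariates: Sequence[str],
    task_columns: Sequence[str] = TASK_COLUMNS,
    winsorize_columns: Sequence[str] = ("apt_active_persistence",),
) -> PreparedMatrix:
    """Covariate-adjusted preparation of the task matrix.

    Per task variable: fit the power-transform parameter against the
    diagnosis-by-covariate interaction design, regress the transformed
    variable on the same design, keep the residuals, then center and scale.
    An empty covariate list reproduces the unadjusted pipeline (the design
    collapses to the intercept-only null model).
    """
    covariates = list(covariates)
    for c in covariates:
        if c not in table.columns:
            raise ValueError(f"missing covariate column {c!r}")
    if covariates:
        D, _ = interaction_design(table["diagnosis"], table[covariates])
    else:
        D = None
    M = np.empty((len(table), len(task_columns)))
    specs: list[TransformSpec] = []
    for j, name in enumerate(task_columns):
        x = table[name].to_numpy(dtype=float)
        if name in winsorize_columns:
            x = winsorize(x)
        spec = fit_power_transform(x, design=D, name=name)
        z = apply_power_transform(x, spec)
        obs = ~np.isnan(z)
        if D is not None:
            Do = D[obs]
            beta, *_ = np.linalg.lstsq(Do, z[obs], rcond=None)
            z[obs] = z[obs] - Do @ beta
        M[:, j] = z
        specs.append(spec)
    ids = list(table["participant_id"]) if "participant_id" in table else list(table.index)
    return standardize(M, columns=list(task_columns), specs=specs, row_ids=ids,
                       adjusted=bool(covariates))


def prepare_task_matrix(
    table: pd.DataFrame,
    task_columns: Sequence[str] = TASK_COLUMNS,
) -> PreparedMatrix:
    """Unadjusted preparation: winsorize sentinels, transform, standardize."""
    return covariate_adjust(table, covariates=[], task_columns=task_columns)
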
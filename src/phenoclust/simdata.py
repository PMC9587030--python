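"""Synthetic cohort generation.

Real participant-level data from the motivating study are not publicly
deposited, so every downstream stage is exercised on synthetic cohorts that
reproduce the statistical structure the analysis assumes: a planted
three-cluster geometry in the ten task measures (Low Exploration / Low
Activity / High Performance), positively skewed task variables in their
physical ranges, a diagnosis-by-cluster composition near the study's counts,
clinical scales with planted cluster main effects (AES) and
diagnosis-by-cluster interactions (AES, PSP), SZ-only covariates, block-wise
missingness mimicking marker failure, and infinite-persistence sentinels.

Task variables are generated on a latent Gaussian scale and mapped through
exponential / logistic / affine links into their physical ranges; counts are
rounded and clipped.  This guarantees the positive skew that motivates the
Box-Cox step downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prep import TASK_COLUMNS

__all__ = ["CohortSpec", "generate_cohort", "inject_missingness", "write_cohort_csv"]

CLUSTERS = ["LE", "LA", "HP"]

# Latent performance offsets per cluster on the two task dimensions
# (NET = exploration, APT = activity), in units of `separation`.
# LE: low exploration, intermediate activity; LA: the reverse; HP: high both.
_CLUSTER_GEOMETRY = {
    "LE": {"NET": -0.6, "APT": 0.0},
    "LA": {"NET": 0.0, "APT": -0.6},
    "HP": {"NET": 0.6, "APT": 0.6},
}

# NET object-exploration block lost when the head marker fails; APT block lost
# when the task recording fails.
NET_EXPLORATION_BLOCK = [
    "net_visobj_count",
    "net_visobj_time",
    "net_tacobj_count",
    "net_tacobj_time",
]
APT_BLOCK = [
    "apt_active_time",
    "apt_switches",
    "apt_active_intensity",
    "apt_active_persistence",
]


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults mirror the study sample: 45 SZ and 47 HC participants, cluster
    proportions 39/23/30 of 92 with SZ shares 20/39, 15/23 and 10/30, and
    moderately separated clusters (centers ``separation`` latent SD apart on
    the defining dimension).  ``clinical_effects`` are in outcome-SD units.
    """

    n_sz: int = 45
    n_hc: int = 47
    cluster_proportions: tuple = (39 / 92, 23 / 92, 30 / 92)
    composition: tuple = (20 / 39, 15 / 23, 10 / 30)
    separation: float = 2.0
    skew: float = 1.0
    noise_sd: float = 1.0
    clinical_effects: dict = field(
        default_factory=lambda: {
            "aes_cluster": 0.8,        # LE/LA elevation vs HP (SD units)
            "aes_interaction": 1.0,    # extra SZ-HC gap in LE and HP
            "psp_interaction": 1.15,   # SZ-HC gap widening HP -> LA -> LE
        }
    )
    missing_rate: float = 0.02
    n_inf_persistence: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sz < 0 or self.n_hc < 0:
            raise ValueError("negative participant counts")
        props = np.asarray(self.cluster_proportions, dtype=float)
        if props.size != 3 or (props < 0).any() or abs(props.sum() - 1.0) > 1e-12:
            raise ValueError("cluster_proportions must be 3 non-negative weights summing to 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of `total` by weights, largest-remainder rule."""
    raw = weights * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def _allocate_cells(spec: CohortSpec) -> dict:
    """Per-(cluster, diagnosis) counts honouring sizes and SZ shares."""
    n = spec.n_sz + spec.n_hc
    sizes = _largest_remainder(n, np.asarray(spec.cluster_proportions))
    sz = np.minimum(
        _largest_remainder(
            spec.n_sz,
            np.asarray(spec.composition) * sizes / max((np.asarray(spec.composition) * sizes).sum(), 1e-12),
        ),
        sizes,
    )
    # repair rounding drift so SZ counts sum to n_sz and stay within sizes
    drift = spec.n_sz - sz.sum()
    i = 0
    while drift != 0 and i < 100:
        for c in range(3):
            if drift > 0 and sz[c] < sizes[c]:
                sz[c] += 1
                drift -= 1
            elif drift < 0 and sz[c] > 0:
                sz[c] -= 1
                drift += 1
        i += 1
    return {CLUSTERS[c]: (int(sz[c]), int(sizes[c] - sz[c])) for c in range(3)}


def _latent_scores(
    spec: CohortSpec,
    cluster: np.ndarray,
    rng: np.random.Generator,
    age: np.ndarray | None = None,
    sz_mask: np.ndarray | None = None,
) -> dict:
    """Latent per-dimension performance score per participant per variable.

    An optional SZ-specific age effect (``clinical_effects['age_task_effect']``,
    latent SD per age SD) depresses exploration scores with age, emulating the
    illness-chronicity correlates the covariate-adjusted rerun must remove.
    """
    n = cluster.size
    age_eff = spec.clinical_effects.get("age_task_effect", 0.0)
    age_z = np.zeros(n)
    if age_eff and age is not None and sz_mask is not None:
        age_z = -age_eff * ((age - age.mean()) / max(age.std(), 1e-9)) * sz_mask
    z = {}
    for var in TASK_COLUMNS:
        dim = "NET" if var.startswith("net") else "APT"
        offset = np.array([_CLUSTER_GEOMETRY[c][dim] for c in cluster]) * spec.separation
        z[var] = offset + age_z + rng.normal(0.0, spec.noise_sd, size=n)
    return z


def _map_to_physical(z: dict, spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Latent performance -> physical task measures (study medians / ranges)."""
    s = spec.skew

    def expit(v):
        return 1.0 / (1.0 + np.exp(-v))

    out = {}
    out["net_distance"] = np.exp(4.6 + 0.7 * s * z["net_distance"])
    # spatial d: lower = more linear = better exploration; bounded (1, 2)
    out["net_spatial_d"] = 1.0 + expit(0.8 * s * (-z["net_spatial_d"]) - 0.8)
    out["net_visobj_count"] = np.clip(
        np.round(10.0 * expit(0.35 * z["net_visobj_count"] + 0.45)), 0, 10
    )
    out["net_visobj_time"] = np.clip(np.exp(4.5 + 0.8 * s * z["net_visobj_time"]), 0.0, 900.0)
    out["net_tacobj_count"] = np.clip(
        np.round(np.exp(0.5 + 0.8 * s * z["net_tacobj_count"]) - 0.5), 0, 10
    )
    out["net_tacobj_time"] = np.clip(np.exp(1.8 + 1.1 * s * z["net_tacobj_time"]), 0.0, 900.0)
    out["apt_active_time"] = 900.0 * expit(0.55 * z["apt_active_time"] + 0.3)
    # more switching = less sustained engagement, hence the reversed latent
    out["apt_switches"] = np.clip(np.round(np.exp(2.0 + 0.55 * s * (-z["apt_switches"]))), 0, None)
    out["apt_active_intensity"] = np.exp(0.2 + 0.5 * s * z["apt_active_intensity"])
    out["apt_active_persistence"] = np.exp(1.3 + 0.35 * s * z["apt_active_persistence"])
    df = pd.DataFrame(out)
    # a count of zero forces the paired duration to zero
    df.loc[df["net_visobj_count"] == 0, "net_visobj_time"] = 0.0
    df.loc[df["net_tacobj_count"] == 0, "net_tacobj_time"] = 0.0
    return df


def _clinical_columns(
    spec: CohortSpec, cluster: np.ndarray, dx: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    n = cluster.size
    sz = (dx == "SZ").astype(float)
    eff = spec.clinical_effects
    is_le = (cluster == "LE").astype(float)
    is_la = (cluster == "LA").astype(float)
    low = is_le + is_la

    out = {}
    # AES (apathy, higher = worse): baseline SZ shift, low-performance
    # elevation, and a diagnosis-by-cluster interaction concentrated in LE
    # and (more weakly) HP; the default magnitudes reproduce within-cluster
    # SZ-HC gaps of roughly 11 / 4 / 6 points in LE / LA / HP.
    aes_sd = 6.0
    aes_inter = eff.get("aes_interaction", 0.0) * (1.2 * is_le + 0.4 * (cluster == "HP"))
    out["AES"] = (
        24.0
        + 3.8 * sz
        + eff.get("aes_cluster", 0.0) * aes_sd * low
        + aes_inter * aes_sd * sz
        + rng.normal(0, 0.8 * aes_sd, n)
    )
    # PSP (functioning, higher = better): SZ deficit widening HP -> LA -> LE,
    # defaults matching gaps of roughly -15 / -22 / -32 points.
    psp_sd = 12.0
    widen = 1.2 * is_le + 0.6 * is_la  # HP contributes 0
    out["PSP"] = np.clip(
        80.0
        - sz * (15.0 + eff.get("psp_interaction", 0.0) * psp_sd * widen)
        + rng.normal(0, 0.7 * psp_sd, n),
        1,
        100,
    )
    out["BACS_z"] = -1.1 * sz + 0.45 * (1 - sz) + rng.normal(0, 0.9, n)
    out["SFS"] = 122.0 - 8.5 * sz + rng.normal(0, 6.5, n)
    out["TEPS_ant"] = 45.0 + rng.normal(0, 7.0, n)
    out["TEPS_con"] = 38.0 + 2.0 * (cluster == "HP") + rng.normal(0, 5.0, n)
    out["BIS"] = 53.0 + 10.0 * sz + 3.0 * is_la + rng.normal(0, 8.0, n)
    out["BAI"] = np.clip(3.0 + 6.0 * sz + 3.0 * is_la + rng.normal(0, 5.0, n), 0, 63)
    for trait, mu in [
        ("BFI_extraversion", 25.0),
        ("BFI_agreeableness", 37.0),
        ("BFI_conscientiousness", 34.0),
        ("BFI_neuroticism", 21.0),
        ("BFI_openness", 36.0),
    ]:
        out[trait] = mu + rng.normal(0, 5.0, n)
    out["DPB"] = 35.0 + 6.0 * sz + rng.normal(0, 13.0, n)
    out["novelty_score"] = np.clip(np.round(10.0 + 3.0 * sz + rng.normal(0, 4.0, n)), 0, 40)
    out["interest_score"] = np.clip(np.round(13.0 + 2.0 * sz + rng.normal(0, 4.5, n)), 0, 40)
    out["finger_tapping"] = 57.0 - 5.0 * sz + rng.normal(0, 6.0, n)
    # SZ-only symptom scales
    sans = np.where(sz == 1, np.clip(16.0 + rng.normal(0, 9.0, n), 0, 100), np.nan)
    out["SANS_total"] = sans
    out["SANS_amot"] = np.where(sz == 1, np.clip(12.0 + rng.normal(0, 6.0, n), 0, 60), np.nan)
    return pd.DataFrame(out)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a synthetic participant table.

    The returned frame has one row per participant with diagnosis,
    demographics, SZ-only covariates, clinical scales, the 10 task measures
    and the planted ``true_cluster`` label.  Reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cells = _allocate_cells(spec)
    cluster = np.concatenate(
        [np.repeat(c, n_sz + n_hc) for c, (n_sz, n_hc) in cells.items()]
    )
    dx = np.concatenate(
        [np.repeat(["SZ", "HC"], [n_sz, n_hc]) for _, (n_sz, n_hc) in cells.items()]
    )
    order = rng.permutation(cluster.size)
    cluster, dx = cluster[order], dx[order]
    n = cluster.size

    sz_mask = dx == "SZ"
    age = np.clip(np.round(rng.normal(34, 10, n)), 18, 55)
    z = _latent_scores(spec, cluster, rng, age=age, sz_mask=sz_mask)
    tasks = _map_to_physical(z, spec, rng)
    clinical = _clinical_columns(spec, cluster, dx, rng)
    illness = np.where(sz_mask, np.round(np.exp(2.1 + 0.7 * rng.normal(0, 1, n))), np.nan)
    illness = np.where(sz_mask, np.clip(illness, 1, age - 16), np.nan)
    cpz = np.where(sz_mask, np.round(np.exp(6.1 + 0.5 * rng.normal(0, 1, n))), np.nan)

    table = pd.DataFrame(
        {
            "participant_id": [f"P{i:03d}" for i in range(n)],
            "diagnosis": dx,
            "sex": rng.choice(["F", "M"], size=n, p=[0.4, 0.6]),
            "age": age,
            "illness_duration": illness,
            "cpz": cpz,
        }
    )
    table = pd.concat([table, clinical, tasks], axis=1)
    table["true_cluster"] = cluster
    return table


def inject_missingness(table: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Plant block-wise missingness and infinite-persistence sentinels.

    Marker failure loses whole task blocks, never lone cells: selected rows
    lose the four NET object-exploration columns jointly, others lose the four
    APT columns jointly.  ``spec.n_inf_persistence`` rows (APT observed)
    receive alternating +inf / -inf active-persistence sentinels, emulating
    participants who engaged exclusively in one option.
    """
    out = table.copy()
    rng = np.random.default_rng(spec.seed + 1)
    n = len(out)
    n_missing = int(round(spec.missing_rate * n))
    if n_missing > 0:
        rows = rng.choice(n, size=n_missing, replace=False)
        half = n_missing // 2
        out.iloc[rows[:half], [out.columns.get_loc(c) for c in NET_EXPLORATION_BLOCK]] = np.nan
        out.iloc[rows[half:], [out.columns.get_loc(c) for c in APT_BLOCK]] = np.nan
    if spec.n_inf_persistence > 0:
        apt_ok = out["apt_active_persistence"].notna().to_numpy()
        candidates = np.nonzero(apt_ok)[0]
        picks = rng.choice(candidates, size=spec.n_inf_persistence, replace=False)
        signs = [np.inf if i % 2 == 0 else -np.inf for i in range(spec.n_inf_persistence)]
        out.iloc[picks, out.columns.get_loc("apt_active_persistence")] = signs
    return out


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """RFC-4180 CSV, UTF-8, header row, empty missing cells, inf as inf/-inf."""
    table.to_csv(path, index=False, na_rep="", encoding="utf-8", lineterminator="\n")
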
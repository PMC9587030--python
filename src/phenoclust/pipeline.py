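"""End-to-end analysis orchestration.

`run_primary` executes the full analysis on a cohort table: preparation,
sparse k-means with a consensus-selected number of clusters, bootstrap
stability, diagnosis/cluster inference and the correlation screen.  The
supplementary reruns (`run_groups_separated`, `run_covariate_adjusted`)
re-cluster weight-transformed group subsets and covariate-adjusted data and
quantify disagreement with the original partition.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import spearman_matrix
from .clusterstats import boot_oneway_anova, boot_twoway_interaction, within_cluster_group_contrasts
from .clusterval import bootstrap_stability, compare_partitions
from .groupstats import fisher_exact, odds_ratio_cmle
from .kselect import clest, gap_curves, make_sparse_clusterer, select_k_consensus
from .prep import TASK_COLUMNS, covariate_adjust, prepare_task_matrix
from .simdata import CohortSpec, generate_cohort, inject_missingness
from .spkmeans import SparseKMeansConfig, sparse_kmeans

__all__ = ["PipelineConfig", "run_primary", "run_groups_separated", "run_covariate_adjusted"]

CLINICAL_PRIMARY = ["AES", "BACS_z", "PSP", "SFS"]


@dataclass
class PipelineConfig:
    """Budgets and choices of one pipeline run.

    Defaults are desk-scale; ``published_scale()`` restores the 50,000/2,000-fold
    resampling budgets of the published analysis.
    """

    k_min: int = 2
    k_max: int = 10
    k_fallback: int = 3
    l: float | None = None  # None = non-binding sqrt(p)
    n_start: int = 50
    B_gap: int = 50
    clest_B_obs: int = 200
    clest_B_ref: int = 100
    clest_B_ref_splits: int = 100
    B_stability: int = 200
    B_boot: int = 2000
    n_perm: int = 2000
    covariates: tuple = ("age", "illness_duration", "cpz")
    seed: int = 0
    select_k: bool = True
    forced_k: int | None = None

    @classmethod
    def published_scale(cls, **overrides) -> "PipelineConfig":
        base = dict(
            n_start=1000,
            B_gap=2000,
            clest_B_obs=2000,
            clest_B_ref=2000,
            clest_B_ref_splits=500,
            B_stability=2000,
            B_boot=50000,
            n_perm=50000,
        )
        base.update(overrides)
        return cls(**base)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_table(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    if isinstance(source, CohortSpec):
        return inject_missingness(generate_cohort(source), source)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path)


def _select_k(prepared, config: PipelineConfig, rng: np.random.Generator) -> dict:
    k_range = range(config.k_min, config.k_max + 1)
    clusterer = make_sparse_clusterer(l=config.l, n_start=min(config.n_start, 20))
    gap, wgap = gap_curves(prepared.values, k_range, config.B_gap, clusterer, seed=rng)
    clest_rep = clest(
        prepared.values,
        k_range,
        clusterer,
        B_obs=config.clest_B_obs,
        B_ref=config.clest_B_ref,
        B_ref_splits=config.clest_B_ref_splits,
        seed=rng,
    )
    consensus = select_k_consensus(gap, wgap, clest_rep)
    return {
        "gap": gap,
        "wgap": wgap,
        "clest": clest_rep,
        "consensus": consensus,
    }


def run_primary(source, config: PipelineConfig | None = None, outdir=None) -> dict:
    """Full analysis: prep, clustering, stability, inference, correlations."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed)
    table = _load_table(source)
    prepared = prepare_task_matrix(table)

    report: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    if config.forced_k is not None:
        k = config.forced_k
        report["k_selection"] = {"forced": k}
    elif config.select_k:
        sel = _select_k(prepared, config, rng)
        k = sel["consensus"]["chosen_k"]
        report["k_selection"] = {
            "votes": sel["consensus"]["votes"],
            "consensus": sel["consensus"]["consensus"],
            "gap_curve": sel["gap"].gap.tolist(),
            "wgap_curve": sel["wgap"].gap.tolist(),
        }
        if k is None:
            report["k_selection"]["note"] = (
                f"no consensus; continuing with configured fallback k={config.k_fallback}"
            )
            k = config.k_fallback
    else:
        k = config.k_fallback
        report["k_selection"] = {"forced": k}

    cfg = SparseKMeansConfig(k=k, l=config.l, n_start=config.n_start, seed=rng)
    solution = sparse_kmeans(prepared.values, cfg)
    report["k"] = k
    report["weights"] = dict(zip(prepared.columns, solution.weights.round(6).tolist()))
    report["cluster_sizes"] = np.bincount(solution.labels, minlength=k).tolist()

    stability = bootstrap_stability(
        prepared.values, solution, B=config.B_stability, seed=rng, n_start=min(config.n_start, 20)
    )
    report["stability"] = stability.to_dict()

    dx = table["diagnosis"].to_numpy()
    counts = np.array(
        [[np.sum((dx == g) & (solution.labels == c)) for c in range(k)] for g in ("SZ", "HC")]
    )
    report["diagnosis_by_cluster"] = counts.tolist()
    report["fisher_allocation_p"] = fisher_exact(counts).p_value

    clinical = {}
    for meas in CLINICAL_PRIMARY:
        y = table[meas].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        res = boot_oneway_anova(y[ok], solution.labels[ok], B=config.B_boot, seed=rng)
        entry = {"F": res.value, "P": res.p_parametric, "P_boot": res.p_empirical}
        if np.unique(dx[ok]).size == 2 and all(
            np.unique(dx[ok & (solution.labels == c)]).size == 2 for c in range(k)
        ):
            inter = boot_twoway_interaction(
                y[ok], dx[ok], solution.labels[ok], B=config.B_boot, seed=rng
            )
            entry["interaction_F"] = inter.value
            entry["interaction_P_boot"] = inter.p_empirical
            contrasts = within_cluster_group_contrasts(
                y[ok], dx[ok], solution.labels[ok], B=min(config.B_boot, 5000), seed=rng
            )
            entry["within_cluster_sz_hc"] = [
                {"cluster": int(c.pair[0]), "delta": c.delta_mean, "ci": list(c.ci)}
                for c in contrasts
            ]
        clinical[meas] = entry
    report["clinical"] = clinical

    corr = spearman_matrix(table[TASK_COLUMNS], table[CLINICAL_PRIMARY])
    report["correlations"] = [
        {"x": r.x, "y": r.y, "rho": r.rho, "n": r.n, "p": r.p, "q": r.q} for r in corr
    ]

    report["_solution"] = solution
    report["_prepared"] = prepared
    report["_table"] = table
    if outdir is not None:
        _write_reports(report, config, Path(outdir))
    return report


def run_groups_separated(source, original: dict, config: PipelineConfig | None = None) -> dict:
    """Re-cluster the weight-transformed matrix separately per diagnosis."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed + 1)
    table = original["_table"]
    prepared = original["_prepared"]
    solution = original["_solution"]
    Xw = prepared.values * np.sqrt(solution.weights)
    out: dict = {}
    for g in ("SZ", "HC"):
        rows = (table["diagnosis"] == g).to_numpy()
        Xg = Xw[rows]
        k = solution.k
        if rows.sum() <= k:
            raise ValueError(f"group {g} too small for k={k}")
        # weights already folded into the matrix: cluster with uniform weights
        cfg = SparseKMeansConfig(k=k, l=None, n_start=config.n_start, seed=rng)
        sol_g = sparse_kmeans(Xg, cfg)
        comparison = compare_partitions(sol_g.labels, solution.labels[rows])
        stab = bootstrap_stability(Xg, sol_g, B=config.B_stability, seed=rng,
                                   n_start=min(config.n_start, 20))
        out[g] = {
            "cluster_sizes": np.bincount(sol_g.labels, minlength=k).tolist(),
            "cer_vs_original": comparison.cer,
            "vi_vs_original": comparison.vi,
            "stability": stab.to_dict(),
        }
    return out


def run_covariate_adjusted(source, original: dict, config: PipelineConfig | None = None) -> dict:
    """Covariate-adjusted re-preparation, re-clustering and re-testing."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed + 2)
    table = original["_table"]
    solution = original["_solution"]
    for c in config.covariates:
        if c not in table.columns:
            raise ValueError(f"missing covariate column {c!r}")
    prepared = covariate_adjust(table, list(config.covariates))
    cfg = SparseKMeansConfig(k=solution.k, l=config.l, n_start=config.n_start, seed=rng)
    adj = sparse_kmeans(prepared.values, cfg)
    comparison = compare_partitions(adj.labels, solution.labels)
    out: dict = {
        "cer_vs_original": comparison.cer,
        "vi_vs_original": comparison.vi,
        "cluster_sizes": np.bincount(adj.labels, minlength=adj.k).tolist(),
    }
    # covariate differences across the new clusters should be redressed
    cov_tests = {}
    for cov in config.covariates:
        v = table[cov].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        labels_ok = adj.labels[ok]
        if np.unique(labels_ok).size < 2 or min(np.bincount(labels_ok)) < 2:
            continue
        res = boot_oneway_anova(v[ok], labels_ok, B=config.B_boot, seed=rng)
        cov_tests[cov] = {"F": res.value, "P_boot": res.p_empirical}
    out["covariate_tests"] = cov_tests
    clin = {}
    for meas in CLINICAL_PRIMARY:
        y = table[meas].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        res = boot_oneway_anova(y[ok], adj.labels[ok], B=config.B_boot, seed=rng)
        clin[meas] = {"F": res.value, "P_boot": res.p_empirical}
    out["clinical_tests"] = clin
    out["_solution"] = adj
    return out


def _write_reports(report: dict, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    public = {k: v for k, v in report.items() if not k.startswith("_")}
    (outdir / "report.json").write_text(json.dumps(public, indent=2, default=str))
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    pd.DataFrame(report["correlations"]).to_csv(outdir / "correlations.csv", index=False)
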
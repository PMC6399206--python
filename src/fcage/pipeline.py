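"""End-to-end orchestration: simulate -> connectome -> decompose -> lifespan
-> features -> predict -> permute, with a collated JSON report.

Stages run in DAG order, each consuming only upstream outputs; everything is
deterministic given the config seeds.  The report collects the explained-
variance curve, top component-age correlations, trajectory class counts, the
model x feature metric grid with external validation, and significant-edge
counts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectome as cn
from . import components as cp
from . import lifespan as ls
from . import synthetic as syn
from .features import (
    EdgeFeaturePipeline,
    NetworkFeaturePipeline,
    TemporalFeaturePipeline,
)
from .prediction import (
    ModelSpec,
    external_validate,
    fit_full,
    kfold_validate,
)
from .significance import PermutationConfig, network_weight_aggregation, permutation_test


@dataclass
class PipelineConfig:
    # cohort scale
    n_internal: int = 200
    n_external: int = 80
    n_nodes: int = 50
    n_volumes_internal: int = 600
    n_volumes_external: int = 160
    tr_internal: float = 0.645
    tr_external: float = 2.5
    seed: int = 7
    # analysis
    n_components: int = 150
    feature_methods: tuple = ("network", "edge", "temporal")
    model_families: tuple = ("ols", "lasso", "svr")
    K: int = 10
    leakage_mode: str = "strict"
    q: float = 0.05
    permutation_B: int = 300
    permutation_alpha: float = 0.01
    # significance is tested through the leading supervised component: the
    # deeper components fit residual noise in real and permuted data alike
    # and only dilute the per-edge null at desk-scale n
    permutation_l: int = 1
    run_lifespan: bool = True
    run_permutation: bool = True
    out_dir: str | None = None


def _falff_bands(tr_seconds: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Default fALFF bands, with the total band capped at Nyquist.

    A slow acquisition (e.g. TR = 2.5 s, Nyquist 0.2 Hz) cannot observe the
    nominal 0.01-0.25 Hz total band; the cap keeps the estimator defined
    while the low band stays at 0.01-0.1 Hz.
    """
    nyq = 0.5 / tr_seconds
    return (0.01, 0.1), (0.01, min(0.25, nyq))


def _pipeline_factory(method: str, cfg: PipelineConfig):
    if method == "network":
        return lambda: NetworkFeaturePipeline(L=cfg.n_components)
    if method == "edge":
        return lambda: EdgeFeaturePipeline(l=(5, 10, 20, 40), seed=cfg.seed)
    if method == "temporal":
        return lambda: TemporalFeaturePipeline()
    raise ValueError(f"unknown feature method {method}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage and return (and optionally write) the report."""
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config)}

    # ---- simulate -------------------------------------------------------
    cfg_int, cfg_ext = syn.default_paired_configs(
        n_internal=config.n_internal, n_external=config.n_external,
        n_nodes=config.n_nodes,
        n_volumes_internal=config.n_volumes_internal,
        n_volumes_external=config.n_volumes_external,
        tr_internal=config.tr_internal, tr_external=config.tr_external,
        seed=config.seed,
    )
    internal, external = syn.generate_paired_cohorts(cfg_int, cfg_ext, shared_truth=True)
    if out:
        internal.metadata.to_csv(out / "metadata_internal.csv", index=False)
        external.metadata.to_csv(out / "metadata_external.csv", index=False)
        internal.partition.to_csv(out / "partition.tsv", sep="\t", index=False)

    # ---- connectome -----------------------------------------------------
    D_int = cn.build_cohort_matrix(internal)
    D_ext = cn.build_cohort_matrix(external)
    low_i, tot_i = _falff_bands(config.tr_internal)
    low_e, tot_e = _falff_bands(config.tr_external)
    falff_int = cn.cohort_falff(internal, low_band=low_i, total_band=tot_i)
    falff_ext = cn.cohort_falff(external, low_band=low_e, total_band=tot_e)

    # ---- components -----------------------------------------------------
    ages = internal.ages
    decomp = cp.fit_components(D_int, ages=ages)
    evr = decomp.explained_variance
    age_corr = cp.coefficient_age_correlations(decomp, ages)
    multi = cn.multi_subject_matrix(internal)
    pc1 = decomp.component_matrix(0, node_count=config.n_nodes)
    cmp_multi = cp.compare_matrices(pc1, multi.z_values)
    age_eff = cp.age_effect_matrix(D_int, ages, node_count=config.n_nodes)
    best_age_j = int(age_corr.iloc[0]["component"])
    pc_age = decomp.component_matrix(best_age_j, node_count=config.n_nodes)
    cmp_age = cp.compare_matrices(pc_age, age_eff)
    report["components"] = {
        "explained_variance_top10": [float(v) for v in evr[:10]],
        "pc1_explained_pct": float(100 * evr[0]),
        "age_component": best_age_j,
        "age_component_coeff_age_r": float(age_corr.iloc[0]["r"]),
        "pc1_multisubject_r": float(abs(cmp_multi["r"])),
        "age_component_age_effect_r": float(abs(cmp_age["r"])),
    }
    if out:
        pd.DataFrame({"explained_variance": evr}).to_csv(
            out / "explained_variance.csv", index=False)
        age_corr.to_csv(out / "age_correlations.csv", index=False)

    # ---- lifespan -------------------------------------------------------
    if config.run_lifespan:
        edge_table = ls.edge_age_tables(D_int, internal.metadata, q=config.q)
        net_summ = ls.cohort_network_summaries(D_int, internal.partition)
        lin_net = ls.age_model_table(net_summ.to_numpy(), internal.metadata, "linear",
                                     config.q, unit_ids=net_summ.index)
        quad_net = ls.age_model_table(net_summ.to_numpy(), internal.metadata, "quadratic",
                                      config.q, unit_ids=net_summ.index)
        lin_net["class"] = ls.classify_trajectories(lin_net, quad_net, config.q)
        falff_table = ls.falff_age_models(falff_int, internal.metadata, q=config.q)
        report["lifespan"] = {
            "edge_class_counts": edge_table["class"].value_counts().to_dict(),
            "network_class_counts": lin_net["class"].value_counts().to_dict(),
            "falff_class_counts": falff_table["class"].value_counts().to_dict(),
        }
        if out:
            edge_table.to_csv(out / "edge_age_models.csv", index=False)
            lin_net.to_csv(out / "network_age_models.csv", index=False)
            falff_table.to_csv(out / "falff_age_models.csv", index=False)

    # ---- features + prediction -----------------------------------------
    data_by_method = {
        "network": (D_int.values, D_ext.values),
        "edge": (D_int.values, D_ext.values),
        "temporal": (falff_int.values, falff_ext.values),
    }
    grid = {}
    predictions_frames = []
    for method in config.feature_methods:
        cols_int, cols_ext = data_by_method[method]
        factory = _pipeline_factory(method, config)
        for family in config.model_families:
            spec = ModelSpec(family=family, seed=config.seed)
            res = kfold_validate(
                spec, factory, cols_int, internal.metadata, K=config.K,
                seed=config.seed, leakage_mode=config.leakage_mode,
                feature_method=method,
            )
            pipe, model = fit_full(spec, factory, cols_int, ages)
            ext = external_validate(pipe, model, cols_ext, external.metadata,
                                    feature_method=method)
            grid[f"{method}/{family}"] = {
                "internal_r": res.pearson_r,
                "internal_mae": res.mae_years,
                "internal_fold_mean_r": res.mean_fold_r,
                "internal_fold_mean_mae": res.mean_fold_mae,
                "external_r": ext.pearson_r,
                "external_mae": ext.mae_years,
            }
            predictions_frames.append(
                res.table.assign(feature=method, family=family, split="internal"))
            predictions_frames.append(
                ext.table.assign(feature=method, family=family, split="external"))
    report["prediction"] = grid
    best = max(grid, key=lambda k: np.nan_to_num(grid[k]["internal_r"], nan=-2.0))
    report["prediction_best"] = {"combo": best, **grid[best]}
    if out:
        pd.concat(predictions_frames).to_csv(out / "predictions.csv", index=False)

    # ---- permutation significance --------------------------------------
    if config.run_permutation:
        perm_cfg = PermutationConfig(
            B=config.permutation_B, alpha=config.permutation_alpha,
            seed=config.seed, model=ModelSpec(family="ols", seed=config.seed),
            l=config.permutation_l,
        )
        sig, reduction, model = permutation_test(D_int.values.T, ages, perm_cfg)
        agg = network_weight_aggregation(
            {"ols": sig.weights}, D_int.edge_index, internal.partition,
            {"ols": sig.significant},
        )
        report["edge_significance"] = {
            "n_significant": int(sig.significant.sum()),
            "n_significant_positive": int(len(agg["common_positive"])),
            "n_significant_negative": int(len(agg["common_negative"])),
            "B": perm_cfg.B,
            "alpha": perm_cfg.alpha,
        }
        if out:
            sig.table(D_int.edge_index).to_csv(out / "edge_significance.csv", index=False)
            agg["network_table"].to_csv(out / "network_weights.csv", index=False)
            agg["node_power"].to_csv(out / "node_power.csv", index=False)

    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
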
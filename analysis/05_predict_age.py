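"""Train the 3 x 3 grid of age predictors with internal and external validation.

For each feature method (network PCA coefficients, supervised edge
reduction, node fALFF) and each regression family (OLS, Lasso, SVR): 10-fold
internal cross-validation on the internal cohort with strict per-fold
feature refitting, then a fit on the whole internal cohort applied to the
external cohort.  Reports pooled Pearson r and MAE, plus the gender z-test,
error-age correlation, and a Steiger test of the best connectivity model
against the best temporal model.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from fcage import connectome as cn
from fcage import prediction as pr
from fcage import synthetic as syn
from fcage.features import (
    EdgeFeaturePipeline,
    NetworkFeaturePipeline,
    TemporalFeaturePipeline,
)
from fcage.pipeline import _falff_bands


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--K", type=int, default=10)
    ap.add_argument("--out", default="results/05_prediction")
    args = ap.parse_args()
    seed = args.seed

    cfg_int, cfg_ext = syn.default_paired_configs(seed=seed)
    internal, external = syn.generate_paired_cohorts(cfg_int, cfg_ext)
    D_int = cn.build_cohort_matrix(internal)
    D_ext = cn.build_cohort_matrix(external)
    f_int = cn.cohort_falff(internal, *_falff_bands(internal.tr_seconds))
    f_ext = cn.cohort_falff(external, *_falff_bands(external.tr_seconds))
    data = {"network": (D_int.values, D_ext.values),
            "edge": (D_int.values, D_ext.values),
            "temporal": (f_int.values, f_ext.values)}
    factories = {"network": lambda: NetworkFeaturePipeline(L=150),
                 "edge": lambda: EdgeFeaturePipeline(seed=seed),
                 "temporal": lambda: TemporalFeaturePipeline()}

    rows, results = [], {}
    for method in ("network", "edge", "temporal"):
        for family in ("ols", "lasso", "svr"):
            spec = pr.ModelSpec(family=family, seed=seed)
            res = pr.kfold_validate(spec, factories[method], data[method][0],
                                    internal.metadata, K=args.K, seed=seed)
            pipe, model = pr.fit_full(spec, factories[method],
                                      data[method][0], internal.ages)
            ext = pr.external_validate(pipe, model, data[method][1],
                                       external.metadata)
            results[(method, family)] = (res, ext)
            rows.append({"feature": method, "family": family,
                         "internal_r": res.pearson_r,
                         "internal_mae": res.mae_years,
                         "external_r": ext.pearson_r,
                         "external_mae": ext.mae_years})
            print(f"{method}/{family}: internal r={res.pearson_r:.3f} "
                  f"MAE={res.mae_years:.1f} y | external r={ext.pearson_r:.3f} "
                  f"MAE={ext.mae_years:.1f} y")

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(rows)
    table.to_csv(out / "prediction_grid.csv", index=False)

    best_conn = table[table.feature != "temporal"].sort_values(
        "internal_r", ascending=False).iloc[0]
    best_temp = table[table.feature == "temporal"].sort_values(
        "internal_r", ascending=False).iloc[0]
    res_c = results[(best_conn.feature, best_conn.family)][0]
    res_t = results[(best_temp.feature, best_temp.family)][0]
    r12 = pr.pearson_r(res_c.table["predicted"], res_t.table["predicted"])
    z, p = pr.steiger_test(res_c.pearson_r, res_t.pearson_r, r12,
                           len(res_c.table))
    print(f"best connectivity ({best_conn.feature}/{best_conn.family}) vs best "
          f"temporal ({best_temp.family}): Steiger z = {z:.2f}, p = {p:.2g}")

    ext_best = results[(best_conn.feature, best_conn.family)][1]
    zg, pg = pr.group_error_ztest(ext_best, external.metadata["sex"].to_numpy())
    r_err, t_err, p_err = pr.error_age_correlation(ext_best)
    print(f"external gender z-test on |error|: z = {zg:.2f} (p = {pg:.2f})")
    print(f"external |error|-age correlation: r = {r_err:.3f} "
          f"(t = {t_err:.2f}, p = {p_err:.2g})")
    print(f"wrote grid to {out}/")


if __name__ == "__main__":
    main()
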
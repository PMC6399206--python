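"""Age prediction: OLS, Lasso and SVR over any feature block, with K-fold
internal validation, external validation, and the accompanying statistics
(Pearson r, MAE, Steiger's z for dependent correlations, a two-sample z-test
on absolute errors by group, and the error-age correlation).

Lasso's penalty grid is anchored at the data-driven lambda_max (the smallest
penalty that zeroes every coefficient); SVR and Lasso hyperparameters are
chosen by inner cross-validation on MAE using training subjects only.
Features are standardized inside the model wrapper for the penalized
families (statistics are reported on the natural age scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR, LinearSVR


def make_svr(kernel: str, C: float, gamma="scale", epsilon: float = 1.0):
    """SVR factory; the linear kernel uses the (much faster) primal solver."""
    if kernel == "linear":
        return LinearSVR(C=C, epsilon=epsilon, loss="epsilon_insensitive",
                         max_iter=50_000, random_state=0)
    return SVR(kernel=kernel, C=C, gamma=gamma, epsilon=epsilon)


@dataclass
class ModelSpec:
    family: str = "lasso"                     # ols | lasso | svr
    lasso_lambda_grid: tuple = ()             # empty -> lambda_max-anchored log grid
    lasso_n_lambdas: int = 15
    svr_kernels: tuple = ("linear", "rbf", "poly")
    svr_C_grid: tuple = (1.0, 10.0, 100.0)
    svr_epsilon: float = 1.0
    rbf_gamma_grid: tuple = ("scale",)
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("ols", "lasso", "svr"):
            raise ValueError("family must be ols, lasso or svr")
        if self.family == "svr" and not self.svr_kernels:
            raise ValueError("empty SVR kernel set")


@dataclass
class FittedModel:
    family: str
    estimator: object
    scaler: StandardScaler | None
    hyperparams: dict

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return np.asarray(self.estimator.predict(X), float)

    def linear_coef(self) -> np.ndarray:
        """Coefficients in the (unscaled) feature space; linear models only."""
        if self.family == "svr" and self.hyperparams.get("kernel") != "linear":
            raise ValueError(
                "per-feature weights require a linear model; refit SVR with a "
                "linear kernel for significance analysis"
            )
        coef = np.ravel(self.estimator.coef_)
        if self.scaler is not None:
            coef = coef / self.scaler.scale_
        return coef


@dataclass
class PredictionResult:
    """Per-subject predictions with pooled and per-fold accuracy."""

    table: pd.DataFrame                      # subject_id, age, predicted, fold
    pearson_r: float
    mae_years: float
    per_fold: pd.DataFrame | None = None     # fold, r, mae
    mean_fold_r: float | None = None
    mean_fold_mae: float | None = None
    family: str = ""
    feature_method: str = ""
    hyperparams: list = field(default_factory=list)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input to Pearson correlation")
    xc, yc = x - x.mean(), y - y.mean()
    return float(xc @ yc / (np.linalg.norm(xc) * np.linalg.norm(yc)))


def mae(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 1:
        raise ValueError("need equal-length, non-empty vectors")
    return float(np.abs(x - y).mean())


def _inner_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(n), k)


def _inner_cv_mae(make_est, X: np.ndarray, y: np.ndarray, folds) -> float:
    errs = []
    idx_all = np.concatenate(folds)
    for f in folds:
        tr = np.setdiff1d(idx_all, f)
        est = make_est()
        est.fit(X[tr], y[tr])
        errs.append(np.abs(est.predict(X[f]) - y[f]).mean())
    return float(np.mean(errs))


def train(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> FittedModel:
    """Fit one model family with seeded inner-CV hyperparameter selection."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n, d = X.shape
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    if spec.family == "ols":
        if d >= n:
            raise ValueError(
                f"OLS with d={d} >= n={n} is ill-posed; use a reducing feature "
                "method (network or edge features) first"
            )
        est = LinearRegression()
        est.fit(X, y)
        return FittedModel("ols", est, None, {})

    scaler = StandardScaler()
    Xs = scaler.fit_transform(X)
    folds = _inner_folds(n, min(spec.inner_folds, n // 2), spec.seed)

    if spec.family == "lasso":
        grid = np.asarray(spec.lasso_lambda_grid, float)
        if grid.size == 0:
            yc = y - y.mean()
            lam_max = np.max(np.abs(Xs.T @ yc)) / n
            lam_max = max(lam_max, 1e-8)
            grid = np.geomspace(lam_max, 1e-3 * lam_max, spec.lasso_n_lambdas)
        best_lam, best_mae = float(grid[0]), np.inf
        for lam in grid:
            m = _inner_cv_mae(
                lambda lam=lam: Lasso(alpha=float(lam), max_iter=20000), Xs, y, folds
            )
            if m < best_mae - 1e-12:
                best_mae, best_lam = m, float(lam)
        boundary = bool(best_lam in (grid[0], grid[-1]))
        est = Lasso(alpha=best_lam, max_iter=20000)
        est.fit(Xs, y)
        return FittedModel("lasso", est, scaler,
                           {"lambda": best_lam, "grid_boundary": boundary})

    # svr
    candidates = []
    for kernel in spec.svr_kernels:
        for C in spec.svr_C_grid:
            gammas = spec.rbf_gamma_grid if kernel in ("rbf", "poly") else ("scale",)
            for gamma in gammas:
                candidates.append({"kernel": kernel, "C": float(C), "gamma": gamma})
    best, best_mae = candidates[0], np.inf
    for cand in candidates:
        m = _inner_cv_mae(
            lambda cand=cand: make_svr(epsilon=spec.svr_epsilon, **cand), Xs, y, folds
        )
        if m < best_mae - 1e-12:
            best_mae, best = m, cand
    est = make_svr(epsilon=spec.svr_epsilon, **best)
    est.fit(Xs, y)
    return FittedModel("svr", est, scaler, dict(best))


def kfold_split(n: int, K: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle into K near-equal folds (sizes differ by at most 1)."""
    if K > n // 3:
        raise ValueError("K too large for the cohort (need K <= n/3)")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), K)
    if min(len(f) for f in folds) < 2:
        raise ValueError("a fold would contain fewer than 2 subjects")
    return folds


def kfold_validate(
    spec: ModelSpec,
    pipeline_factory,
    data_columns: np.ndarray,
    meta: pd.DataFrame,
    K: int = 10,
    seed: int = 0,
    leakage_mode: str = "strict",
    feature_method: str = "",
) -> PredictionResult:
    """K-fold cross-validation with per-fold feature refitting.

    ``pipeline_factory()`` returns a fresh object with
    ``fit(columns, ages)`` / ``transform(columns)``; ``data_columns`` is a
    units x subjects matrix (edges or nodes).  In ``strict`` mode the
    pipeline is refit on each training fold and never sees held-out ages;
    ``paper`` mode fits the feature step once on all subjects (the
    optimistic protocol of fitting reducers on the whole cohort) while the
    regression model itself is still trained per fold.
    """
    if leakage_mode not in ("strict", "paper"):
        raise ValueError("leakage_mode must be 'strict' or 'paper'")
    ages = meta["age"].to_numpy(float)
    n = ages.size
    folds = kfold_split(n, K, seed)

    shared_pipeline = None
    if leakage_mode == "paper":
        shared_pipeline = pipeline_factory()
        shared_pipeline.fit(data_columns, ages)

    pred = np.full(n, np.nan)
    fold_label = np.full(n, -1)
    hyper = []
    for f_idx, test in enumerate(folds):
        trainset = np.setdiff1d(np.arange(n), test)
        if leakage_mode == "strict":
            pipe = pipeline_factory()
            pipe.fit(data_columns[:, trainset], ages[trainset])
        else:
            pipe = shared_pipeline
        X_train = pipe.transform(data_columns[:, trainset])
        X_test = pipe.transform(data_columns[:, test])
        model = train(spec, X_train, ages[trainset])
        pred[test] = model.predict(X_test)
        fold_label[test] = f_idx
        hyper.append(model.hyperparams)

    table = pd.DataFrame(
        {
            "subject_id": meta["subject_id"].to_numpy(),
            "age": ages,
            "predicted": pred,
            "fold": fold_label,
        }
    )
    def _fold_r(test):
        # a fold's predictions can be constant (e.g. a fully penalized
        # Lasso predicting the mean age); its r is then undefined
        if len(test) < 3 or np.std(pred[test]) == 0:
            return np.nan
        return pearson_r(ages[test], pred[test])

    per_fold = pd.DataFrame(
        [
            {"fold": f_idx, "r": _fold_r(test), "mae": mae(ages[test], pred[test])}
            for f_idx, test in enumerate(folds)
        ]
    )
    pooled_r = np.nan if np.std(pred) == 0 else pearson_r(ages, pred)
    return PredictionResult(
        table=table,
        pearson_r=pooled_r,
        mae_years=mae(ages, pred),
        per_fold=per_fold,
        mean_fold_r=float(per_fold["r"].mean()),
        mean_fold_mae=float(per_fold["mae"].mean()),
        family=spec.family,
        feature_method=feature_method,
        hyperparams=hyper,
    )


def fit_full(
    spec: ModelSpec,
    pipeline_factory,
    data_columns: np.ndarray,
    ages: np.ndarray,
):
    """Fit the feature pipeline and model on an entire (internal) cohort."""
    pipe = pipeline_factory()
    pipe.fit(data_columns, np.asarray(ages, float))
    X = pipe.transform(data_columns)
    model = train(spec, X, np.asarray(ages, float))
    return pipe, model


def external_validate(
    pipe, model: FittedModel, data_columns_ext: np.ndarray, meta_ext: pd.DataFrame,
    feature_method: str = "",
) -> PredictionResult:
    """Apply an internally fitted pipeline + model to an external cohort."""
    ages = meta_ext["age"].to_numpy(float)
    X = pipe.transform(data_columns_ext)
    pred = model.predict(X)
    table = pd.DataFrame(
        {
            "subject_id": meta_ext["subject_id"].to_numpy(),
            "age": ages,
            "predicted": pred,
            "fold": -1,
        }
    )
    return PredictionResult(
        table=table,
        pearson_r=np.nan if np.std(pred) == 0 else pearson_r(ages, pred),
        mae_years=mae(ages, pred),
        family=model.family,
        feature_method=feature_method,
        hyperparams=[model.hyperparams],
    )


# --------------------------------------------------------------------------
# statistics on prediction results


def steiger_test(r1: float, r2: float, r12: float, n: int) -> tuple[float, float]:
    """Steiger's z for two dependent correlations sharing one variable.

    ``r1`` and ``r2`` are the correlations of each model's prediction with
    age, ``r12`` the correlation between the two predictions, ``n`` the
    sample size.  Two-sided p.
    """
    for r in (r1, r2, r12):
        if not np.isfinite(r) or abs(r) >= 1:
            raise ValueError("correlations must be finite with |r| < 1")
    if n <= 3:
        raise ValueError("need n > 3")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar = 0.5 * (r1 + r2)
    s = (r12 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r12**2)) / (
        (1 - rbar**2) ** 2
    )
    z = (z1 - z2) * np.sqrt((n - 3) / (2 - 2 * s))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def group_error_ztest(result: PredictionResult, groups: np.ndarray) -> tuple[float, float]:
    """Two-sample z on per-subject absolute errors, pooled variance.

    ``groups`` is a 0/1 label vector aligned with the result table (e.g.
    sex), probing group-related prediction bias.
    """
    groups = np.asarray(groups, int)
    err = np.abs(result.table["age"].to_numpy() - result.table["predicted"].to_numpy())
    e0, e1 = err[groups == 0], err[groups == 1]
    if e0.size == 0 or e1.size == 0:
        raise ValueError("both groups must be non-empty")
    n0, n1 = e0.size, e1.size
    sp2 = ((n0 - 1) * e0.var(ddof=1) + (n1 - 1) * e1.var(ddof=1)) / (n0 + n1 - 2)
    z = (e0.mean() - e1.mean()) / np.sqrt(sp2 * (1 / n0 + 1 / n1))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def error_age_correlation(result: PredictionResult) -> tuple[float, float, float]:
    """Correlation of absolute error with age: (r, t, two-sided p).

    t = r * sqrt((n - 2) / (1 - r^2)).
    """
    age = result.table["age"].to_numpy(float)
    err = np.abs(age - result.table["predicted"].to_numpy(float))
    n = age.size
    if n <= 3:
        raise ValueError("need n > 3")
    r = pearson_r(err, age)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return float(r), float(t), float(p)
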
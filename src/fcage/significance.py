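"""Permutation-based significance of per-edge predictive weights.

A linear model trained on supervised edge components is linear in the
standardized edges, so its per-edge weight is the composition of the
component-space coefficients with the reduction's loading/deflation chain.
Shuffling ages across subjects and refitting both the reduction and the
model (hyperparameters frozen at the real-fit values) builds an empirical
null for every edge weight; two-tailed p-values use the add-one estimator
(count + 1)/(B + 1), so p is never zero and is bounded below by 1/(B + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.preprocessing import StandardScaler

from .features import (
    SupervisedReduction,
    edge_rotation_vectors,
    fit_supervised_reduction,
    transform_supervised,
)
from .prediction import FittedModel, ModelSpec, train


@dataclass
class PermutationConfig:
    B: int = 10_000
    alpha: float = 0.001
    seed: int = 0
    model: ModelSpec = field(default_factory=lambda: ModelSpec(family="ols"))
    l: int = 10
    refit_reduction: bool = True
    freeze_hyperparams: bool = True

    def __post_init__(self) -> None:
        if self.B < 100:
            raise ValueError("need B >= 100 permutations")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if 1.0 / (self.B + 1) > self.alpha:
            raise ValueError(
                f"B={self.B} cannot resolve alpha={self.alpha}: the minimum "
                f"attainable p is 1/(B+1) = {1 / (self.B + 1):.2e}"
            )


@dataclass
class EdgeSignificance:
    weights: np.ndarray              # per-edge real-fit weights (standardized space)
    p_values: np.ndarray
    significant: np.ndarray          # boolean
    alpha: float
    B: int

    def table(self, edge_index: np.ndarray | None = None) -> pd.DataFrame:
        out = pd.DataFrame(
            {"weight": self.weights, "p": self.p_values, "significant": self.significant}
        )
        if edge_index is not None:
            out.insert(0, "node_i", edge_index[:, 0])
            out.insert(1, "node_j", edge_index[:, 1])
        return out


def edge_weights(model: FittedModel, reduction: SupervisedReduction) -> np.ndarray:
    """Per-edge weight of a linear model over the reduced components.

    Returned in standardized-edge space, in the full canonical edge order
    (edges dropped at fit time get weight 0).
    """
    w = model.linear_coef()
    rot = edge_rotation_vectors(reduction)
    beta_kept = rot @ w
    beta = np.zeros(reduction.kept_edges.size)
    beta[reduction.kept_edges] = beta_kept
    return beta


def _fit_with_fixed_hyperparams(family: str, hyper: dict, X: np.ndarray, y: np.ndarray) -> FittedModel:
    if family == "ols":
        est = LinearRegression()
        est.fit(X, y)
        return FittedModel("ols", est, None, {})
    scaler = StandardScaler()
    Xs = scaler.fit_transform(X)
    if family == "lasso":
        est = Lasso(alpha=hyper["lambda"], max_iter=20000)
    elif family == "svr":
        from .prediction import make_svr

        est = make_svr(hyper["kernel"], hyper["C"], hyper.get("gamma", "scale"),
                       hyper.get("epsilon", 1.0))
    else:
        raise ValueError(family)
    est.fit(Xs, y)
    return FittedModel(family, est, scaler, dict(hyper))


def permutation_test(
    X_edges: np.ndarray, ages: np.ndarray, config: PermutationConfig
) -> tuple[EdgeSignificance, SupervisedReduction, FittedModel]:
    """Empirical two-tailed test of every edge weight against a shuffled-age null.

    The real fit selects hyperparameters once (inner CV); each of the B
    permutations shuffles ages, refits the reduction (ages enter the
    reduction, so the null must break that path too) and the model with the
    frozen hyperparameters, and records the permuted edge weights.
    p_edge = (1 + #{b : |beta_b| >= |beta_real|}) / (B + 1).
    """
    X = np.asarray(X_edges, float)
    y = np.asarray(ages, float)
    n, m = X.shape
    if y.size != n:
        raise ValueError("ages must match the number of subjects")
    if config.model.family == "svr" and "linear" not in config.model.svr_kernels:
        raise ValueError("edge significance requires a linear-kernel SVR")

    spec = config.model
    if spec.family == "svr":
        # restrict to the linear kernel so edge weights are defined
        from dataclasses import replace

        spec = replace(spec, svr_kernels=("linear",))

    reduction = fit_supervised_reduction(X, y, config.l)
    U = transform_supervised(reduction, X).matrix
    model = train(spec, U, y)
    beta_real = edge_weights(model, reduction)

    rng = np.random.default_rng(config.seed)
    exceed = np.zeros(m, dtype=np.int64)
    abs_real = np.abs(beta_real)
    for _ in range(config.B):
        y_perm = y[rng.permutation(n)]
        if config.refit_reduction:
            red_b = fit_supervised_reduction(X, y_perm, config.l)
        else:
            red_b = reduction
        U_b = transform_supervised(red_b, X).matrix
        if config.freeze_hyperparams:
            model_b = _fit_with_fixed_hyperparams(model.family, model.hyperparams, U_b, y_perm)
        else:
            model_b = train(spec, U_b, y_perm)
        beta_b = edge_weights(model_b, red_b)
        exceed += np.abs(beta_b) >= abs_real

    p = (1.0 + exceed) / (config.B + 1.0)
    sig = p <= config.alpha
    return (
        EdgeSignificance(weights=beta_real, p_values=p, significant=sig,
                         alpha=config.alpha, B=config.B),
        reduction,
        model,
    )


def network_weight_aggregation(
    weights_by_model: dict[str, np.ndarray],
    edge_index: np.ndarray,
    partition: pd.DataFrame,
    significance_by_model: dict[str, np.ndarray] | None = None,
) -> dict:
    """Network-level sums/means of edge weights, node power, and common edges.

    For each model: per-network and per-network-pair sum and mean of edge
    weights, and per-node predictive power (sum of |weights| of incident
    edges).  Across the supplied models: the edge sets significant with
    positive (resp. negative) weight in every model.
    """
    net = partition.sort_values("node_id")["network"].to_numpy()
    p = net.size
    e_i, e_j = edge_index[:, 0], edge_index[:, 1]
    networks = list(pd.unique(net))
    rows = []
    power_rows = []
    for name, w in weights_by_model.items():
        w = np.asarray(w, float)
        if w.size != edge_index.shape[0]:
            raise ValueError(f"weights for {name} do not match the edge index")
        for xi, x in enumerate(networks):
            mask = (net[e_i] == x) & (net[e_j] == x)
            if mask.any():
                rows.append({"model": name, "block": f"Within({x})",
                             "sum": float(w[mask].sum()), "mean": float(w[mask].mean())})
            for y_ in networks[xi + 1:]:
                mask = ((net[e_i] == x) & (net[e_j] == y_)) | (
                    (net[e_i] == y_) & (net[e_j] == x))
                if mask.any():
                    rows.append({"model": name, "block": f"Between({x},{y_})",
                                 "sum": float(w[mask].sum()), "mean": float(w[mask].mean())})
        power = np.zeros(p)
        np.add.at(power, e_i, np.abs(w))
        np.add.at(power, e_j, np.abs(w))
        for node in range(p):
            power_rows.append({"model": name, "node": node, "power": float(power[node])})

    common_pos = common_neg = None
    if significance_by_model:
        for name, sig in significance_by_model.items():
            w = np.asarray(weights_by_model[name], float)
            pos = np.asarray(sig, bool) & (w > 0)
            neg = np.asarray(sig, bool) & (w < 0)
            common_pos = pos if common_pos is None else (common_pos & pos)
            common_neg = neg if common_neg is None else (common_neg & neg)
    return {
        "network_table": pd.DataFrame(rows),
        "node_power": pd.DataFrame(power_rows),
        "common_positive": np.where(common_pos)[0] if common_pos is not None else None,
        "common_negative": np.where(common_neg)[0] if common_neg is not None else None,
    }
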
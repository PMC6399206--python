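"""Mass-univariate lifespan models of connectivity and fALFF.

Each unit (edge, network summary, or node fALFF) is regressed on age with
sex, head motion (mean FD) and total intracranial volume as covariates:

    linear     y = b0 + b1*age + b2*sex + b3*FD + b4*TIV + e
    quadratic  y = b0 + b1*ac + b2*ac^2 + b3*sex + b4*FD + b5*TIV + e

where ``ac`` is age centered at the cohort mean (collinearity control).
Two-sided t-tests give the age-term p; the overall-fit F-test gives the
model p.  Both are Benjamini-Hochberg corrected within their family, and a
unit is classified (linear-increase / linear-decrease / U / inverted-U)
only when both survive at the configured q, with the quadratic class taking
precedence by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectome import ConnectivityMatrix


# --------------------------------------------------------------------------
# network summaries


def network_summaries(Z: np.ndarray | ConnectivityMatrix, partition: pd.DataFrame) -> dict:
    """Within/Between/Within-Between summaries of one z-matrix.

    Within(X) is the mean z over unordered node pairs inside network X;
    Between(X, Y) the mean z over pairs crossing X and Y; WithinBetween(X)
    is Within(X) minus the mean of Between(X, Y) over all other networks Y.
    Singleton networks have no Within value (reported as NaN).
    """
    M = Z.z_values if isinstance(Z, ConnectivityMatrix) else np.asarray(Z, float)
    net = partition.sort_values("node_id")["network"].to_numpy()
    networks = list(pd.unique(net))
    within: dict = {}
    between: dict = {}
    for x in networks:
        idx = np.where(net == x)[0]
        if idx.size < 2:
            within[x] = np.nan
        else:
            block = M[np.ix_(idx, idx)]
            within[x] = float(block[np.triu_indices(idx.size, k=1)].mean())
    for i, x in enumerate(networks):
        for y in networks[i + 1:]:
            bi, bj = np.where(net == x)[0], np.where(net == y)[0]
            between[(x, y)] = float(M[np.ix_(bi, bj)].mean())
    within_between: dict = {}
    for x in networks:
        others = [between[(x, y)] if (x, y) in between else between[(y, x)]
                  for y in networks if y != x]
        within_between[x] = within[x] - float(np.mean(others)) if np.isfinite(within[x]) else np.nan
    return {"within": within, "between": between, "within_between": within_between}


def cohort_network_summaries(D, partition: pd.DataFrame) -> pd.DataFrame:
    """Per-subject network summaries from the cohort edge matrix.

    Returns a units x subjects table whose index holds summary names like
    ``Within(N00)``, ``Between(N00,N01)``, ``WithinBetween(N00)``.
    """
    from .connectome import CohortEdgeMatrix, devectorize

    values = D.values if isinstance(D, CohortEdgeMatrix) else np.asarray(D, float)
    edge_index = D.edge_index
    net = partition.sort_values("node_id")["network"].to_numpy()
    networks = list(pd.unique(net))
    e_i, e_j = edge_index[:, 0], edge_index[:, 1]
    rows, names = [], []
    within_rows: dict = {}
    between_rows: dict = {}
    for x in networks:
        mask = (net[e_i] == x) & (net[e_j] == x)
        if mask.sum() >= 1:
            within_rows[x] = values[mask].mean(axis=0)
        else:
            within_rows[x] = np.full(values.shape[1], np.nan)
        names.append(f"Within({x})")
        rows.append(within_rows[x])
    for i, x in enumerate(networks):
        for y in networks[i + 1:]:
            mask = ((net[e_i] == x) & (net[e_j] == y)) | ((net[e_i] == y) & (net[e_j] == x))
            between_rows[(x, y)] = values[mask].mean(axis=0)
            names.append(f"Between({x},{y})")
            rows.append(between_rows[(x, y)])
    for x in networks:
        others = [between_rows[(x, y)] if (x, y) in between_rows else between_rows[(y, x)]
                  for y in networks if y != x]
        names.append(f"WithinBetween({x})")
        rows.append(within_rows[x] - np.mean(others, axis=0))
    return pd.DataFrame(np.vstack(rows), index=names)


# --------------------------------------------------------------------------
# regression


def design_matrix(meta: pd.DataFrame, model: str) -> tuple[np.ndarray, list[str], list[int]]:
    """Design matrix for the stated model; returns (X, names, age term columns)."""
    age = meta["age"].to_numpy(float)
    sex = meta["sex"].to_numpy(float)
    fd = meta["fd"].to_numpy(float)
    tiv = meta["tiv"].to_numpy(float)
    ones = np.ones_like(age)
    if model == "linear":
        X = np.column_stack([ones, age, sex, fd, tiv])
        return X, ["intercept", "age", "sex", "fd", "tiv"], [1]
    if model == "quadratic":
        ac = age - age.mean()
        X = np.column_stack([ones, ac, ac**2, sex, fd, tiv])
        return X, ["intercept", "age_c", "age_c2", "sex", "fd", "tiv"], [1, 2]
    raise ValueError("model must be 'linear' or 'quadratic'")


def fit_age_models(Y: np.ndarray, meta: pd.DataFrame, model: str) -> pd.DataFrame:
    """Vectorized OLS of every unit (row of Y) on the age model.

    Returns one row per unit with coefficients, t-statistics, the two-sided
    p of the age term (the quadratic term for the quadratic model), and the
    overall-fit F-test p (``model_p``).
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    X, names, age_cols = design_matrix(meta, model)
    n, k = X.shape
    if Y.shape[1] != n:
        raise ValueError("Y columns must match the number of subjects")
    if n <= k + 2:
        raise ValueError("too few subjects for the model")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # identify near-collinear columns via the R factor of a QR decomposition
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in range(k) if abs(R[i, i]) < 1e-10 * abs(R[0, 0])]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ (xtx_inv @ X.T).T                      # (units, k)
    resid = Y - beta @ X.T
    dof = n - k
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / dof
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    with np.errstate(invalid="ignore", divide="ignore"):
        tvals = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)

    yc = Y - Y.mean(axis=1, keepdims=True)
    tss = np.einsum("ij,ij->i", yc, yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(rss > 0, ((tss - rss) / (k - 1)) / (rss / dof), np.inf)
    model_p = stats.f.sf(F, k - 1, dof)
    model_p = np.where(np.isfinite(F), model_p, 0.0)
    # constant units: no evidence either way
    model_p = np.where(tss > 0, model_p, 1.0)

    out = pd.DataFrame(beta, columns=[f"beta_{c}" for c in names])
    for i, c in enumerate(names):
        out[f"t_{c}"] = tvals[:, i]
    age_col = age_cols[-1]  # the quadratic term for the quadratic model
    out["age_p"] = np.where(tss > 0, pvals[:, age_col], 1.0)
    out["age_beta"] = beta[:, age_col]
    out["model_p"] = model_p
    out["model"] = model
    return out


def fit_age_model(y: np.ndarray, meta: pd.DataFrame, model: str) -> pd.Series:
    """Single-unit convenience wrapper around :func:`fit_age_models`."""
    return fit_age_models(np.asarray(y, float)[None, :], meta, model).iloc[0]


def fdr_adjust(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and the rejection set."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([]), np.array([], bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj <= q


def age_model_table(Y: np.ndarray, meta: pd.DataFrame, model: str, q: float = 0.05,
                    unit_ids=None) -> pd.DataFrame:
    """Fit + FDR within this family (all units of one level and model type).

    A unit is significant only when both the overall model p and the
    age-term p survive BH correction at q.
    """
    table = fit_age_models(Y, meta, model)
    table["unit_id"] = np.arange(len(table)) if unit_ids is None else list(unit_ids)
    table["age_p_fdr"], age_rej = fdr_adjust(table["age_p"].to_numpy(), q)
    table["model_p_fdr"], model_rej = fdr_adjust(table["model_p"].to_numpy(), q)
    table["significant"] = age_rej & model_rej
    return table


def classify_trajectories(
    linear_table: pd.DataFrame,
    quadratic_table: pd.DataFrame,
    q: float = 0.05,
    precedence: str = "quadratic",
) -> pd.Series:
    """Per-unit trajectory class from the two fitted-and-corrected tables.

    linear-increase / linear-decrease by the sign of the significant linear
    age term; U / inverted-U by the sign of the significant quadratic term;
    'none' otherwise.  When both terms survive, ``precedence`` decides.
    """
    if not np.array_equal(linear_table["unit_id"].to_numpy(),
                          quadratic_table["unit_id"].to_numpy()):
        raise ValueError("tables must cover identical units in the same order")
    lin_sig = linear_table["significant"].to_numpy()
    quad_sig = quadratic_table["significant"].to_numpy()
    lin_up = linear_table["age_beta"].to_numpy() > 0
    quad_up = quadratic_table["age_beta"].to_numpy() > 0
    out = np.full(len(linear_table), "none", dtype=object)
    if precedence == "quadratic":
        out[lin_sig & lin_up] = "linear-increase"
        out[lin_sig & ~lin_up] = "linear-decrease"
        out[quad_sig & quad_up] = "U"
        out[quad_sig & ~quad_up] = "inverted-U"
    elif precedence == "linear":
        out[quad_sig & quad_up] = "U"
        out[quad_sig & ~quad_up] = "inverted-U"
        out[lin_sig & lin_up] = "linear-increase"
        out[lin_sig & ~lin_up] = "linear-decrease"
    else:
        raise ValueError("precedence must be 'quadratic' or 'linear'")
    return pd.Series(out, index=linear_table.index, name="class")


def edge_age_tables(D, meta: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Linear + quadratic age models for every edge, with classes."""
    values = D.values if hasattr(D, "values") else np.asarray(D, float)
    ids = [f"{i}-{j}" for i, j in D.edge_index] if hasattr(D, "edge_index") else None
    lin = age_model_table(values, meta, "linear", q, unit_ids=ids)
    quad = age_model_table(values, meta, "quadratic", q, unit_ids=ids)
    lin["class"] = classify_trajectories(lin, quad, q)
    quad["class"] = lin["class"]
    return lin.assign(**{f"quad_{c}": quad[c] for c in
                         ["age_beta", "age_p", "age_p_fdr", "model_p", "model_p_fdr",
                          "significant"]})


def falff_age_models(falff, meta: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Linear + quadratic age models of node fALFF, FDR-corrected per family."""
    values = falff.values if hasattr(falff, "values") else np.asarray(falff, float)
    ids = list(getattr(falff, "node_ids", range(values.shape[0])))
    lin = age_model_table(values, meta, "linear", q, unit_ids=ids)
    quad = age_model_table(values, meta, "quadratic", q, unit_ids=ids)
    lin["class"] = classify_trajectories(lin, quad, q)
    return lin.assign(**{f"quad_{c}": quad[c] for c in
                         ["age_beta", "age_p", "age_p_fdr", "significant"]})
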
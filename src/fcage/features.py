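"""Feature constructions for age prediction, with strict fit/transform contracts.

Three feature families:

* network features — per-subject coefficients on the first L cross-subject
  PCA components (out-of-fit subjects are projected onto the fitted
  components by least squares, which, by orthogonality, is a per-component
  inner product);
* edge features — a supervised covariance-maximizing reduction: after
  standardizing edges X and age Y on the training set, the first loading is
  p1 = X'Y / ||X'Y|| (the closed-form maximizer of Cov(Xp, Y) under
  ||p|| = 1), the component is u1 = X p1, X and Y are deflated by their
  regressions on u1, and the step is iterated l times;
* temporal features — node fALFF values passed through unchanged.

Fitting only ever sees training subjects and training ages; transforming a
held-out subject uses stored training statistics exclusively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .components import ComponentDecomposition, fit_components


@dataclass
class FeatureBlock:
    matrix: np.ndarray              # subjects x d
    feature_names: list[str]
    method: str                     # network | edge | temporal
    provenance: str = ""


@dataclass
class SupervisedReduction:
    """Fitted state of the supervised edge reduction.

    ``loadings`` (m x l) holds the unit-norm p_k, ``x_coeffs`` (m x l) the
    deflation regression vectors c_k, ``y_coeffs`` the scalars r_k, and
    ``projections`` the training component matrix U (n x l, mutually
    orthogonal columns).  Standardization statistics are from the training
    data only.
    """

    loadings: np.ndarray
    x_coeffs: np.ndarray
    y_coeffs: np.ndarray
    projections: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    l: int
    kept_edges: np.ndarray          # boolean mask of training edges kept
    early_stop: bool = False


def fit_supervised_reduction(
    X: np.ndarray, Y: np.ndarray, l: int, tol: float = 1e-12
) -> SupervisedReduction:
    """Iterative covariance-maximizing reduction of edges against age.

    ``X`` is subjects x edges, ``Y`` the age vector.  Zero-variance training
    edges are dropped (recorded in ``kept_edges``) before standardization.
    Stops early, with a warning flag, if the residual covariance vanishes.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float).ravel()
    n, m_all = X.shape
    if Y.size != n:
        raise ValueError("X and Y must agree on the number of subjects")
    if l > min(n - 1, m_all):
        raise ValueError(f"l={l} exceeds min(n-1, m) = {min(n - 1, m_all)}")

    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0)
    kept = x_std > 0
    Xs = (X[:, kept] - x_mean[kept]) / x_std[kept]
    y_mean, y_std = float(Y.mean()), float(Y.std())
    if y_std == 0:
        raise ValueError("constant age vector")
    Ys = (Y - y_mean) / y_std

    m = int(kept.sum())
    P = np.zeros((m, l))
    C = np.zeros((m, l))
    R = np.zeros(l)
    U = np.zeros((n, l))
    E, f = Xs.copy(), Ys.copy()
    scale = np.linalg.norm(Xs) * np.linalg.norm(Ys) + 1e-30
    k_done = 0
    for k in range(l):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm <= tol * scale:
            break
        p = w / norm
        u = E @ p
        uu = float(u @ u)
        c = E.T @ u / uu
        r = float(f @ u) / uu
        E = E - np.outer(u, c)
        f = f - r * u
        P[:, k], C[:, k], R[k], U[:, k] = p, c, r, u
        k_done += 1

    return SupervisedReduction(
        loadings=P[:, :k_done],
        x_coeffs=C[:, :k_done],
        y_coeffs=R[:k_done],
        projections=U[:, :k_done],
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        l=k_done,
        kept_edges=kept,
        early_stop=k_done < l,
    )


def transform_supervised(reduction: SupervisedReduction, X_new: np.ndarray) -> FeatureBlock:
    """Project new subjects through the fitted reduction (no refitting).

    Standardizes with the stored training statistics (dropped training edges
    are zero-imputed by exclusion), then applies the loading/deflation chain
    sequentially.
    """
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != reduction.x_mean.size:
        raise ValueError("edge set of X_new does not match the fitted reduction")
    kept = reduction.kept_edges
    E = (X_new[:, kept] - reduction.x_mean[kept]) / reduction.x_std[kept]
    out = np.zeros((X_new.shape[0], reduction.l))
    for k in range(reduction.l):
        u = E @ reduction.loadings[:, k]
        out[:, k] = u
        E = E - np.outer(u, reduction.x_coeffs[:, k])
    return FeatureBlock(
        matrix=out,
        feature_names=[f"edge_component_{k + 1}" for k in range(reduction.l)],
        method="edge",
    )


def predict_from_reduction(reduction: SupervisedReduction, X_new: np.ndarray) -> np.ndarray:
    """Age prediction implied by the reduction's own inner regressions."""
    U = transform_supervised(reduction, X_new).matrix
    return reduction.y_mean + reduction.y_std * (U @ reduction.y_coeffs)


def edge_rotation_vectors(reduction: SupervisedReduction) -> np.ndarray:
    """Vectors rho_k with u_k = x_standardized @ rho_k, for all k (m x l).

    Components are linear in the standardized edges: u_k = E_{k-1} p_k with
    E_k = E_{k-1} (I - p_k c_k'); unrolling gives
    rho_k = (I - p_1 c_1') ... (I - p_{k-1} c_{k-1}') p_k.
    """
    P, C = reduction.loadings, reduction.x_coeffs
    m, l = P.shape
    rot = np.zeros((m, l))
    for k in range(l):
        v = P[:, k].copy()
        for j in range(k - 1, -1, -1):
            v = v - P[:, j] * float(C[:, j] @ v)
        rot[:, k] = v
    return rot


def network_features(
    decomp: ComponentDecomposition, D_columns: np.ndarray, L: int | None = None
) -> FeatureBlock:
    """Component-coefficient features for arbitrary subjects.

    ``D_columns`` is edges x subjects.  Coefficients are least-squares
    projections onto the fitted components; since components are mutually
    orthogonal this is ``T_j' d / ||T_j||^2`` per component, and for
    training subjects it reproduces the decomposition's own coefficients.
    """
    L = decomp.n_components if L is None else min(L, decomp.n_components)
    T = decomp.components[:, :L]
    d = np.atleast_2d(np.asarray(D_columns, float))
    if d.shape[0] != T.shape[0]:
        d = d.T
    if d.shape[0] != T.shape[0]:
        raise ValueError("edge dimension mismatch with the decomposition")
    if decomp.column_offset is not None:
        d = d - decomp.column_offset
    norms2 = np.einsum("ij,ij->j", T, T)
    norms2 = np.where(norms2 > 0, norms2, 1.0)
    coeffs = (T.T @ d) / norms2[:, None]            # (L, subjects)
    return FeatureBlock(
        matrix=coeffs.T,
        feature_names=[f"pc_{j + 1}" for j in range(L)],
        method="network",
    )


def temporal_features(falff) -> FeatureBlock:
    """Node fALFF values as features (subjects x nodes)."""
    values = falff.values if hasattr(falff, "values") else np.asarray(falff, float)
    node_ids = getattr(falff, "node_ids", np.arange(values.shape[0]))
    return FeatureBlock(
        matrix=np.asarray(values, float).T.copy(),
        feature_names=[f"falff_node_{int(i)}" for i in node_ids],
        method="temporal",
    )


# --------------------------------------------------------------------------
# fold-refittable pipelines (used by cross-validation and external validation)


class NetworkFeaturePipeline:
    """Fit cross-subject PCA on training columns of D; project any subject."""

    def __init__(self, L: int = 150):
        self.L = L
        self.decomp_: ComponentDecomposition | None = None

    def fit(self, D_train_columns: np.ndarray, ages_train: np.ndarray | None = None):
        self.decomp_ = fit_components(np.asarray(D_train_columns, float))
        return self

    def transform(self, D_columns: np.ndarray) -> np.ndarray:
        if self.decomp_ is None:
            raise RuntimeError("pipeline not fitted")
        L = min(self.L, self.decomp_.n_components)
        return network_features(self.decomp_, D_columns, L=L).matrix


class EdgeFeaturePipeline:
    """Supervised reduction on training subjects; transform any subject.

    ``l`` may be a fixed count or a grid, in which case the count is chosen
    by inner cross-validation on the reduction's own predictions (MAE).
    """

    def __init__(self, l=(5, 10, 20, 40), inner_folds: int = 5, seed: int = 0):
        self.l = l
        self.inner_folds = inner_folds
        self.seed = seed
        self.reduction_: SupervisedReduction | None = None
        self.chosen_l_: int | None = None

    def _select_l(self, X: np.ndarray, Y: np.ndarray) -> int:
        grid = [v for v in np.atleast_1d(self.l) if v <= min(X.shape[0] - 2, X.shape[1])]
        if not grid:
            return 1
        if len(grid) == 1:
            return int(grid[0])
        rng = np.random.default_rng(self.seed)
        idx = rng.permutation(X.shape[0])
        folds = np.array_split(idx, self.inner_folds)
        best_l, best_mae = int(grid[0]), np.inf
        for l in grid:
            errs = []
            for f in folds:
                tr = np.setdiff1d(idx, f)
                if tr.size <= l:
                    continue
                red = fit_supervised_reduction(X[tr], Y[tr], int(l))
                pred = predict_from_reduction(red, X[f])
                errs.append(np.abs(pred - Y[f]).mean())
            mae = float(np.mean(errs)) if errs else np.inf
            if mae < best_mae - 1e-12:
                best_mae, best_l = mae, int(l)
        return best_l

    def fit(self, D_train_columns: np.ndarray, ages_train: np.ndarray):
        X = np.asarray(D_train_columns, float).T
        Y = np.asarray(ages_train, float)
        self.chosen_l_ = self._select_l(X, Y)
        self.reduction_ = fit_supervised_reduction(X, Y, self.chosen_l_)
        return self

    def transform(self, D_columns: np.ndarray) -> np.ndarray:
        if self.reduction_ is None:
            raise RuntimeError("pipeline not fitted")
        return transform_supervised(self.reduction_, np.asarray(D_columns, float).T).matrix


class TemporalFeaturePipeline:
    """Stateless passthrough of node fALFF (columns are subjects)."""

    def fit(self, falff_train_columns: np.ndarray, ages_train: np.ndarray | None = None):
        return self

    def transform(self, falff_columns: np.ndarray) -> np.ndarray:
        return np.asarray(falff_columns, float).T.copy()
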
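"""Cross-subject principal component analysis of the cohort edge matrix.

The decomposition operates on the raw (uncentered, by default) edges-by-
subjects matrix ``D``: the coefficient matrix ``P`` holds the eigenvectors
of ``D'D`` sorted by descending eigenvalue, and the component matrix is
``T = D P``.  Because the data are not centered, the leading component
tracks the shared (intrinsic) connectivity pattern, while lower-variance
components can carry structured cross-subject variation such as an
age-related pattern.  Utilities characterize components against the
multi-subject matrix and the edgewise age-effect matrix, summarize a
component by network blocks, and test hemispheric asymmetry of an edge set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import CohortEdgeMatrix, devectorize, vectorize


@dataclass
class ComponentDecomposition:
    """Result of the edgewise PCA across subjects.

    ``components`` is m x L (columns are edge-space components T_j),
    ``coefficients`` is n x L (row i holds subject i's weights p_ij), and
    ``explained_variance`` the full length-n eigenvalue fractions.
    """

    components: np.ndarray
    coefficients: np.ndarray
    explained_variance: np.ndarray
    eigenvalues: np.ndarray
    edge_index: np.ndarray
    centering: str = "none"
    column_offset: np.ndarray | None = None  # edge means when centering='edge_mean'

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def component_matrix(self, j: int, node_count: int | None = None) -> np.ndarray:
        """Devectorized edge-space component ``T_j`` with unit diagonal."""
        return devectorize(self.components[:, j], node_count=node_count, diag=1.0)


def fit_components(
    D: CohortEdgeMatrix | np.ndarray,
    L: int | None = None,
    centering: str = "none",
    ages: np.ndarray | None = None,
) -> ComponentDecomposition:
    """PCA of D via the eigendecomposition of the n x n Gram matrix D'D.

    ``explained_variance`` is each eigenvalue over the eigenvalue total
    (the variance of D under the chosen centering).  Eigenvector sign is
    arbitrary; it is fixed so each coefficient column's largest-magnitude
    entry is positive, except that when ``ages`` are supplied the component
    whose coefficients correlate most strongly with age is oriented so that
    correlation is non-negative.
    """
    values = D.values if isinstance(D, CohortEdgeMatrix) else np.asarray(D, float)
    edge_index = D.edge_index if isinstance(D, CohortEdgeMatrix) else None
    m, n = values.shape
    if L is None:
        L = n
    if L > n:
        raise ValueError(f"L={L} exceeds the number of subjects n={n}")
    offset = None
    if centering == "edge_mean":
        offset = values.mean(axis=1, keepdims=True)
        values = values - offset
    elif centering != "none":
        raise ValueError("centering must be 'none' or 'edge_mean'")

    gram = values.T @ values
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    P = eigvecs[:, order]

    total = eigvals.sum()
    evr = eigvals / total if total > 0 else np.zeros_like(eigvals)

    # sign convention
    flip = np.ones(n)
    for j in range(n):
        col = P[:, j]
        k = np.argmax(np.abs(col))
        if col[k] < 0:
            flip[j] = -1.0
    if ages is not None:
        ages = np.asarray(ages, float)
        ac = ages - ages.mean()
        denom = np.linalg.norm(ac)
        if denom > 0:
            rs = np.zeros(n)
            for j in range(n):
                cc = P[:, j] - P[:, j].mean()
                s = np.linalg.norm(cc)
                rs[j] = 0.0 if s == 0 else float(cc @ ac) / (s * denom)
            top = int(np.argmax(np.abs(rs)))
            flip[top] = 1.0 if rs[top] >= 0 else -1.0
    P = P * flip
    T = values @ P

    return ComponentDecomposition(
        components=T[:, :L],
        coefficients=P[:, :L],
        explained_variance=evr,
        eigenvalues=eigvals,
        edge_index=edge_index,
        centering=centering,
        column_offset=offset,
    )


def subject_expansion(
    decomp: ComponentDecomposition, i: int, L: int | None = None,
    node_count: int | None = None,
) -> np.ndarray:
    """Truncated reconstruction of subject i's matrix: sum_j p_ij T_j.

    With all components retained this recovers the subject's matrix exactly
    off-diagonal; the diagonal is set to 1.
    """
    L = decomp.n_components if L is None else L
    vec = decomp.components[:, :L] @ decomp.coefficients[i, :L]
    if decomp.column_offset is not None:
        vec = vec + decomp.column_offset[:, 0]
    return devectorize(vec, node_count=node_count, diag=1.0)


def coefficient_age_correlations(
    decomp: ComponentDecomposition, ages: np.ndarray
) -> pd.DataFrame:
    """Pearson correlation of each component's coefficients with age.

    Returns a table ranked by |r| with columns component, r, abs_r and a
    flag for zero-variance coefficient columns (recorded as r = 0).
    """
    ages = np.asarray(ages, float)
    n, L = decomp.coefficients.shape
    if ages.size != n:
        raise ValueError("ages length must equal the number of subjects")
    ac = ages - ages.mean()
    a_norm = np.linalg.norm(ac)
    rows = []
    for j in range(L):
        col = decomp.coefficients[:, j]
        cc = col - col.mean()
        s = np.linalg.norm(cc)
        if s == 0 or a_norm == 0:
            rows.append((j, 0.0, True))
        else:
            rows.append((j, float(cc @ ac / (s * a_norm)), False))
    out = pd.DataFrame(rows, columns=["component", "r", "zero_variance"])
    out["abs_r"] = out["r"].abs()
    return out.sort_values("abs_r", ascending=False).reset_index(drop=True)


def age_effect_matrix(
    D: CohortEdgeMatrix | np.ndarray, ages: np.ndarray, node_count: int | None = None
) -> np.ndarray:
    """Per-edge Pearson correlation with age, devectorized (unit diagonal).

    Constant edges get entry 0.
    """
    values = D.values if isinstance(D, CohortEdgeMatrix) else np.asarray(D, float)
    ages = np.asarray(ages, float)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 subjects")
    Xc = values - values.mean(axis=1, keepdims=True)
    ac = ages - ages.mean()
    num = Xc @ ac
    den = np.linalg.norm(Xc, axis=1) * np.linalg.norm(ac)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    return devectorize(r, node_count=node_count, diag=1.0)


def compare_matrices(Ma: np.ndarray, Mb: np.ndarray) -> dict:
    """Similarity of two node matrices over their off-diagonal triangles.

    Returns the Pearson r of the vectorized upper triangles plus linear and
    quadratic least-squares fits of Mb-edges on Ma-edges, with coefficient
    t-statistics.
    """
    a, b = vectorize(np.asarray(Ma, float)), vectorize(np.asarray(Mb, float))
    if a.size != b.size:
        raise ValueError("matrices must share node count")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance triangle")
    r = float(np.corrcoef(a, b)[0, 1])

    def _ols(design: np.ndarray) -> dict:
        coef, *_ = np.linalg.lstsq(design, b, rcond=None)
        resid = b - design @ coef
        dof = b.size - design.shape[1]
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov))
        t = coef / se
        p = 2 * stats.t.sf(np.abs(t), dof)
        return {"coefficients": coef, "t": t, "p": p}

    ones = np.ones_like(a)
    linear = _ols(np.column_stack([ones, a]))
    quadratic = _ols(np.column_stack([ones, a, a**2]))
    return {"r": r, "linear": linear, "quadratic": quadratic}


def component_network_summary(
    decomp: ComponentDecomposition,
    j: int,
    partition: pd.DataFrame,
    threshold: float | None = None,
) -> dict:
    """Within/between-network means of component j's edges plus top edges.

    ``threshold`` selects edges with |value| above it for the top-edge list
    (None keeps the list empty).  Networks with fewer than two nodes have no
    within value and are reported missing.
    """
    vec = decomp.components[:, j]
    net = partition.sort_values("node_id")["network"].to_numpy()
    p = net.size
    M = devectorize(vec, node_count=p, diag=np.nan)
    networks = pd.unique(net)
    within, between = {}, {}
    for x in networks:
        idx = np.where(net == x)[0]
        if idx.size < 2:
            within[x] = np.nan
        else:
            block = M[np.ix_(idx, idx)]
            within[x] = float(np.nanmean(block[np.triu_indices(idx.size, k=1)]))
    for xi, x in enumerate(networks):
        for y in networks[xi + 1:]:
            bi = np.where(net == x)[0]
            bj = np.where(net == y)[0]
            between[(x, y)] = float(M[np.ix_(bi, bj)].mean())
    top_edges = []
    if threshold is not None:
        iu = np.triu_indices(p, k=1)
        sel = np.abs(vec) > threshold
        for i_, j_, v in zip(iu[0][sel], iu[1][sel], vec[sel]):
            top_edges.append((int(i_), int(j_), float(v)))
    return {"within": within, "between": between, "top_edges": top_edges}


def hemisphere_chi_square(
    edge_set: list[tuple[int, int]] | np.ndarray, partition: pd.DataFrame
) -> dict:
    """Goodness-of-fit of intra- vs inter-hemispheric counts in an edge set.

    The expected split is the proportion of intra/inter pairs among all
    possible node pairs; 1 degree of freedom.  A warning flag is raised when
    an expected count falls below 1.
    """
    edge_set = np.asarray(edge_set, int)
    if edge_set.size == 0:
        raise ValueError("empty edge set")
    hemi = partition.sort_values("node_id")["hemisphere"].to_numpy()
    p = hemi.size
    iu = np.triu_indices(p, k=1)
    intra_all = int(np.sum(hemi[iu[0]] == hemi[iu[1]]))
    total_all = iu[0].size
    prop_intra = intra_all / total_all
    obs_intra = int(np.sum(hemi[edge_set[:, 0]] == hemi[edge_set[:, 1]]))
    n = edge_set.shape[0]
    observed = np.array([obs_intra, n - obs_intra], float)
    expected = np.array([prop_intra * n, (1 - prop_intra) * n])
    stat = float(np.sum((observed - expected) ** 2 / expected))
    pval = float(stats.chi2.sf(stat, df=1))
    return {
        "statistic": stat,
        "p": pval,
        "observed": observed,
        "expected": expected,
        "low_expected_warning": bool(np.any(expected < 1)),
    }
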
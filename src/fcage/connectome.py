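"""Functional connectome construction from ROI time series.

Pearson correlation matrices, Fisher z-transform, canonical edge
vectorization (row-major upper triangle, 0-based i < j), the cohort edge
matrix ``D`` (edges x subjects), the multi-subject matrix (correlation over
all subjects' concatenated, per-subject standardized series), and node-level
fALFF (ratio of low-band 0.01-0.1 Hz spectral amplitude to the 0.01-0.25 Hz
band).

Connectivity is computed, by default, on band-pass filtered series
(0.01-0.1 Hz Butterworth, forward-backward); fALFF is always computed on the
unfiltered series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

FISHER_CLIP = 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity matrix with unit diagonal convention."""

    z_values: np.ndarray
    node_ids: np.ndarray

    def __post_init__(self) -> None:
        z = self.z_values
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z_values must be square")
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite connectivity values")
        if np.max(np.abs(z - z.T)) > 1e-12:
            raise ValueError("z_values must be symmetric within 1e-12")

    @property
    def n_nodes(self) -> int:
        return self.z_values.shape[0]


@dataclass
class CohortEdgeMatrix:
    """Edges-by-subjects matrix D stacking each subject's upper triangle."""

    values: np.ndarray              # (m, n)
    edge_index: np.ndarray          # (m, 2) node pairs, i < j, canonical order
    subject_ids: np.ndarray

    @property
    def n_edges(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    @property
    def n_nodes(self) -> int:
        m = self.values.shape[0]
        return int(round((1 + np.sqrt(1 + 8 * m)) / 2))


@dataclass
class NodeFalff:
    """Node-by-subject fALFF table with the band definition used."""

    values: np.ndarray              # (p, n), in (0, 1)
    node_ids: np.ndarray
    subject_ids: np.ndarray
    low_band: tuple[float, float] = (0.01, 0.1)
    total_band: tuple[float, float] = (0.01, 0.25)


def correlation_matrix(ts: np.ndarray) -> np.ndarray:
    """Pearson correlations between every pair of node series.

    ``ts`` is nodes x time with at least 3 time points and no constant rows.
    """
    ts = np.asarray(ts, float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("need a nodes x time array with >= 3 time points")
    sd = ts.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"constant time series at node(s) {bad.tolist()}")
    r = np.corrcoef(ts)
    r = np.clip(r, -1.0, 1.0)
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform z = atanh(r), with |r| clipped to 1 - 1e-7."""
    arr = np.asarray(r, float)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError("correlation magnitude exceeds 1")
    clipped = np.sign(arr) * np.minimum(np.abs(arr), 1.0 - FISHER_CLIP)
    out = np.arctanh(clipped)
    return out if isinstance(r, np.ndarray) else float(out)


def edge_index_for(p: int) -> np.ndarray:
    """Canonical edge ordering: row-major over (i, j), 0-based, i < j."""
    iu = np.triu_indices(p, k=1)
    return np.column_stack(iu)


def vectorize(matrix: np.ndarray | ConnectivityMatrix) -> np.ndarray:
    """Upper triangle (excluding the diagonal) in canonical edge order."""
    z = matrix.z_values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    iu = np.triu_indices(z.shape[0], k=1)
    return z[iu].copy()


def devectorize(v: np.ndarray, node_count: int | None = None, diag: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize`; the diagonal is set to ``diag``."""
    v = np.asarray(v, float)
    m = v.size
    p = node_count if node_count is not None else int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if p * (p - 1) // 2 != m:
        raise ValueError(f"vector length {m} is not triangular for {p} nodes")
    out = np.full((p, p), 0.0)
    iu = np.triu_indices(p, k=1)
    out[iu] = v
    out = out + out.T
    np.fill_diagonal(out, diag)
    return out


def bandpass(ts: np.ndarray, tr_seconds: float,
             band: tuple[float, float] = (0.01, 0.1), order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass of each node series."""
    fs = 1.0 / tr_seconds
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, ts, axis=-1)


def subject_z_matrix(ts: np.ndarray, tr_seconds: float | None = None,
                     apply_bandpass: bool = True) -> np.ndarray:
    """One subject's Fisher-z connectivity matrix (unit diagonal)."""
    if apply_bandpass:
        if tr_seconds is None:
            raise ValueError("tr_seconds required when band-pass filtering")
        ts = bandpass(ts, tr_seconds)
    z = fisher_z(correlation_matrix(ts))
    np.fill_diagonal(z, 1.0)
    return z


def build_cohort_matrix(cohort, apply_bandpass: bool = True) -> CohortEdgeMatrix:
    """Stack every subject's vectorized z-edges into D (m x n).

    Column order follows the cohort metadata order; column k is exactly
    ``vectorize(fisher_z(corr(ts_k)))`` of the (optionally band-passed)
    series.
    """
    n, p, _ = cohort.time_series.shape
    m = p * (p - 1) // 2
    values = np.empty((m, n))
    for k in range(n):
        z = subject_z_matrix(cohort.time_series[k], cohort.tr_seconds, apply_bandpass)
        values[:, k] = vectorize(z)
    return CohortEdgeMatrix(
        values=values,
        edge_index=edge_index_for(p),
        subject_ids=cohort.metadata["subject_id"].to_numpy(),
    )


def multi_subject_matrix(cohort, apply_bandpass: bool = True) -> ConnectivityMatrix:
    """Correlation over all subjects' concatenated time series, Fisher-z.

    Each subject's series is standardized per node before concatenation so
    subjects with different variances contribute equally.
    """
    n, p, T = cohort.time_series.shape
    chunks = []
    for k in range(n):
        ts = cohort.time_series[k]
        if apply_bandpass:
            ts = bandpass(ts, cohort.tr_seconds)
        sd = ts.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError(f"constant node series for subject {k}")
        chunks.append((ts - ts.mean(axis=1, keepdims=True)) / sd)
    concat = np.concatenate(chunks, axis=1)
    z = fisher_z(correlation_matrix(concat))
    np.fill_diagonal(z, 1.0)
    return ConnectivityMatrix(z_values=z, node_ids=np.arange(p))


def compute_falff(
    ts: np.ndarray,
    tr_seconds: float,
    low_band: tuple[float, float] = (0.01, 0.1),
    total_band: tuple[float, float] = (0.01, 0.25),
    spectrum: str = "amplitude",
) -> np.ndarray:
    """Fractional amplitude of low-frequency fluctuations, per node.

    Single-taper (Hann) periodogram of the linearly detrended series; the
    taper keeps spectral leakage from off-bin components out of the band
    sums.  A bin belongs to a band when its center frequency lies in the
    closed interval.  With ``spectrum='amplitude'`` (default) the band sums
    are of the amplitude spectrum (square root of power); ``'power'`` sums
    power instead.
    """
    ts = np.atleast_2d(np.asarray(ts, float))
    T = ts.shape[-1]
    if T < 64:
        raise ValueError("series too short for spectral estimation (need >= 64)")
    nyq = 0.5 / tr_seconds
    if total_band[1] > nyq + 1e-12:
        raise ValueError(
            f"total band upper edge {total_band[1]} Hz exceeds Nyquist {nyq:.3f} Hz"
        )
    if not (total_band[0] <= low_band[0] and low_band[1] <= total_band[1]):
        raise ValueError("low band must be nested in the total band")
    detrended = signal.detrend(ts, axis=-1, type="linear")
    taper = signal.windows.hann(T, sym=False)
    freqs = np.fft.rfftfreq(T, d=tr_seconds)
    amp = np.abs(np.fft.rfft(detrended * taper, axis=-1))
    if spectrum == "power":
        amp = amp**2
    elif spectrum != "amplitude":
        raise ValueError("spectrum must be 'amplitude' or 'power'")
    low_sel = (freqs >= low_band[0]) & (freqs <= low_band[1])
    tot_sel = (freqs >= total_band[0]) & (freqs <= total_band[1])
    denom = amp[:, tot_sel].sum(axis=1)
    denom[denom == 0] = np.finfo(float).tiny
    return amp[:, low_sel].sum(axis=1) / denom


def cohort_falff(cohort, low_band=(0.01, 0.1), total_band=(0.01, 0.25),
                 spectrum: str = "amplitude") -> NodeFalff:
    """Node x subject fALFF for a whole cohort (unfiltered series)."""
    n, p, _ = cohort.time_series.shape
    values = np.empty((p, n))
    for k in range(n):
        values[:, k] = compute_falff(
            cohort.time_series[k], cohort.tr_seconds, low_band, total_band, spectrum
        )
    return NodeFalff(
        values=values,
        node_ids=np.arange(p),
        subject_ids=cohort.metadata["subject_id"].to_numpy(),
        low_band=low_band,
        total_band=total_band,
    )


def read_timeseries_tsv(path) -> tuple[np.ndarray, float]:
    """Read a per-subject TSV (nodes x volumes; '# tr_seconds=' header)."""
    tr = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "tr_seconds=" in first:
            tr = float(first.split("tr_seconds=")[1])
    data = np.loadtxt(path, delimiter="\t", comments="#")
    if tr is None:
        raise ValueError(f"missing tr_seconds header in {path}")
    return data, tr
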
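"""Synthetic resting-state cohort generator with planted lifespan structure.

Emulates the statistical regime of a lifespan rs-fMRI study: block-structured
functional connectivity by network, an additive age-related connectivity
pattern (linear slopes on a sparse edge set, plus optional quadratic edges),
subject-level connectivity noise, age-dependent low-frequency spectral power
(so node fALFF tracks planted trends), and nuisance covariates (sex, head
motion FD, total intracranial volume) correlated with age/sex.

Every draw is derived from the config seed, so identical configs produce
bitwise-identical cohorts.  Ground truth (baseline matrix ``B``, age-slope
pattern ``A``, quadratic curvatures, fALFF trends) is returned alongside the
data for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised when a generator config is internally inconsistent."""


class GenerationError(RuntimeError):
    """Raised when a subject's target matrix cannot be realized."""


# --------------------------------------------------------------------------
# configuration


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic cohort.

    Connectivity targets are specified on the Fisher-z scale.  For subject
    *i* with age ``a_i`` the target z-matrix is

        Z_i = B + (a_i - abar) * A + Q(a_i) + E_i

    with ``B`` the block baseline, ``A`` the per-year slope pattern,
    ``Q(a) = C * (a - abar)^2`` the planted quadratic terms, and ``E_i``
    symmetric Gaussian subject noise with sd ``noise_sd_z``.  fALFF targets
    are ``falff_base + falff_age_slope * (a - abar)`` plus a quadratic term
    on listed nodes, clipped into the attainable range of the spectral
    mixing model.
    """

    n_subjects: int = 200
    n_nodes: int = 50
    n_networks: int = 10
    network_sizes: tuple[int, ...] | None = None
    n_volumes: int = 600
    tr_seconds: float = 0.645
    age_range: tuple[float, float] = (6.0, 85.0)
    baseline_within_z: float = 0.45
    baseline_between_z: float = 0.08
    baseline_jitter_sd: float = 0.04
    baseline_eig_floor: float = 0.15
    # sparse planted maps: {(i, j) with i < j: value}
    age_slope_map: dict[tuple[int, int], float] = field(default_factory=dict)
    quadratic_edge_map: dict[tuple[int, int], float] = field(default_factory=dict)
    noise_sd_z: float = 0.03
    falff_base: float | np.ndarray = 0.55
    falff_age_slope: float | np.ndarray = 0.0
    falff_quadratic_map: dict[int, float] = field(default_factory=dict)
    falff_subject_sd: float = 0.04
    fd_age_correlation: float = 0.2
    tiv_sex_offset: float = 0.10
    seed: int = 0
    structure_seed: int | None = None
    cohort_label: str = "internal"

    def __post_init__(self) -> None:
        if self.network_sizes is None:
            base = self.n_nodes // self.n_networks
            sizes = [base] * self.n_networks
            for k in range(self.n_nodes - base * self.n_networks):
                sizes[k] += 1
            self.network_sizes = tuple(sizes)
        if sum(self.network_sizes) != self.n_nodes:
            raise ConfigurationError(
                f"network_sizes sum {sum(self.network_sizes)} != n_nodes {self.n_nodes}"
            )
        if self.noise_sd_z < 0:
            raise ConfigurationError("noise_sd_z must be >= 0")
        if not np.all(np.isfinite(list(self.age_slope_map.values()) or [0.0])):
            raise ConfigurationError("non-finite age slope")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigurationError("age_range must be increasing")
        if self.n_volumes < 64:
            raise ConfigurationError("n_volumes must be >= 64")


@dataclass
class GroundTruth:
    """Planted structure shared by all subjects of a cohort."""

    baseline_z: np.ndarray          # (p, p) symmetric, zero diagonal
    age_slope: np.ndarray           # (p, p) z-units per year
    quad_curvature: np.ndarray      # (p, p) z-units per year^2
    falff_base: np.ndarray          # (p,)
    falff_slope: np.ndarray         # (p,)
    falff_quad: np.ndarray          # (p,)
    age_mean: float                 # centering point abar
    partition: pd.DataFrame         # node_id, network, hemisphere


@dataclass
class SubjectCohort:
    """Per-subject ROI time series plus metadata and planted ground truth."""

    time_series: np.ndarray         # (n_subjects, n_nodes, n_volumes)
    metadata: pd.DataFrame          # subject_id, age, sex, fd, tiv, cohort
    partition: pd.DataFrame         # node_id, network, hemisphere
    ground_truth: GroundTruth
    tr_seconds: float
    target_z: np.ndarray | None = None   # (n, p, p) pre-noise-free targets incl. E_i

    @property
    def n_subjects(self) -> int:
        return self.time_series.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.time_series.shape[1]

    @property
    def ages(self) -> np.ndarray:
        return self.metadata["age"].to_numpy(float)


# --------------------------------------------------------------------------
# default planted structure


def make_partition(config: GeneratorConfig) -> pd.DataFrame:
    labels = []
    for k, size in enumerate(config.network_sizes):
        labels += [f"N{k:02d}"] * size
    hemis = ["L" if i % 2 == 0 else "R" for i in range(config.n_nodes)]
    return pd.DataFrame(
        {"node_id": np.arange(config.n_nodes), "network": labels, "hemisphere": hemis}
    )


def default_config(
    n_subjects: int = 200,
    n_nodes: int = 50,
    n_volumes: int = 600,
    tr_seconds: float = 0.645,
    seed: int = 7,
    cohort_label: str = "internal",
    plant_age_effects: bool = True,
    structure_seed: int | None = None,
) -> GeneratorConfig:
    """Study-condition defaults with a planted lifespan signal.

    ~5% of edges carry linear age slopes of magnitude 0.004 z/yr (two thirds
    negative, mirroring the predominance of age-related connectivity
    decline), ~1% carry quadratic curvature 1.5e-4 z/yr^2 (mostly inverted-U),
    70% of nodes lose low-frequency power with age (-8e-4 fALFF/yr), 10%
    gain (+5e-4), and four nodes carry a U-shaped fALFF trend.
    """
    cfg = GeneratorConfig(
        n_subjects=n_subjects,
        n_nodes=n_nodes,
        n_volumes=n_volumes,
        tr_seconds=tr_seconds,
        seed=seed,
        structure_seed=seed if structure_seed is None else structure_seed,
        cohort_label=cohort_label,
    )
    rng = np.random.default_rng((cfg.structure_seed or 0) + 9_001)
    p = n_nodes
    iu = np.triu_indices(p, k=1)
    m = iu[0].size
    if plant_age_effects:
        n_lin = max(4, int(round(0.05 * m)))
        n_quad = max(3, int(round(0.01 * m)))
        chosen = rng.choice(m, size=n_lin + n_quad, replace=False)
        lin_idx, quad_idx = chosen[:n_lin], chosen[n_lin:]
        slope_map = {}
        for k, e in enumerate(lin_idx):
            sign = -1.0 if k < int(np.ceil(2 * n_lin / 3)) else 1.0
            slope_map[(int(iu[0][e]), int(iu[1][e]))] = sign * 0.004
        quad_map = {}
        for k, e in enumerate(quad_idx):
            sign = -1.0 if k < int(np.ceil(2 * n_quad / 3)) else 1.0
            quad_map[(int(iu[0][e]), int(iu[1][e]))] = sign * 1.5e-4
        n_dec = int(round(0.7 * p))
        n_inc = int(round(0.1 * p))
        falff_slope = np.zeros(p)
        order = rng.permutation(p)
        falff_slope[order[:n_dec]] = -8e-4
        falff_slope[order[n_dec : n_dec + n_inc]] = 5e-4
        quad_nodes = order[n_dec + n_inc : n_dec + n_inc + 4]
        falff_quad_map = {int(v): 2e-5 for v in quad_nodes}
        cfg = replace(
            cfg,
            age_slope_map=slope_map,
            quadratic_edge_map=quad_map,
            falff_age_slope=falff_slope,
            falff_quadratic_map=falff_quad_map,
        )
    return cfg


def default_paired_configs(
    n_internal: int = 200,
    n_external: int = 80,
    n_nodes: int = 50,
    n_volumes_internal: int = 600,
    n_volumes_external: int = 160,
    tr_internal: float = 0.645,
    tr_external: float = 2.5,
    seed: int = 7,
    external_noise_sd_z: float = 0.08,
    external_falff_subject_sd: float = 0.08,
) -> tuple[GeneratorConfig, GeneratorConfig]:
    """Internal/external config pair emulating a two-protocol study.

    The internal cohort uses a fast multiband-like acquisition, the external
    cohort a slow conventional one; the external cohort additionally carries
    elevated subject-level connectivity and fALFF noise, standing in for the
    site/protocol/sample differences that degrade external validation
    relative to internal cross-validation.
    """
    cfg_int = default_config(
        n_subjects=n_internal, n_nodes=n_nodes, n_volumes=n_volumes_internal,
        tr_seconds=tr_internal, seed=seed, cohort_label="internal",
    )
    cfg_ext = default_config(
        n_subjects=n_external, n_nodes=n_nodes, n_volumes=n_volumes_external,
        tr_seconds=tr_external, seed=seed + 1, cohort_label="external",
        structure_seed=cfg_int.structure_seed,
    )
    cfg_ext = replace(
        cfg_ext,
        noise_sd_z=external_noise_sd_z,
        falff_subject_sd=external_falff_subject_sd,
    )
    return cfg_int, cfg_ext


# --------------------------------------------------------------------------
# ground truth construction


def _sparse_to_matrix(p: int, entries: dict[tuple[int, int], float]) -> np.ndarray:
    out = np.zeros((p, p))
    for (i, j), v in entries.items():
        if not (0 <= i < j < p):
            raise ConfigurationError(f"edge ({i}, {j}) is not an upper-triangle pair")
        out[i, j] = out[j, i] = v
    return out


def make_ground_truth(config: GeneratorConfig) -> GroundTruth:
    """Build the planted structure from the structure seed (subject draws untouched)."""
    p = config.n_nodes
    partition = make_partition(config)
    rng = np.random.default_rng(
        (config.structure_seed if config.structure_seed is not None else config.seed)
        + 77_003
    )
    net = partition["network"].to_numpy()
    same = net[:, None] == net[None, :]
    B = np.where(same, config.baseline_within_z, config.baseline_between_z).astype(float)
    jitter = rng.normal(0.0, config.baseline_jitter_sd, size=(p, p))
    B = B + np.triu(jitter, k=1) + np.triu(jitter, k=1).T
    np.fill_diagonal(B, 0.0)
    # make the baseline itself a valid correlation pattern with spectral
    # headroom, so per-subject age/noise deviations rarely need projection
    # (an active projection would shrink planted effects)
    Rb = np.tanh(B)
    np.fill_diagonal(Rb, 1.0)
    Cb = nearest_correlation(Rb, eig_floor=config.baseline_eig_floor)
    B = np.arctanh(np.clip(Cb, -1 + 1e-9, 1 - 1e-9))
    np.fill_diagonal(B, 0.0)
    A = _sparse_to_matrix(p, config.age_slope_map)
    Q = _sparse_to_matrix(p, config.quadratic_edge_map)
    base = np.broadcast_to(np.asarray(config.falff_base, float), (p,)).copy()
    slope = np.broadcast_to(np.asarray(config.falff_age_slope, float), (p,)).copy()
    quad = np.zeros(p)
    for node, c in config.falff_quadratic_map.items():
        quad[node] = c
    age_mean = 0.5 * (config.age_range[0] + config.age_range[1])
    return GroundTruth(B, A, Q, base, slope, quad, age_mean, partition)


# --------------------------------------------------------------------------
# numerical pieces


def nearest_correlation(r_matrix: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest valid correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the diagonal renormalized to
    unit; deterministic and idempotent on already-valid inputs.
    """
    sym = 0.5 * (r_matrix + r_matrix.T)
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eig_floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = 0.5 * (fixed + fixed.T)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _spectral_shapes(n_volumes: int, tr: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Discrete power shapes of the low-band and broadband components.

    Both are unit-total-power over the rfft grid; the low-band component is
    an ideal band-limited process on [0.01, 0.1] Hz.
    """
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    low_mask = (freqs >= 0.01) & (freqs <= 0.1)
    if low_mask.sum() < 3:
        raise ConfigurationError("series too short to resolve the 0.01-0.1 Hz band")
    s_low = low_mask / low_mask.sum()
    pos = freqs > 0
    s_broad = pos / pos.sum()
    return freqs, s_low.astype(float), s_broad.astype(float)


def expected_falff_of_mix(
    w: np.ndarray, n_volumes: int, tr: float
) -> np.ndarray:
    """Expected amplitude-spectrum fALFF of the mixture w*low + (1-w)*broad.

    The amplitude of each periodogram bin scales with the square root of its
    expected power with a bin-independent constant, so the expected band
    ratio is a deterministic, strictly increasing function of the low-band
    weight ``w``.
    """
    freqs, s_low, s_broad = _spectral_shapes(n_volumes, tr)
    nyq = freqs[-1]
    total_hi = min(0.25, nyq)
    low_sel = (freqs >= 0.01) & (freqs <= 0.1)
    tot_sel = (freqs >= 0.01) & (freqs <= total_hi)
    w = np.atleast_1d(np.asarray(w, float))
    power = w[:, None] * s_low[None, :] + (1.0 - w[:, None]) * s_broad[None, :]
    amp = np.sqrt(power)
    return amp[:, low_sel].sum(axis=1) / amp[:, tot_sel].sum(axis=1)


def solve_lowband_weights(
    targets: np.ndarray, n_volumes: int, tr: float, tol: float = 0.02
) -> np.ndarray:
    """Invert ``expected_falff_of_mix`` by monotone bisection, per node.

    Targets outside (0, 1) or below the broadband floor by more than ``tol``
    raise a :class:`ConfigurationError`; targets within tolerance are clipped
    into the attainable range.
    """
    targets = np.asarray(targets, float)
    if np.any(targets <= -tol) or np.any(targets >= 1.0 + tol):
        raise ConfigurationError("fALFF target outside (0, 1) beyond tolerance")
    floor = float(expected_falff_of_mix(np.array([0.0]), n_volumes, tr)[0])
    lo_ok = floor + 1e-4
    if np.any(targets < floor - tol):
        raise ConfigurationError(
            f"fALFF target below the broadband floor {floor:.3f} — unattainable "
            "under the low-band mixing model"
        )
    t = np.clip(targets, lo_ok, 0.995)
    lo = np.zeros_like(t)
    hi = np.ones_like(t)
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        val = expected_falff_of_mix(mid, n_volumes, tr)
        too_low = val < t
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def _ideal_lowband(noise: np.ndarray, tr: float) -> np.ndarray:
    """Ideal-mask band-pass of each row to [0.01, 0.1] Hz, unit row variance."""
    T = noise.shape[-1]
    freqs = np.fft.rfftfreq(T, d=tr)
    mask = (freqs >= 0.01) & (freqs <= 0.1)
    spec = np.fft.rfft(noise, axis=-1)
    spec[..., ~mask] = 0.0
    out = np.fft.irfft(spec, n=T, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


# --------------------------------------------------------------------------
# generation


def generate_cohort(
    config: GeneratorConfig, truth: GroundTruth | None = None
) -> SubjectCohort:
    """Generate one cohort of ROI time series with planted structure.

    See :class:`GeneratorConfig` for the target model.  Target z-matrices are
    mapped edgewise to correlations (inverse Fisher transform), projected to
    the nearest valid correlation matrix, and realized by coloring Gaussian
    noise with a symmetric square-root factor.  The same factor colors both
    the broadband and the band-limited low-frequency component, so the
    cross-node correlation target survives the per-node spectral mixing that
    sets expected fALFF.
    """
    truth = truth if truth is not None else make_ground_truth(config)
    if truth.baseline_z.shape[0] != config.n_nodes:
        raise ConfigurationError("ground truth node count does not match config")
    p, T = config.n_nodes, config.n_volumes
    n = config.n_subjects
    rng = np.random.default_rng(config.seed)

    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=n)
    sex = rng.integers(0, 2, size=n).astype(int)
    z_age = (ages - ages.mean()) / ages.std()
    rho = config.fd_age_correlation
    latent = rho * z_age + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=n)
    fd = np.exp(np.log(0.08) + 0.4 * latent)
    tiv = rng.normal(1350.0, 110.0, size=n) * (1.0 + config.tiv_sex_offset * sex)

    # validate the noiseless fALFF trajectory over the age range once;
    # subject-level deviations are clipped into the attainable range below
    for a in (config.age_range[0], truth.age_mean, config.age_range[1]):
        d = a - truth.age_mean
        solve_lowband_weights(
            truth.falff_base + truth.falff_slope * d + truth.falff_quad * d**2,
            T, config.tr_seconds,
        )
    falff_floor = float(expected_falff_of_mix(np.array([0.0]), T, config.tr_seconds)[0])

    centered = ages - truth.age_mean
    series = np.empty((n, p, T))
    targets = np.empty((n, p, p))
    for i in range(n):
        Z = (
            truth.baseline_z
            + centered[i] * truth.age_slope
            + centered[i] ** 2 * truth.quad_curvature
        )
        if config.noise_sd_z > 0:
            E = rng.normal(0.0, config.noise_sd_z, size=(p, p))
            Z = Z + np.triu(E, k=1) + np.triu(E, k=1).T
        targets[i] = Z
        R = np.tanh(Z)
        np.fill_diagonal(R, 1.0)
        C = nearest_correlation(R)
        if not np.all(np.isfinite(C)):
            raise GenerationError(f"non-projectable target matrix for subject {i}")
        vals, vecs = np.linalg.eigh(C)
        factor = vecs * np.sqrt(np.clip(vals, 0.0, None))

        falff_target = (
            truth.falff_base
            + truth.falff_slope * centered[i]
            + truth.falff_quad * centered[i] ** 2
        )
        if config.falff_subject_sd > 0:
            falff_target = falff_target + rng.normal(0.0, config.falff_subject_sd, p)
        falff_target = np.clip(falff_target, falff_floor + 1e-3, 0.99)
        w = solve_lowband_weights(falff_target, T, config.tr_seconds)

        broad = factor @ rng.normal(size=(p, T))
        low = factor @ _ideal_lowband(rng.normal(size=(p, T)), config.tr_seconds)
        sw = np.sqrt(w)[:, None]
        series[i] = sw * low + np.sqrt(1.0 - w)[:, None] * broad

    metadata = pd.DataFrame(
        {
            "subject_id": [f"{config.cohort_label}-{i:04d}" for i in range(n)],
            "age": ages,
            "sex": sex,
            "fd": fd,
            "tiv": tiv,
            "cohort": config.cohort_label,
        }
    )
    return SubjectCohort(
        time_series=series,
        metadata=metadata,
        partition=truth.partition,
        ground_truth=truth,
        tr_seconds=config.tr_seconds,
        target_z=targets,
    )


def generate_paired_cohorts(
    config_internal: GeneratorConfig,
    config_external: GeneratorConfig,
    shared_truth: bool = True,
) -> tuple[SubjectCohort, SubjectCohort]:
    """Generate internal/external cohorts, optionally sharing planted structure.

    With ``shared_truth`` the two cohorts share the same baseline and
    age-effect patterns (the regime of scanning distinct samples of one
    population with different protocols); acquisition parameters and subject
    draws still differ per config.
    """
    if config_internal.n_nodes != config_external.n_nodes:
        raise ConfigurationError("paired cohorts must share n_nodes")
    if tuple(config_internal.network_sizes) != tuple(config_external.network_sizes):
        raise ConfigurationError("paired cohorts must share the node partition")
    truth = make_ground_truth(config_internal)
    internal = generate_cohort(config_internal, truth=truth)
    ext_truth = truth if shared_truth else make_ground_truth(config_external)
    external = generate_cohort(config_external, truth=ext_truth)
    return internal, external


# --------------------------------------------------------------------------
# on-disk interchange (plain text)


def write_cohort(cohort: SubjectCohort, out_dir) -> None:
    """Write per-subject TSV series, metadata.csv, partition.tsv, truth TSVs."""
    from pathlib import Path

    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(cohort.metadata["subject_id"]):
        path = out / "timeseries" / f"{sid}.tsv"
        with open(path, "w") as fh:
            fh.write(f"# tr_seconds={cohort.tr_seconds}\n")
            np.savetxt(fh, cohort.time_series[i], delimiter="\t", fmt="%.6f")
    cohort.metadata.to_csv(out / "metadata.csv", index=False)
    cohort.partition.to_csv(out / "partition.tsv", sep="\t", index=False)
    gt = cohort.ground_truth
    np.savetxt(out / "truth_baseline_z.tsv", gt.baseline_z, delimiter="\t")
    np.savetxt(out / "truth_age_slope.tsv", gt.age_slope, delimiter="\t")
    np.savetxt(out / "truth_quad_curvature.tsv", gt.quad_curvature, delimiter="\t")
    np.savetxt(
        out / "truth_falff.tsv",
        np.column_stack([gt.falff_base, gt.falff_slope, gt.falff_quad]),
        delimiter="\t",
        header="base\tslope\tquad",
    )
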
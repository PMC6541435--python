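"""Multi-subject, multi-run mode-based fMRI simulator.

Builds a 1-D "brain" of contiguous atlas parcels, assembles overlapping
weighted node maps from parcel groups, warps them per subject (simulated
misalignment), generates sparse correlated "neural" timecourses with a
low-frequency spectral bias, convolves them with subject-specific
haemodynamic response functions, combines timecourses and maps through a
saturating outer-product model, and adds structured (low-rank) plus
heavy-tailed unstructured noise.  Everything needed to reconstruct the data
exactly — including the seed of the voxelwise noise — is recorded in the
returned ground-truth bundle.

The 1-D voxel line is sufficient for every downstream estimator (ICA, dual
regression, netmats), which never use spatial geometry beyond vectorised
maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import special
from scipy.ndimage import uniform_filter1d
from scipy.stats import wishart

from .containers import GroundTruthBundle, NetMat

__all__ = [
    "ModesSimConfig",
    "Atlas",
    "WarpField",
    "generate_atlas",
    "generate_warps",
    "generate_node_maps",
    "generate_timecourses",
    "make_hrf",
    "hrf_convolve",
    "assemble_data",
    "simulate_modes",
    "reconstruct_unstructured_noise",
]


@dataclass
class ModesSimConfig:
    """Configuration for the mode-based simulator.

    Structural defaults (10,000 voxels, 30 subjects, 2 runs of 600
    timepoints, 100 parcels, 15 modes) match the study conditions; the
    distribution parameters are chosen to give reasonable but not excessive
    spatial overlap between modes, moderate inter-mode temporal correlation,
    and roughly unit signal-to-noise.  All of them are recorded with the
    output, so every run is self-describing.
    """

    n_voxels: int = 10_000
    n_subjects: int = 30
    n_runs: int = 2
    n_timepoints: int = 600
    n_repeats: int = 10
    n_parcels: int = 100
    n_modes: int = 15

    # atlas
    parcel_width_concentration: float = 5.0
    parcel_weight_shape: float = 3.0
    parcel_weight_scale: float = 1.0 / 3.0

    # node maps
    regions_per_mode_rate: float = 1.5  # n_regions = 1 + Poisson(rate)
    parcel_budget_beta_a: float = 2.0
    parcel_budget_beta_b: float = 4.0
    parcel_budget_max: int = 12
    parcels_per_region_concentration: float = 2.0
    negative_region_prob: float = 0.2
    max_mode_overlap: float = 0.5  # redraw a mode whose group-map |r| with an
    #   existing mode exceeds this: overlap stays "reasonable, not excessive"
    subject_weight_jitter: float = 0.25

    # warps
    warp_smoothness: int = 500  # boxcar width in voxels
    warp_amplitude: float = 1.0  # max displacement in units of avg parcel size

    # timecourses
    tr: float = 1.0  # nominal repetition time, seconds
    lowfreq_knee: float = 0.1  # Hz; spectral power concentrated below this
    wishart_dof_group: int = 50
    wishart_dof_subject: int = 100
    wishart_dof_run: int = 150
    sparsify_threshold: float = 0.3  # in SD units; entries below are zeroed

    # HRF
    hrf_length: float = 24.0  # seconds
    hrf_coeff_mean: tuple = (1.0, 0.2, 0.1)
    hrf_coeff_sd: tuple = (0.1, 0.1, 0.05)

    # outer product + noise
    nonlinearity_strength: float = 0.2
    structured_noise_rank: int = 10
    structured_noise_var_frac: float = 0.1
    unstructured_t_dof: float = 10.0  # weakly non-Gaussian voxel noise
    unstructured_var_frac: float = 0.3

    emit_dtype: str = "float32"  # emitted data precision (internals are float64)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_parcels > self.n_voxels:
            raise ValueError("n_parcels must not exceed n_voxels")
        if self.n_modes > self.n_parcels:
            raise ValueError("n_modes must not exceed n_parcels")
        for name in ("n_voxels", "n_subjects", "n_runs", "n_timepoints",
                     "n_parcels", "n_modes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("wishart_dof_group", "wishart_dof_subject", "wishart_dof_run"):
            if getattr(self, name) < self.n_modes:
                raise ValueError(f"{name} must be >= n_modes")
        if self.nonlinearity_strength < 0:
            raise ValueError("nonlinearity_strength must be >= 0")
        if not 0 <= self.negative_region_prob <= 1:
            raise ValueError("negative_region_prob must lie in [0, 1]")
        if self.warp_amplitude < 0 or self.warp_smoothness < 1:
            raise ValueError("invalid warp parameters")


@dataclass
class Atlas:
    """Contiguous half-open parcel intervals tiling [0, n_voxels)."""

    boundaries: np.ndarray  # (n_parcels + 1,) ints, boundaries[0]=0, [-1]=n_voxels
    weights: np.ndarray  # (n_parcels,) positive parcel weights

    @property
    def n_parcels(self) -> int:
        return len(self.weights)

    @property
    def n_voxels(self) -> int:
        return int(self.boundaries[-1])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    @property
    def average_parcel_size(self) -> float:
        return self.n_voxels / self.n_parcels

    def parcel_of_voxel(self) -> np.ndarray:
        """Parcel index for every voxel."""
        return np.repeat(np.arange(self.n_parcels), self.widths)

    def voxel_map(self, parcel_values: np.ndarray) -> np.ndarray:
        """Expand per-parcel values to a voxel map (weighted by parcel weight)."""
        return np.repeat(parcel_values * self.weights, self.widths)


@dataclass
class WarpField:
    """Signed voxel displacement; subject map value v -> map(v + displacement)."""

    displacement: np.ndarray  # (n_voxels,)

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Resample a voxel map at the warped coordinates (linear, edge-clamped)."""
        n = len(self.displacement)
        coords = np.arange(n) + self.displacement
        return np.interp(coords, np.arange(n), values)

    @property
    def is_identity(self) -> bool:
        return not np.any(self.displacement)


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Round nonnegative fractions (summing to 1) to ints summing to total."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    # deterministic ties: larger remainder first, then lower index
    order = np.lexsort((np.arange(len(raw)), -(raw - base)))
    base[order[:short]] += 1
    return base


def generate_atlas(config: ModesSimConfig, rng: np.random.Generator,
                   max_retries: int = 50) -> Atlas:
    """Dirichlet parcel widths (integer, summing to n_voxels) + Gamma weights."""
    alpha = np.full(config.n_parcels, config.parcel_width_concentration)
    for _ in range(max_retries):
        widths = _largest_remainder(rng.dirichlet(alpha), config.n_voxels)
        if np.all(widths >= 1):
            break
    else:
        raise RuntimeError(f"could not draw all-nonzero parcel widths in {max_retries} tries")
    weights = rng.gamma(config.parcel_weight_shape, config.parcel_weight_scale,
                        size=config.n_parcels)
    boundaries = np.concatenate([[0], np.cumsum(widths)])
    return Atlas(boundaries=boundaries, weights=weights)


def generate_warps(config: ModesSimConfig, rng: np.random.Generator,
                   atlas: Atlas) -> list[WarpField]:
    """Per-subject smooth, invertible 1-D warps.

    The warp *gradient* is boxcar-smoothed Gaussian noise squashed through
    tanh (range [-1, 1], so the voxel mapping is monotone and invertible);
    the cumulative displacement is rescaled so its maximum magnitude is
    ``warp_amplitude`` times the average parcel size (never upscaled beyond
    gradient 1).  Amplitude 0 gives the identity warp.
    """
    warps = []
    for _ in range(config.n_subjects):
        if config.warp_amplitude == 0:
            warps.append(WarpField(np.zeros(config.n_voxels)))
            # keep the stream aligned regardless of amplitude
            rng.standard_normal(config.n_voxels)
            continue
        noise = rng.standard_normal(config.n_voxels)
        smooth = uniform_filter1d(noise, size=config.warp_smoothness, mode="reflect")
        smooth = smooth / max(smooth.std(), 1e-12)
        grad = np.tanh(1.5 * smooth)
        disp = np.cumsum(grad)
        disp = disp - disp.mean()
        target = config.warp_amplitude * atlas.average_parcel_size
        scale = min(target / max(np.abs(disp).max(), 1e-12), 1.0)
        warps.append(WarpField(scale * disp))
    return warps


def generate_node_maps(
    config: ModesSimConfig,
    rng: np.random.Generator,
    atlas: Atlas,
    warps: list[WarpField] | None = None,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Group and per-subject node maps built from atlas parcels.

    Each mode is a weighted sum of parcels grouped into contiguous regions:
    region count ~ 1 + Poisson, total parcel budget ~ scaled Beta, split over
    regions by a Dirichlet; each region may be anticorrelated (negative
    weight) except the largest, and parcel weights are Gamma draws.  Subject
    maps share the parcel identities but have multiplicative log-normal
    weight jitter, and are finally resampled through the subject warp.

    Returns ``(group_maps, subject_maps, group_parcel_weights)`` where
    ``group_parcel_weights`` is the (n_modes, n_parcels) assignment matrix.
    """
    p = config.n_parcels
    parcel_w = np.zeros((config.n_modes, p))
    group_rows: list[np.ndarray] = []

    def _draw_mode() -> np.ndarray:
        w_row = np.zeros(p)
        n_regions = 1 + rng.poisson(config.regions_per_mode_rate)
        budget = int(round(rng.beta(config.parcel_budget_beta_a,
                                    config.parcel_budget_beta_b)
                           * config.parcel_budget_max))
        budget = min(max(budget, n_regions), p)
        sizes = _largest_remainder(
            rng.dirichlet(np.full(n_regions, config.parcels_per_region_concentration)),
            budget,
        )
        sizes = np.maximum(sizes, 1)
        signs = np.where(rng.random(n_regions) < config.negative_region_prob, -1.0, 1.0)
        signs[np.argmax(sizes)] = 1.0  # anchor: largest region is positive
        for size, sgn in zip(sizes, signs):
            size = int(min(size, p))
            start = int(rng.integers(0, p - size + 1))
            w = rng.gamma(config.parcel_weight_shape, config.parcel_weight_scale,
                          size=size)
            w_row[start:start + size] += sgn * w
        return w_row

    for m in range(config.n_modes):
        for _ in range(100):
            w_row = _draw_mode()
            if not np.any(w_row):
                continue
            vox = atlas.voxel_map(w_row)
            if group_rows:
                prev = np.vstack(group_rows)
                c = np.corrcoef(np.vstack([prev, vox]))[-1, :-1]
                if np.abs(c).max() > config.max_mode_overlap:
                    continue  # a near-duplicate mode: redraw
            parcel_w[m] = w_row
            group_rows.append(vox)
            break
        else:
            raise RuntimeError(f"mode {m}: could not draw a sufficiently "
                               "distinct non-empty mode")

    group_maps = np.vstack(group_rows)

    jitter = config.subject_weight_jitter
    subject_maps = []
    for s in range(config.n_subjects):
        if jitter > 0:
            factors = np.exp(jitter * rng.standard_normal((config.n_modes, p))
                             - 0.5 * jitter**2)
        else:
            factors = np.ones((config.n_modes, p))
        pw = parcel_w * factors
        maps = np.vstack([atlas.voxel_map(pw[m]) for m in range(config.n_modes)])
        if warps is not None and not warps[s].is_identity:
            maps = np.vstack([warps[s].apply(maps[m]) for m in range(config.n_modes)])
        subject_maps.append(maps)
    return group_maps, subject_maps, parcel_w


def _random_lowfreq_series(rng: np.random.Generator, n: int, tr: float,
                           knee: float, n_series: int) -> np.ndarray:
    """Random-phase series with spectral power concentrated below ``knee`` Hz."""
    freqs = np.fft.rfftfreq(n, d=tr)
    envelope = 1.0 / np.sqrt(1.0 + (freqs / knee) ** 4)
    envelope[0] = 0.0  # no DC
    spec = (rng.standard_normal((len(freqs), n_series))
            + 1j * rng.standard_normal((len(freqs), n_series))) * envelope[:, None]
    x = np.fft.irfft(spec, n=n, axis=0)
    x = x - x.mean(axis=0)
    return x / x.std(axis=0)


def generate_timecourses(
    config: ModesSimConfig, rng: np.random.Generator
) -> tuple[dict[tuple[int, int], np.ndarray], dict]:
    """Sparse, correlated "neural" timecourses per subject and run.

    Inter-mode correlations are induced by a hierarchy of Wishart draws
    (group -> subject -> run, each centred on the level above); the series
    are then sparsified by zeroing timepoints below ``sparsify_threshold``
    (in SD units).  Returns the per-(subject, run) series and a record of the
    drawn covariances and realized (post-sparsification) correlations.
    """
    k = config.n_modes
    eye = np.eye(k)
    cov_group = wishart.rvs(config.wishart_dof_group, eye / config.wishart_dof_group,
                            random_state=rng)
    record = {"cov_group": cov_group, "cov_subject": [], "cov_run": {},
              "realized_corr": {}}
    series: dict[tuple[int, int], np.ndarray] = {}
    thr = config.sparsify_threshold
    for s in range(config.n_subjects):
        cov_s = wishart.rvs(config.wishart_dof_subject,
                            cov_group / config.wishart_dof_subject, random_state=rng)
        record["cov_subject"].append(cov_s)
        for r in range(config.n_runs):
            cov_r = wishart.rvs(config.wishart_dof_run,
                                cov_s / config.wishart_dof_run, random_state=rng)
            record["cov_run"][(s, r)] = cov_r
            d = np.sqrt(np.diag(cov_r))
            corr = cov_r / np.outer(d, d)
            corr = corr + 1e-9 * eye
            chol = np.linalg.cholesky(corr)
            x = _random_lowfreq_series(rng, config.n_timepoints, config.tr,
                                       config.lowfreq_knee, k)
            y = x @ chol.T
            y = (y - y.mean(axis=0)) / y.std(axis=0)
            if np.isfinite(thr):
                y = np.where(y < thr, 0.0, y)
            elif thr == -np.inf:
                pass
            else:  # +inf
                y = np.zeros_like(y)
            if np.any(~np.any(y != 0, axis=0)):
                raise ValueError(
                    "sparsification threshold zeroed an entire timecourse; lower it"
                )
            series[(s, r)] = y
            record["realized_corr"][(s, r)] = np.corrcoef(y, rowvar=False)
    return series, record


def make_hrf(config: ModesSimConfig, rng: np.random.Generator) -> np.ndarray:
    """One subject's HRF kernel: a perturbed canonical double-gamma.

    The kernel is a random combination (coefficients Gaussian around
    ``hrf_coeff_mean``) of the canonical double-gamma response and its
    temporal and dispersion derivatives — a subject-varying HRF shape with
    the same role as a draw from an empirical HRF basis.  Normalised to unit
    peak.
    """
    t = np.arange(0, config.hrf_length, config.tr)

    def dgamma(a1=6.0, b1=1.0, a2=16.0, b2=1.0, c=1.0 / 6.0):
        g1 = np.exp((a1 - 1) * np.log(np.maximum(t, 1e-12)) - b1 * t
                    + a1 * np.log(b1) - special.gammaln(a1))
        g2 = np.exp((a2 - 1) * np.log(np.maximum(t, 1e-12)) - b2 * t
                    + a2 * np.log(b2) - special.gammaln(a2))
        return g1 - c * g2

    h = dgamma()
    dt = np.gradient(h, config.tr)  # temporal derivative
    dd = (dgamma(b1=1.01) - h) / 0.01  # dispersion derivative
    basis = [b / np.linalg.norm(b) for b in (h, dt, dd)]
    coeffs = np.asarray(config.hrf_coeff_mean) + \
        np.asarray(config.hrf_coeff_sd) * rng.standard_normal(3)
    kernel = sum(c * b for c, b in zip(coeffs, basis))
    peak = np.abs(kernel).max()
    if peak == 0 or not np.all(np.isfinite(kernel)):
        raise ValueError("degenerate HRF kernel")
    return kernel / peak


def hrf_convolve(neural: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve each mode's series with the HRF, truncated to input length."""
    kernel = np.asarray(kernel, dtype=np.float64)
    if not np.all(np.isfinite(kernel)):
        raise ValueError("non-finite HRF kernel")
    n = neural.shape[0]
    out = sp_signal.fftconvolve(neural, kernel[:, None], mode="full", axes=0)
    return out[:n]


def _saturate(x: np.ndarray, strength: float) -> np.ndarray:
    """Weak saturating nonlinearity c*tanh(x/c); identity at strength 0."""
    if strength < 0:
        raise ValueError("nonlinearity strength must be >= 0")
    if strength == 0:
        return x
    c = float(np.sqrt(np.mean(x**2))) / strength
    return c * np.tanh(x / c)


def assemble_data(
    timecourses: np.ndarray,
    maps: np.ndarray,
    config: ModesSimConfig,
    rng: np.random.Generator,
    *,
    noise_seed: int | None = None,
) -> tuple[np.ndarray, dict]:
    """One run's data: saturate(T @ M) + structured + heavy-tailed noise.

    Structured noise is a sum of ``structured_noise_rank`` outer products of
    Gaussian maps and timecourses; unstructured noise is i.i.d. Student's t
    (regenerable from ``noise_seed``).  Both are scaled to the configured
    variance fractions of the signal.  Returns ``(data, record)`` where the
    record holds every component needed for exact reconstruction.
    """
    signal = timecourses @ maps
    signal_nl = _saturate(signal, config.nonlinearity_strength)
    sig_var = float(signal_nl.var())
    t_len, n_vox = signal.shape

    record: dict = {"nonlinearity_strength": config.nonlinearity_strength}
    data = signal_nl.copy()

    rank = config.structured_noise_rank
    if rank > 0 and config.structured_noise_var_frac > 0:
        smaps = rng.standard_normal((rank, n_vox))
        sts = rng.standard_normal((t_len, rank))
        struct = sts @ smaps
        struct *= np.sqrt(config.structured_noise_var_frac * sig_var / struct.var())
        data += struct
        record["structured_maps"] = smaps
        record["structured_ts"] = sts
        record["structured_scale"] = float(
            np.sqrt(config.structured_noise_var_frac * sig_var / (sts @ smaps).var()))

    if config.unstructured_var_frac > 0:
        if noise_seed is None:
            noise_seed = int(rng.integers(2**31 - 1))
        nrng = np.random.default_rng(noise_seed)
        t_noise = nrng.standard_t(config.unstructured_t_dof, size=(t_len, n_vox))
        nu = config.unstructured_t_dof
        t_sd = np.sqrt(nu / (nu - 2)) if nu > 2 else t_noise.std()
        scale = np.sqrt(config.unstructured_var_frac * sig_var) / t_sd
        data += scale * t_noise
        record["unstructured_seed"] = noise_seed
        record["unstructured_scale"] = float(scale)

    record["signal_var"] = sig_var
    return data.astype(config.emit_dtype), record


def reconstruct_unstructured_noise(config: ModesSimConfig, record: dict,
                                   shape: tuple[int, int]) -> np.ndarray:
    """Regenerate the recorded Student-t noise realization bit-identically."""
    nrng = np.random.default_rng(record["unstructured_seed"])
    return record["unstructured_scale"] * nrng.standard_t(
        config.unstructured_t_dof, size=shape)


def simulate_modes(config: ModesSimConfig) -> tuple[list[list[np.ndarray]], GroundTruthBundle]:
    """Simulate one repeat of the full mode-based dataset.

    Returns ``(data, truth)`` where ``data[subject][run]`` is a
    ``(n_timepoints, n_voxels)`` matrix.  The bundle's
    ``true_subject_timecourses`` are the pre-HRF sparse neural series
    (concatenated over runs); the HRF-convolved clean series and their
    netmats live in ``extras['bold_timecourses']`` / ``extras['bold_tnet']``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    atlas = generate_atlas(config, rng)
    warps = generate_warps(config, rng, atlas)
    group_maps, subject_maps, parcel_weights = generate_node_maps(
        config, rng, atlas, warps)
    neural, tc_record = generate_timecourses(config, rng)
    hrfs = [make_hrf(config, rng) for _ in range(config.n_subjects)]

    data: list[list[np.ndarray]] = []
    noise_records: dict[tuple[int, int], dict] = {}
    bold_by_run: dict[tuple[int, int], np.ndarray] = {}
    tnets, snets, bold_tnets = [], [], []
    true_ts_concat, bold_ts_concat = [], []

    for s in range(config.n_subjects):
        runs = []
        neural_runs, bold_runs = [], []
        for r in range(config.n_runs):
            bold = hrf_convolve(neural[(s, r)], hrfs[s])
            bold = (bold - bold.mean(axis=0)) / bold.std(axis=0)
            y, rec = assemble_data(bold, subject_maps[s], config, rng)
            runs.append(y)
            noise_records[(s, r)] = rec
            bold_by_run[(s, r)] = bold
            neural_runs.append(neural[(s, r)])
            bold_runs.append(bold)
        data.append(runs)
        nts = np.concatenate(neural_runs, axis=0)
        bts = np.concatenate(bold_runs, axis=0)
        true_ts_concat.append(nts)
        bold_ts_concat.append(bts)
        tnets.append(NetMat(np.corrcoef(nts, rowvar=False), "temporal", s, "truth"))
        bold_tnets.append(NetMat(np.corrcoef(bts, rowvar=False), "temporal", s,
                                 "truth-bold"))
        snets.append(NetMat(np.corrcoef(subject_maps[s]), "spatial", s, "truth"))

    truth = GroundTruthBundle(
        true_group_maps=group_maps,
        true_subject_maps=subject_maps,
        true_subject_timecourses=true_ts_concat,
        true_tnet=tnets,
        true_snet=snets,
        seed=config.seed,
        config=config,
        extras={
            "atlas": atlas,
            "warps": warps,
            "parcel_weights": parcel_weights,
            "hrfs": hrfs,
            "neural_by_run": neural,
            "bold_by_run": bold_by_run,
            "bold_timecourses": bold_ts_concat,
            "bold_tnet": bold_tnets,
            "timecourse_record": tc_record,
            "noise_records": noise_records,
        },
    )
    return data, truth
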
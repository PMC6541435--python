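"""Two-node overlapping outer-product simulator.

Generates the minimal dataset that exposes the dual-regression overlap bias:
two spatial nodes whose supports overlap by a configurable fraction, placed on
a Laplacian background, multiplied against per-node timecourses that share a
common component (so the true temporal correlation is positive).  Per-subject
data are the exact outer product of the subject's timecourses and (noisy)
subject maps — all randomness is recorded in the returned
:class:`~overlapdr.containers.GroundTruthBundle`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GroundTruthBundle, NetMat


@dataclass
class OverlapSimConfig:
    """Configuration for the two-node overlap simulator.

    Defaults reproduce the study conditions: 50 subjects with 200 timepoints
    over 10,000 voxels; each node occupies 100 voxels of which 25% are shared;
    node weights are uniform on [2, 12] added onto a Laplacian(0, 0.5)
    background.  ``shared_signal_weight`` mixes a common Gaussian series into
    both node timecourses; the default sqrt(2/3) yields a population true
    temporal correlation of w^2/(1+w^2) = 0.4.  ``map_noise_scale`` is the
    standard deviation of the additive Gaussian per-subject map noise; the
    default is 0.1 x the mean node weight.
    """

    n_voxels: int = 10_000
    n_subjects: int = 50
    n_timepoints: int = 200
    n_repeats: int = 10
    n_nodes: int = 2
    node_size: int = 100
    overlap_fraction: float = 0.25
    background_scale: float = 0.5
    weight_low: float = 2.0
    weight_high: float = 12.0
    shared_signal_weight: float = float(np.sqrt(2.0 / 3.0))
    map_noise_scale: float | None = None  # default: 0.1 * mean node weight
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_overlap_voxels(self) -> int:
        return int(round(self.node_size * self.overlap_fraction))

    @property
    def resolved_map_noise_scale(self) -> float:
        if self.map_noise_scale is not None:
            return float(self.map_noise_scale)
        return 0.1 * 0.5 * (self.weight_low + self.weight_high)

    def validate(self) -> None:
        for name in ("n_voxels", "n_subjects", "n_timepoints", "n_repeats", "node_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_nodes != 2:
            raise ValueError("the overlap simulator is defined for exactly 2 nodes")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        shared = self.node_size * self.overlap_fraction
        if abs(shared - round(shared)) > 1e-9:
            raise ValueError(
                f"node_size * overlap_fraction = {shared} is not an integer voxel count"
            )
        if self.weight_low > self.weight_high:
            raise ValueError("weight_low must not exceed weight_high")
        # two nodes sharing n_overlap voxels need this many voxels in total
        if 2 * self.node_size - self.n_overlap_voxels > self.n_voxels:
            raise ValueError("node regions exceed n_voxels")


def _node_supports(config: OverlapSimConfig, rng: np.random.Generator):
    """Contiguous index ranges for the two nodes, overlapping as configured."""
    n_shared = config.n_overlap_voxels
    total = 2 * config.node_size - n_shared
    start = int(rng.integers(0, config.n_voxels - total + 1))
    node_a = np.arange(start, start + config.node_size)
    node_b = np.arange(start + config.node_size - n_shared,
                       start + 2 * config.node_size - n_shared)
    return node_a, node_b


def _standardize(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-(sample)-variance columns."""
    x = x - x.mean(axis=0)
    return x / x.std(axis=0)


def simulate_overlap(config: OverlapSimConfig) -> tuple[list[np.ndarray], GroundTruthBundle]:
    """Simulate one repeat of the two-node overlap dataset.

    Returns ``(data, truth)`` where ``data`` is a list of per-subject
    ``(n_timepoints, n_voxels)`` matrices and ``truth`` records group maps,
    per-subject noisy maps, timecourses, and the true temporal/spatial
    netmats.  The emitted data equal ``T @ M`` exactly for the stored
    components (the only noise is in the subject maps, which are stored).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    node_a, node_b = _node_supports(config, rng)
    overlap = np.intersect1d(node_a, node_b)

    # Group maps: Laplacian background everywhere + uniform node weights
    # added on the node support.  Drawn once per repeat.
    group = rng.laplace(0.0, config.background_scale,
                        size=(2, config.n_voxels)) if config.background_scale > 0 else \
        np.zeros((2, config.n_voxels))
    weights_a = rng.uniform(config.weight_low, config.weight_high, size=config.node_size)
    weights_b = rng.uniform(config.weight_low, config.weight_high, size=config.node_size)
    group[0, node_a] += weights_a
    group[1, node_b] += weights_b

    sigma_map = config.resolved_map_noise_scale
    w = config.shared_signal_weight

    data: list[np.ndarray] = []
    subj_maps: list[np.ndarray] = []
    subj_ts: list[np.ndarray] = []
    tnets: list[NetMat] = []
    snets: list[NetMat] = []
    map_noise: list[np.ndarray] = []

    for s in range(config.n_subjects):
        noise = (rng.normal(0.0, sigma_map, size=group.shape)
                 if sigma_map > 0 else np.zeros_like(group))
        maps = group + noise

        e = rng.standard_normal((config.n_timepoints, 2))
        shared = rng.standard_normal((config.n_timepoints, 1))
        ts = _standardize(e + w * shared)

        y = ts @ maps
        data.append(y)
        subj_maps.append(maps)
        subj_ts.append(ts)
        map_noise.append(noise)
        tnets.append(NetMat(np.corrcoef(ts, rowvar=False), "temporal", s, "truth"))
        snets.append(NetMat(np.corrcoef(maps), "spatial", s, "truth"))

    truth = GroundTruthBundle(
        true_group_maps=group,
        true_subject_maps=subj_maps,
        true_subject_timecourses=subj_ts,
        true_tnet=tnets,
        true_snet=snets,
        seed=config.seed,
        config=config,
        extras={
            "node_supports": [node_a, node_b],
            "overlap_voxels": overlap,
            "node_weights": [weights_a, weights_b],
            "map_noise": map_noise,
            "realized_temporal_edges": np.array([t.values[0, 1] for t in tnets]),
            "realized_spatial_edges": np.array([s_.values[0, 1] for s_ in snets]),
        },
    )
    return data, truth
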
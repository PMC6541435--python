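"""Shared in-memory containers.

Conventions used throughout the package:

* a *data matrix* (one subject/run's BOLD data) is ``(n_timepoints, n_voxels)``;
* a *spatial map set* is ``(n_modes, n_voxels)``;
* a *timeseries set* is ``(n_timepoints, n_modes)``;
* a *netmat* is an ``(n_modes, n_modes)`` symmetric Pearson correlation matrix.

Plain ``numpy`` arrays are used for the first three; :class:`NetMat` and
:class:`GroundTruthBundle` carry the light metadata the pipeline needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class NetMat:
    """A modes x modes full-correlation matrix.

    ``kind`` distinguishes temporal network matrices (correlations between
    node timecourses) from spatial overlap matrices (correlations between
    vectorised node maps).  ``source`` records which pipeline stage produced
    the underlying timeseries/maps (e.g. ``"stage1"``, ``"truth"``).
    """

    values: np.ndarray
    kind: str  # "temporal" | "spatial"
    subject: int | str | None = None
    source: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"netmat must be square, got shape {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("netmat must be symmetric")
        self.values = v

    @property
    def n_modes(self) -> int:
        return self.values.shape[0]


@dataclass
class GroundTruthBundle:
    """Everything a simulator knows about the data it emitted.

    The stored components are sufficient to reconstruct the emitted data
    exactly: ``data = nonlinearity(T @ M) + noise`` with the recorded noise,
    where ``T`` are the per-subject true timecourses and ``M`` the per-subject
    true maps (for the overlap simulator the nonlinearity is the identity and
    the noise lives in the maps themselves).
    """

    true_group_maps: np.ndarray  # (n_modes, n_voxels)
    true_subject_maps: list[np.ndarray]  # each (n_modes, n_voxels)
    true_subject_timecourses: list[np.ndarray]  # each (n_timepoints, n_modes)
    true_tnet: list[NetMat]  # per subject, correlations of true timecourses
    true_snet: list[NetMat]  # per subject, correlations of true maps
    seed: int
    config: Any = None
    extras: dict[str, Any] = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.true_subject_maps)

    @property
    def n_modes(self) -> int:
        return self.true_group_maps.shape[0]


def as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    """Accept either a seed or a Generator and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
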
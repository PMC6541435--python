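"""Temporal network matrices and spatial overlap matrices.

A temporal edge is the full Pearson correlation between two node
timecourses; a spatial edge is the full Pearson correlation between two
vectorised node spatial maps.  Both are assembled into modes x modes
symmetric matrices with unit diagonal.
"""

from __future__ import annotations

import numpy as np

from .containers import NetMat

__all__ = ["temporal_netmat", "spatial_netmat", "fisher_z", "edge_vector", "edges_to_netmat"]


def temporal_netmat(ts: np.ndarray, subject: int | str | None = None,
                    source: str = "") -> NetMat:
    """Full Pearson correlation matrix of timeseries columns."""
    ts = np.asarray(ts, dtype=np.float64)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("need a (timepoints >= 3, modes) timeseries matrix")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0].tolist()
        raise ValueError(f"constant timeseries column(s): modes {bad}")
    c = np.corrcoef(ts, rowvar=False)
    return NetMat(np.clip(c, -1.0, 1.0), "temporal", subject, source)


def spatial_netmat(maps: np.ndarray, subject: int | str | None = None,
                   source: str = "") -> NetMat:
    """Full Pearson correlation matrix of (vectorised) spatial map rows."""
    maps = np.asarray(maps, dtype=np.float64)
    if maps.ndim != 2 or maps.shape[1] < 3:
        raise ValueError("need a (modes, voxels >= 3) map matrix")
    sd = maps.std(axis=1)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0].tolist()
        raise ValueError(f"constant (or all-zero) map(s): modes {bad}")
    c = np.corrcoef(maps)
    return NetMat(np.clip(c, -1.0, 1.0), "spatial", subject, source)


def fisher_z(r):
    """Fisher r-to-z transform, atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    return np.arctanh(r) if r.ndim else float(np.arctanh(r))


def edge_vector(netmat: NetMat | np.ndarray) -> np.ndarray:
    """Row-major upper triangle (excluding diagonal), length n(n-1)/2."""
    v = netmat.values if isinstance(netmat, NetMat) else np.asarray(netmat)
    i, j = np.triu_indices(v.shape[0], k=1)
    return v[i, j]


def edges_to_netmat(edges: np.ndarray, n_modes: int) -> np.ndarray:
    """Inverse of :func:`edge_vector` (unit diagonal)."""
    out = np.eye(n_modes)
    i, j = np.triu_indices(n_modes, k=1)
    out[i, j] = edges
    out[j, i] = edges
    return out
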
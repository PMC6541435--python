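"""Group-level spatial ICA via temporal concatenation.

Subjects' data matrices are temporally demeaned, stacked along time, reduced
to ``n_modes`` principal components, and unmixed so that the estimated
spatial maps are maximally independent across voxels.  Because the maps come
out of a whitening rotation, their sample correlations are (by construction)
zero — the spatial-independence constraint that suppresses true spatial
overlap between modes.

The PCA step uses a randomized SVD (cheap for the small mode counts used
here) and the ICA rotation itself is delegated to scikit-learn's FastICA with
``whiten=False`` on the pre-whitened spatial basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning


@dataclass
class GroupDecomposition:
    """Result of group spatial ICA.

    ``group_maps`` is ``(n_modes, n_voxels)`` with zero-mean, unit-variance
    rows; ``mixing`` is the ``(total_timepoints, n_modes)`` concatenated
    component timecourse matrix (the temporal side of the decomposition);
    ``explained_variance`` orders the components.
    """

    group_maps: np.ndarray
    mixing: np.ndarray
    pca_dim: int
    explained_variance: np.ndarray
    singular_values: np.ndarray
    contrast: float
    n_restarts_used: int
    converged: bool
    seed: int


def _randomized_svd(x: np.ndarray, k: int, rng: np.random.Generator,
                    n_oversamples: int = 10, n_iter: int = 4):
    """Truncated SVD by randomized range finding, in the input dtype.

    All large products stay in ``x``'s dtype (no float64 upcast of the data
    stack); only the small projected problem is solved in double precision.
    """
    n, m = x.shape
    l = min(k + n_oversamples, min(n, m))
    omega = rng.standard_normal((m, l)).astype(x.dtype, copy=False)
    q = x @ omega
    for _ in range(n_iter):
        q, _ = np.linalg.qr(q)
        z = x.T @ q
        z, _ = np.linalg.qr(z)
        q = x @ z
    q, _ = np.linalg.qr(q)
    b = (q.T @ x).astype(np.float64)  # (l, m), small
    ub, s, vt = np.linalg.svd(b, full_matrices=False)
    u = q.astype(np.float64) @ ub
    return u[:, :k], s[:k], vt[:k]


def _logcosh_contrast(sources: np.ndarray) -> float:
    """Negentropy proxy: sum over components of (E[log cosh s] - gauss)^2."""
    gauss = 0.3746  # E[log cosh Z], Z ~ N(0,1)
    vals = np.mean(np.log(np.cosh(sources)), axis=0)
    return float(np.sum((vals - gauss) ** 2))


def group_ica(
    data: list[np.ndarray] | np.ndarray,
    n_modes: int,
    seed: int = 0,
    *,
    variance_normalize: bool = False,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 10,
    svd_n_iter: int = 4,
) -> GroupDecomposition:
    """Temporal-concatenation group spatial ICA.

    Parameters
    ----------
    data
        List of per-subject ``(timepoints, voxels)`` matrices (or a single
        matrix).  All subjects must share the voxel dimension.
    n_modes
        Number of components; also the PCA dimension (no automatic
        dimensionality estimation).
    variance_normalize
        If True, scale each voxel's timeseries to unit variance per subject
        before concatenation (off by default).

    Returns a :class:`GroupDecomposition` with components ordered by explained
    variance and signs fixed so the heavier tail of each map is positive.
    """
    if isinstance(data, np.ndarray):
        data = [data]
    n_voxels = data[0].shape[1]
    for i, y in enumerate(data):
        if y.ndim != 2 or y.shape[1] != n_voxels:
            raise ValueError(f"subject {i}: expected (timepoints, {n_voxels}), got {y.shape}")
    total_t = sum(y.shape[0] for y in data)
    if total_t < n_modes:
        raise ValueError("total timepoints must be at least n_modes")

    # Temporal demeaning per voxel within subject, then concatenation.
    # The stack is preallocated once (in the input dtype) to bound memory.
    dtype = np.result_type(np.float32, *(y.dtype for y in data))
    x = np.empty((total_t, n_voxels), dtype=dtype)
    offset = 0
    for y in data:
        block = x[offset:offset + y.shape[0]]
        np.copyto(block, y)
        block -= block.mean(axis=0, keepdims=True)
        if variance_normalize:
            sd = block.std(axis=0, keepdims=True)
            sd[sd == 0] = 1.0
            block /= sd
        offset += y.shape[0]

    rng = np.random.default_rng(seed)
    u, s, vt = _randomized_svd(x, n_modes, rng, n_iter=svd_n_iter)
    if s[-1] <= max(x.shape) * np.finfo(float).eps * s[0]:
        raise np.linalg.LinAlgError(
            f"data are rank deficient: singular value {n_modes} is "
            f"{s[-1]:.3e} vs leading {s[0]:.3e}"
        )

    # Whiten the spatial basis across voxels (rows of vt): exact zero mean,
    # identity covariance, so FastICA only has to find a rotation.
    b = vt.astype(np.float64) - vt.mean(axis=1, keepdims=True).astype(np.float64)
    cov = (b @ b.T) / n_voxels
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * evals[-1]:
        raise np.linalg.LinAlgError("whitening failed: degenerate spatial basis")
    z = (evecs / np.sqrt(evals)).T @ b  # (n_modes, n_voxels), cov == I

    best = None
    n_used = 0
    for restart in range(n_restarts):
        n_used = restart + 1
        w_init = rng.standard_normal((n_modes, n_modes))
        ica = FastICA(
            whiten=False, fun="logcosh",
            tol=tol, max_iter=max_iter, w_init=w_init,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                sources = ica.fit_transform(z.T)  # (n_voxels, n_modes)
            except ConvergenceWarning:
                continue
        contrast = _logcosh_contrast(sources / sources.std(axis=0, keepdims=True))
        if best is None or contrast > best[0]:
            best = (contrast, sources)
        break  # first converged restart wins; later seeds only used on failure
    if best is None:
        raise RuntimeError(
            f"FastICA did not converge in {n_restarts} restarts "
            f"(tol={tol}, max_iter={max_iter})"
        )
    contrast, sources = best

    maps = sources.T  # (n_modes, n_voxels)
    maps = maps - maps.mean(axis=1, keepdims=True)
    maps = maps / maps.std(axis=1, keepdims=True)

    # Sign: heavier tail positive (positive skew), deterministic.
    sk = skew(maps, axis=1)
    signs = np.where(sk >= 0, 1.0, -1.0)
    maps = maps * signs[:, None]

    # Timecourses / explained variance: least-squares projection of the
    # concatenated data onto the maps (small n_modes x n_modes solve).
    # The projection runs in the data's dtype to avoid a full upcast copy.
    gram = maps @ maps.T
    proj = maps.astype(x.dtype, copy=False) @ x.T  # (n_modes, total_t)
    mixing = np.linalg.solve(gram, proj.astype(np.float64)).T  # (total_t, n_modes)
    ev = mixing.var(axis=0) * n_voxels  # maps are unit variance rows
    order = np.argsort(ev)[::-1]

    return GroupDecomposition(
        group_maps=np.ascontiguousarray(maps[order]),
        mixing=np.ascontiguousarray(mixing[:, order]),
        pca_dim=n_modes,
        explained_variance=ev[order],
        singular_values=s,
        contrast=contrast,
        n_restarts_used=n_used,
        converged=True,
        seed=seed,
    )
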
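"""Dual regression, including mixture-model-thresholded stages 3-4.

Standard dual regression maps a set of group spatial maps to subject-specific
timecourses (stage 1: multiple *spatial* regression of each timepoint's voxel
vector on the group maps) and subject-specific maps (stage 2: multiple
*temporal* regression of each voxel's timeseries on the stage-1
timecourses).  When the true networks overlap in space, the stage-1
timecourse covariance absorbs the true spatial covariance (inflating temporal
edges) and the stage-2 maps are weighted by the inverse of that covariance
(deflating spatial edges).

The corrective extension adds two stages: stage 3 fits a Gaussian/Gamma
mixture model (Gaussian background, positive and negative Gamma tails) to
each stage-2 map, shifts/rescales the map by the background mean and standard
deviation, and zeroes everything with |z| < 2; stage 4 re-runs the spatial
regression against the thresholded maps.  The stage-4 timecourses are the
ones to use for temporal network matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.optimize import brentq

__all__ = [
    "DualRegResult",
    "MixtureFit",
    "dual_regression",
    "fit_ggm",
    "stage1",
    "stage2",
    "stage3_threshold",
    "stage4",
]

_COND_THRESHOLD = 1e8


# ---------------------------------------------------------------------------
# regression stages
# ---------------------------------------------------------------------------

def _check_design_condition(design: np.ndarray, what: str) -> None:
    """Raise if regressors are (near-)collinear, naming the offending pair."""
    cond = np.linalg.cond(design)
    if cond > _COND_THRESHOLD:
        c = np.corrcoef(design)
        np.fill_diagonal(c, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(c)), c.shape)
        raise np.linalg.LinAlgError(
            f"collinear {what} (condition number {cond:.3g}); "
            f"worst pair ({i}, {j}) with |r| = {abs(c[i, j]):.4f}"
        )


def _spatial_regression(y: np.ndarray, maps: np.ndarray, what: str) -> np.ndarray:
    """Regress each timepoint's voxel vector on all maps jointly.

    Maps are demeaned across voxels; data are demeaned per timepoint across
    voxels (equivalent to including an intercept).  Returns
    ``(timepoints, n_modes)`` coefficients.
    """
    if y.ndim != 2 or maps.ndim != 2 or y.shape[1] != maps.shape[1]:
        raise ValueError(
            f"shape mismatch: data {y.shape} vs maps {maps.shape} (voxels must agree)"
        )
    g = maps - maps.mean(axis=1, keepdims=True)
    _check_design_condition(g, what)
    yd = y - y.mean(axis=1, keepdims=True)
    gram = g @ g.T
    return np.linalg.solve(gram, g @ yd.T).T


def stage1(y: np.ndarray, group_maps: np.ndarray) -> np.ndarray:
    """Stage 1: subject timecourses from spatial regression on group maps."""
    return _spatial_regression(np.asarray(y, dtype=np.float64),
                               np.asarray(group_maps, dtype=np.float64),
                               "group maps")


def stage2(y: np.ndarray, ts: np.ndarray, *, normalize: bool = True) -> np.ndarray:
    """Stage 2: subject maps from temporal regression on stage-1 timecourses.

    The timeseries design is demeaned (and, by default, scaled to unit
    variance) per column; the data are demeaned across time per voxel.  This
    is the pseudo-inverse solution ``pinv(A) @ Y`` applied voxel-wise.
    """
    y = np.asarray(y, dtype=np.float64)
    ts = np.asarray(ts, dtype=np.float64)
    if ts.shape[0] != y.shape[0]:
        raise ValueError(f"timepoint mismatch: data {y.shape} vs timeseries {ts.shape}")
    if ts.shape[0] <= ts.shape[1]:
        raise ValueError("need more timepoints than modes")
    a = ts - ts.mean(axis=0, keepdims=True)
    if normalize:
        sd = a.std(axis=0)
        if np.any(sd == 0):
            raise np.linalg.LinAlgError("constant timeseries column in stage-2 design")
        a = a / sd
    _check_design_condition(a.T, "stage-1 timeseries")
    yd = y - y.mean(axis=0, keepdims=True)
    gram = a.T @ a
    return np.linalg.solve(gram, a.T @ yd)


def stage4(y: np.ndarray, thresholded_maps: np.ndarray) -> np.ndarray:
    """Stage 4: re-estimate timecourses against stage-3 thresholded maps."""
    m = np.asarray(thresholded_maps, dtype=np.float64)
    zero = ~np.any(m != 0, axis=1)
    if np.any(zero):
        raise ValueError(
            f"all-zero thresholded map(s) in stage-4 design: modes {np.where(zero)[0].tolist()}"
        )
    return _spatial_regression(np.asarray(y, dtype=np.float64), m, "thresholded maps")


# ---------------------------------------------------------------------------
# Gaussian/Gamma mixture model
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Parameters of a Gaussian-background + two-Gamma-tail mixture.

    The Gammas are offset to start at the (robustly initialised) background
    mean; ``mixing`` is ``(background, positive tail, negative tail)`` and
    sums to 1.  ``loglik_path`` records the (non-decreasing) EM
    log-likelihood trajectory of the final fit.
    """

    mu: float
    sigma: float
    pos_shape: float
    pos_scale: float
    pos_offset: float
    neg_shape: float
    neg_scale: float
    neg_offset: float
    mixing: np.ndarray
    log_likelihood: float
    loglik_path: np.ndarray
    n_iter: int
    converged: bool
    components_dropped: bool


def _gamma_logpdf(d: np.ndarray, shape: float, scale: float) -> np.ndarray:
    """log Gamma(d; shape, scale) with density 0 (log -> -inf) for d <= 0."""
    out = np.full(d.shape, -np.inf)
    pos = d > 0
    dp = d[pos]
    out[pos] = (
        (shape - 1.0) * np.log(dp) - dp / scale
        - shape * np.log(scale) - special.gammaln(shape)
    )
    return out


def _gamma_mle(mean_d: float, mean_log_d: float) -> tuple[float, float]:
    """Weighted-MLE Gamma (shape, scale) from sufficient statistics."""
    s = np.log(mean_d) - mean_log_d
    if s <= 0:  # numerically degenerate (near-constant excursions)
        return 1e4, mean_d / 1e4
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(40):  # Newton refinement of log(k) - psi(k) = s
        f = np.log(k) - special.digamma(k) - s
        fp = 1.0 / k - special.polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < 1e-10 * k:
            k = k_new
            break
        k = k_new
    k = float(np.clip(k, 1e-2, 1e6))
    return k, mean_d / k


def _gamma_mle_fixed_mean(mean_target: float, mean_d: float, mean_log_d: float
                          ) -> tuple[float, float]:
    """Gamma MLE constrained to mean shape*scale == mean_target."""
    def score(k: float) -> float:
        return (np.log(k) - np.log(mean_target) + 1.0 - special.digamma(k)
                + mean_log_d - mean_d / mean_target)

    lo, hi = 1e-2, 1e6
    if score(lo) * score(hi) > 0:
        k = 1.0 if score(lo) < 0 else hi
    else:
        k = brentq(score, lo, hi, xtol=1e-8)
    return float(k), mean_target / float(k)


def fit_ggm(
    values: np.ndarray,
    *,
    max_iter: int = 300,
    tol: float = 1e-5,
    drop_mixing_floor: float = 1e-3,
    drop_count_floor: float = 10.0,
    min_tail_separation: float = 1.0,
    separation_drop_floor: float = 2.5,
) -> MixtureFit:
    """EM fit of the Gaussian/Gamma mixture to one spatial map's weights.

    The background Gaussian is initialised from interquartile-range-trimmed
    sample moments; the Gamma tails from the moments of excursions beyond
    one (trimmed) standard deviation.  The Gamma offsets are fixed at the
    initial background mean, and each Gamma's mean is constrained to at least
    ``min_tail_separation`` initial standard deviations away from it (so the
    tails cannot collapse onto the background of a pure-Gaussian map).  With
    the offsets and constraint fixed up front, every M-step maximises the
    expected complete-data log-likelihood over a fixed feasible set, so the
    likelihood path is non-decreasing.

    A tail is dropped (``components_dropped``) when its mixing proportion
    falls below ``drop_mixing_floor``, its responsibility-weighted voxel
    count below ``drop_count_floor``, or its fitted mean lies within
    ``separation_drop_floor`` background standard deviations of the
    background mean — an unseparated "tail" is just background being
    absorbed (the failure mode on a pure-Gaussian map).  Remaining
    components are then refit.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ValueError(f"need at least 100 finite values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate all-constant map")

    # Robust background init: moments of the interquartile core, with the
    # truncated-normal variance correction (middle 50% of a Gaussian has
    # SD 0.3776 sigma).
    q1, q3 = np.percentile(x, [25, 75])
    core = x[(x >= q1) & (x <= q3)]
    mu0 = float(core.mean())
    sigma0 = float(core.std() / 0.3776) or float(x.std())
    offset = mu0
    min_tail_mean = min_tail_separation * sigma0

    dp = x - offset  # positive-tail excursions
    dn = offset - x  # negative-tail excursions

    def _tail_init(d: np.ndarray) -> tuple[float, float]:
        exc = d[d > sigma0]
        if exc.size < 10:
            return 2.0, max(min_tail_mean, sigma0) / 2.0
        m, v = float(exc.mean()), float(exc.var())
        m = max(m, min_tail_mean)
        v = max(v, 1e-12)
        k = max(m * m / v, 1e-2)
        return k, m / k

    kp, tp = _tail_init(dp)
    kn, tn = _tail_init(dn)
    mixing = np.array([0.9, 0.05, 0.05])
    mu, sigma = mu0, sigma0

    active = [True, True]  # positive / negative tail present
    dropped = False
    loglik_path: list[float] = []
    n_iter = 0
    converged = False

    def _run_em(mu, sigma, kp, tp, kn, tn, mixing):
        nonlocal n_iter, converged
        path: list[float] = []
        prev = -np.inf
        converged = False
        for it in range(max_iter):
            logp = np.full((3, x.size), -np.inf)
            if mixing[0] > 0:
                logp[0] = (np.log(mixing[0]) - 0.5 * np.log(2 * np.pi) - np.log(sigma)
                           - 0.5 * ((x - mu) / sigma) ** 2)
            if active[0] and mixing[1] > 0:
                logp[1] = np.log(mixing[1]) + _gamma_logpdf(dp, kp, tp)
            if active[1] and mixing[2] > 0:
                logp[2] = np.log(mixing[2]) + _gamma_logpdf(dn, kn, tn)
            m = logp.max(axis=0)
            tot = m + np.log(np.sum(np.exp(logp - m), axis=0))
            ll = float(tot.sum())
            path.append(ll)
            r = np.exp(logp - tot)  # responsibilities (3, n)

            if abs(ll - prev) < tol * (abs(ll) + 1.0):
                converged = True
                n_iter = it + 1
                break
            prev = ll

            # M-step
            counts = r.sum(axis=1)
            mixing = counts / x.size
            mu = float((r[0] @ x) / counts[0])
            sigma = float(np.sqrt((r[0] @ (x - mu) ** 2) / counts[0]))
            if not np.isfinite(sigma):
                raise np.linalg.LinAlgError("background sigma became non-finite")
            # floor against collapse onto a point mass (e.g. refitting an
            # already-thresholded map whose background is exactly zero)
            sigma = max(sigma, 1e-9 * float(np.ptp(x)))
            for side, (d, idx) in enumerate([(dp, 1), (dn, 2)]):
                if not active[side] or counts[idx] <= 0:
                    continue
                pos = d > 0
                w = r[idx][pos]
                wsum = w.sum()
                if wsum <= 0:
                    continue
                md = float((w @ d[pos]) / wsum)
                mld = float((w @ np.log(d[pos])) / wsum)
                if md >= min_tail_mean:
                    k, th = _gamma_mle(md, mld)
                    if k * th < min_tail_mean:
                        k, th = _gamma_mle_fixed_mean(min_tail_mean, md, mld)
                else:
                    k, th = _gamma_mle_fixed_mean(min_tail_mean, md, mld)
                if side == 0:
                    kp, tp = k, th
                else:
                    kn, tn = k, th
        else:
            n_iter = max_iter
        return mu, sigma, kp, tp, kn, tn, mixing, path

    mu, sigma, kp, tp, kn, tn, mixing, loglik_path = _run_em(
        mu, sigma, kp, tp, kn, tn, mixing)

    # Tail-dropping rule, then refit remaining components.
    def _weak(idx: int) -> bool:
        return mixing[idx] < drop_mixing_floor or mixing[idx] * x.size < drop_count_floor

    def _unseparated(mean: float) -> bool:
        return mean < separation_drop_floor * sigma

    drop_pos = active[0] and (_weak(1) or _unseparated(kp * tp))
    drop_neg = active[1] and (_weak(2) or _unseparated(kn * tn))
    if drop_pos or drop_neg:
        dropped = True
        if drop_pos:
            active[0] = False
        if drop_neg:
            active[1] = False
        keep = np.array([True, active[0], active[1]])
        mixing = np.where(keep, mixing, 0.0)
        mixing = mixing / mixing.sum()
        mu, sigma, kp, tp, kn, tn, mixing, loglik_path = _run_em(
            mu, sigma, kp, tp, kn, tn, mixing)

    return MixtureFit(
        mu=mu, sigma=sigma,
        pos_shape=kp, pos_scale=tp, pos_offset=offset,
        neg_shape=kn, neg_scale=tn, neg_offset=offset,
        mixing=np.asarray(mixing, dtype=float),
        log_likelihood=loglik_path[-1],
        loglik_path=np.asarray(loglik_path),
        n_iter=n_iter,
        converged=converged,
        components_dropped=dropped,
    )


def stage3_threshold(
    maps: np.ndarray,
    fits: list[MixtureFit],
    *,
    z_threshold: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stage 3: z-score each map by its background fit and zero |z| < 2.

    Surviving voxels keep their signed z value (the boundary |z| == 2
    survives).  Returns ``(thresholded_maps, all_zero_flags)``.
    """
    maps = np.asarray(maps, dtype=np.float64)
    if maps.shape[0] != len(fits):
        raise ValueError("need exactly one mixture fit per map")
    out = np.zeros_like(maps)
    for i, fit in enumerate(fits):
        if fit.sigma <= 0:
            raise ValueError(f"mode {i}: zero background sigma")
        if not fit.converged:
            warnings.warn(
                f"mode {i}: mixture fit did not converge; thresholding with best fit",
                RuntimeWarning, stacklevel=2,
            )
        z = (maps[i] - fit.mu) / fit.sigma
        out[i] = np.where(np.abs(z) >= z_threshold, z, 0.0)
    all_zero = ~np.any(out != 0, axis=1)
    return out, all_zero


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

@dataclass
class DualRegResult:
    """All stages of (optionally thresholded) dual regression for one subject."""

    stage1_timeseries: np.ndarray
    stage2_maps: np.ndarray
    stage3_maps: np.ndarray | None = None
    stage4_timeseries: np.ndarray | None = None
    mixture_fits: list[MixtureFit] = field(default_factory=list)
    all_zero_maps: np.ndarray | None = None

    @property
    def n_modes(self) -> int:
        return self.stage2_maps.shape[0]


def dual_regression(
    y: np.ndarray,
    group_maps: np.ndarray,
    *,
    thresholded: bool = True,
    normalize_timeseries: bool = True,
    z_threshold: float = 2.0,
    ggm_kwargs: dict | None = None,
) -> DualRegResult:
    """Run dual regression stages 1-2 (and, by default, 3-4) on one subject."""
    ts1 = stage1(y, group_maps)
    maps2 = stage2(y, ts1, normalize=normalize_timeseries)
    result = DualRegResult(stage1_timeseries=ts1, stage2_maps=maps2)
    if thresholded:
        fits = [fit_ggm(maps2[i], **(ggm_kwargs or {})) for i in range(maps2.shape[0])]
        maps3, flags = stage3_threshold(maps2, fits, z_threshold=z_threshold)
        result.mixture_fits = fits
        result.stage3_maps = maps3
        result.all_zero_maps = flags
        result.stage4_timeseries = stage4(y, maps3)
    return result
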
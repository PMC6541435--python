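"""Matching estimated components to ground truth and accuracy metrics.

ICA components are identified only up to permutation and sign, so every
comparison with ground truth starts with an optimal assignment (Hungarian
algorithm on the absolute spatial-correlation matrix).  The accuracy metrics
are: (i) per-subject timeseries correlation, (ii) per-subject map
correlation, (iii) per-edge cross-subject correlation of temporal edges, and
(iv) the same for spatial edges; plus raw bias distributions
(estimated - truth) per edge, and the positive-spatial-edge subset analysis
used to quantify absolute bias where true overlap exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .containers import GroundTruthBundle
from .netmats import edge_vector, fisher_z

__all__ = [
    "MatchResult",
    "EvalReport",
    "match_components",
    "accuracy_metrics",
    "positive_edge_subset",
    "tnet_snet_association",
]


@dataclass
class MatchResult:
    """Truth-mode -> estimated-mode assignment with signs.

    ``permutation[t]`` is the estimated mode matched to truth mode ``t``;
    ``signs[t]`` aligns its orientation.  ``included`` flags truth modes whose
    group-average matched correlation reaches the inclusion threshold
    (default 0.5); edges incident to excluded modes are left out of the
    edge-level metrics.
    """

    permutation: np.ndarray
    signs: np.ndarray
    matched_correlations: np.ndarray
    group_average_correlations: np.ndarray
    included: np.ndarray
    inclusion_threshold: float = 0.5

    def align_maps(self, est_maps: np.ndarray) -> np.ndarray:
        return est_maps[self.permutation] * self.signs[:, None]

    def align_timeseries(self, est_ts: np.ndarray) -> np.ndarray:
        return est_ts[:, self.permutation] * self.signs[None, :]


def _row_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross-correlation matrix between rows of a and rows of b."""
    az = (a - a.mean(axis=1, keepdims=True))
    bz = (b - b.mean(axis=1, keepdims=True))
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz /= np.linalg.norm(bz, axis=1, keepdims=True)
    return az @ bz.T


def match_components(
    est_maps: np.ndarray,
    true_maps: np.ndarray,
    *,
    est_subject_maps: list[np.ndarray] | None = None,
    true_subject_maps: list[np.ndarray] | None = None,
    inclusion_threshold: float = 0.5,
) -> MatchResult:
    """Optimal truth->estimate assignment maximising total |spatial r|.

    When per-subject maps are supplied, the inclusion rule uses the group
    average of the per-subject matched correlations; otherwise it uses the
    group-map matched correlations directly.
    """
    est_maps = np.asarray(est_maps, dtype=np.float64)
    true_maps = np.asarray(true_maps, dtype=np.float64)
    if est_maps.shape != true_maps.shape:
        raise ValueError("estimated and true map sets must have equal shapes")
    for name, m in (("estimated", est_maps), ("true", true_maps)):
        if np.any(m.std(axis=1) == 0):
            raise ValueError(f"degenerate all-constant {name} map")

    c = _row_corr(true_maps, est_maps)
    rows, cols = linear_sum_assignment(-np.abs(c))
    perm = cols[np.argsort(rows)]
    matched = c[np.arange(len(perm)), perm]
    signs = np.where(matched >= 0, 1.0, -1.0)

    if est_subject_maps is not None and true_subject_maps is not None:
        per_subj = []
        for em, tm in zip(est_subject_maps, true_subject_maps):
            cc = _row_corr(tm, em[perm] * signs[:, None])
            per_subj.append(np.diag(cc))
        group_avg = np.mean(per_subj, axis=0)
    else:
        group_avg = np.abs(matched)

    return MatchResult(
        permutation=perm,
        signs=signs,
        matched_correlations=matched,
        group_average_correlations=group_avg,
        included=group_avg >= inclusion_threshold,
        inclusion_threshold=inclusion_threshold,
    )


@dataclass
class EvalReport:
    """Accuracy metrics (i)-(iv) plus raw edge bias distributions."""

    timeseries_accuracy: np.ndarray  # (n_subjects, n_modes), metric (i)
    map_accuracy: np.ndarray  # (n_subjects, n_modes), metric (ii)
    tnet_edge_accuracy: np.ndarray  # (n_edges,), metric (iii)
    snet_edge_accuracy: np.ndarray  # (n_edges,), metric (iv)
    temporal_bias: np.ndarray  # (n_subjects, n_edges), est - truth (raw r)
    spatial_bias: np.ndarray  # (n_subjects, n_edges)
    est_temporal_edges: np.ndarray  # (n_subjects, n_edges)
    est_spatial_edges: np.ndarray
    true_temporal_edges: np.ndarray
    true_spatial_edges: np.ndarray
    edge_modes: np.ndarray  # (n_edges, 2) truth-mode indices per edge
    included_modes: np.ndarray
    fisher: bool = True


def _corr_cols(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Columnwise Pearson correlation between two equal-shape matrices."""
    az = a - a.mean(axis=0)
    bz = b - b.mean(axis=0)
    denom = np.linalg.norm(az, axis=0) * np.linalg.norm(bz, axis=0)
    return np.sum(az * bz, axis=0) / denom


def accuracy_metrics(
    est_timeseries: list[np.ndarray],
    est_maps: list[np.ndarray],
    truth: GroundTruthBundle,
    match: MatchResult,
    *,
    true_timeseries: list[np.ndarray] | None = None,
    use_fisher: bool = True,
) -> EvalReport:
    """Compute metrics (i)-(iv) and bias distributions against ground truth.

    ``est_timeseries``/``est_maps`` are per-subject, in estimated-mode order;
    the match is applied internally.  ``true_timeseries`` overrides the
    bundle's stored timecourses (used when the estimate can at best recover a
    transformed version, e.g. HRF-convolved, of the stored series).
    Edge-level metrics (iii)/(iv) are computed on Fisher-z-transformed edges
    by default; the bias distributions are always raw correlation units.
    """
    n_subj = len(est_timeseries)
    if n_subj != truth.n_subjects or len(est_maps) != n_subj:
        raise ValueError("subject count mismatch between estimates and truth")
    true_ts = true_timeseries if true_timeseries is not None else truth.true_subject_timecourses

    n_modes = truth.n_modes
    iu = np.vstack(np.triu_indices(n_modes, k=1)).T  # (n_edges, 2)
    keep_edge = match.included[iu[:, 0]] & match.included[iu[:, 1]]
    iu = iu[keep_edge]

    ts_acc = np.empty((n_subj, n_modes))
    map_acc = np.empty((n_subj, n_modes))
    est_t_edges = np.empty((n_subj, len(iu)))
    est_s_edges = np.empty((n_subj, len(iu)))
    true_t_edges = np.empty((n_subj, len(iu)))
    true_s_edges = np.empty((n_subj, len(iu)))

    for s in range(n_subj):
        a_ts = match.align_timeseries(np.asarray(est_timeseries[s], dtype=np.float64))
        a_maps = match.align_maps(np.asarray(est_maps[s], dtype=np.float64))
        ts_acc[s] = _corr_cols(a_ts, np.asarray(true_ts[s], dtype=np.float64))
        map_acc[s] = _corr_cols(a_maps.T, np.asarray(truth.true_subject_maps[s]).T)
        est_t = np.corrcoef(a_ts, rowvar=False)
        est_s = np.corrcoef(a_maps)
        est_t_edges[s] = est_t[iu[:, 0], iu[:, 1]]
        est_s_edges[s] = est_s[iu[:, 0], iu[:, 1]]
        true_t_edges[s] = truth.true_tnet[s].values[iu[:, 0], iu[:, 1]]
        true_s_edges[s] = truth.true_snet[s].values[iu[:, 0], iu[:, 1]]

    if n_subj >= 3:
        if use_fisher:
            clip = lambda e: np.clip(e, -0.999999, 0.999999)
            t_est, t_true = fisher_z(clip(est_t_edges)), fisher_z(clip(true_t_edges))
            s_est, s_true = fisher_z(clip(est_s_edges)), fisher_z(clip(true_s_edges))
        else:
            t_est, t_true, s_est, s_true = est_t_edges, true_t_edges, est_s_edges, true_s_edges
        tnet_acc = _corr_cols(t_est, t_true)
        snet_acc = _corr_cols(s_est, s_true)
    else:
        raise ValueError("cross-subject edge metrics need at least 3 subjects")

    return EvalReport(
        timeseries_accuracy=ts_acc,
        map_accuracy=map_acc,
        tnet_edge_accuracy=tnet_acc,
        snet_edge_accuracy=snet_acc,
        temporal_bias=est_t_edges - true_t_edges,
        spatial_bias=est_s_edges - true_s_edges,
        est_temporal_edges=est_t_edges,
        est_spatial_edges=est_s_edges,
        true_temporal_edges=true_t_edges,
        true_spatial_edges=true_s_edges,
        edge_modes=iu,
        included_modes=match.included,
        fisher=use_fisher,
    )


def positive_edge_subset(
    true_spatial_edges: list[np.ndarray],
    *,
    alpha: float = 0.05,
) -> tuple[np.ndarray, int]:
    """Edges with significantly positive true spatial correlation.

    ``true_spatial_edges`` holds one ``(n_subjects, n_edges)`` array per
    simulation repeat.  Per repeat and edge, a one-tailed t-test of the true
    spatial edges > 0 across subjects is Bonferroni-corrected over the full
    family of ``n_edges * n_repeats`` comparisons.  Returns a boolean
    ``(n_repeats, n_edges)`` survival mask and the family size.
    """
    n_repeats = len(true_spatial_edges)
    if n_repeats < 1:
        raise ValueError("need at least one repeat")
    n_edges = true_spatial_edges[0].shape[1]
    family = n_edges * n_repeats
    mask = np.zeros((n_repeats, n_edges), dtype=bool)
    for r, edges in enumerate(true_spatial_edges):
        if edges.shape[0] < 3:
            raise ValueError("need at least 3 subjects for the t-test")
        sd = edges.std(axis=0)
        ok = sd > 0
        if not np.all(ok):
            import warnings
            warnings.warn(
                f"repeat {r}: excluding {np.sum(~ok)} zero-variance edge(s)",
                RuntimeWarning, stacklevel=2,
            )
        res = stats.ttest_1samp(edges[:, ok], 0.0, alternative="greater")
        m = np.zeros(n_edges, dtype=bool)
        m[np.where(ok)[0]] = res.pvalue * family < alpha
        mask[r] = m
    return mask, family


def tnet_snet_association(
    tnets,
    snets,
    *,
    spatial_floor: float | None = None,
) -> float:
    """Pooled correlation between temporal and spatial edges.

    ``tnets``/``snets`` are matching per-subject lists of NetMats (or raw
    square arrays).  All (edge, subject) pairs are pooled into two vectors
    and their Pearson correlation returned.  ``spatial_floor=-0.2`` gives the
    outlier-filtered variant that drops pairs whose spatial edge is below
    -0.2.
    """
    if len(tnets) != len(snets) or len(tnets) == 0:
        raise ValueError("tnets and snets must be matching non-empty lists")
    t_pool, s_pool = [], []
    for t, s in zip(tnets, snets):
        tv, sv = edge_vector(t), edge_vector(s)
        if tv.shape != sv.shape:
            raise ValueError("temporal and spatial netmats must have equal mode counts")
        t_pool.append(tv)
        s_pool.append(sv)
    t_all = np.concatenate(t_pool)
    s_all = np.concatenate(s_pool)
    if spatial_floor is not None:
        keep = s_all >= spatial_floor
        t_all, s_all = t_all[keep], s_all[keep]
    if t_all.size < 2:
        raise ValueError("not enough pooled edges to correlate")
    return float(np.corrcoef(t_all, s_all)[0, 1])
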
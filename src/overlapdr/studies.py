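"""End-to-end simulation studies.

``run_overlap_study`` drives the two-node overlap simulator through group
ICA + (thresholded) dual regression and summarises, per repeat, the bias of
estimated temporal and spatial edges against ground truth, the pooled
temporal-vs-spatial edge association, and the relative underestimation of
group-map weights in the overlap region.

``run_modes_study`` does the same for the mode-based simulator, producing
full accuracy reports (metrics i-iv) for the plain and thresholded pipelines
plus the positive-spatial-edge subset analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import GroundTruthBundle
from .decomposition import group_ica
from .dualreg import dual_regression
from .evaluation import (
    EvalReport,
    accuracy_metrics,
    match_components,
    positive_edge_subset,
    tnet_snet_association,
)
from .netmats import spatial_netmat, temporal_netmat
from .sim_modes import ModesSimConfig, simulate_modes
from .sim_overlap import OverlapSimConfig, simulate_overlap

__all__ = ["run_overlap_study", "run_modes_study", "OverlapStudyResult", "ModesStudyResult"]


def _overlap_weight_ratios(decomp_maps: np.ndarray, truth: GroundTruthBundle,
                           match) -> tuple[float, float]:
    """Mean estimated/true group-map weight over overlap vs non-overlap voxels.

    Both maps are scaled to unit norm over the node support before the
    voxelwise ratio, so only the weight *profile* matters.
    """
    supports = truth.extras["node_supports"]
    overlap = truth.extras["overlap_voxels"]
    est = match.align_maps(decomp_maps)
    ratios_overlap, ratios_non = [], []
    for m, support in enumerate(supports):
        tvals = truth.true_group_maps[m, support]
        evals_ = est[m, support]
        tvals = tvals / np.linalg.norm(tvals)
        evals_ = evals_ / np.linalg.norm(evals_)
        ratio = evals_ / tvals
        in_overlap = np.isin(support, overlap)
        ratios_overlap.append(ratio[in_overlap])
        ratios_non.append(ratio[~in_overlap])
    return (float(np.concatenate(ratios_overlap).mean()),
            float(np.concatenate(ratios_non).mean()))


@dataclass
class OverlapStudyResult:
    summary: pd.DataFrame  # one row per repeat
    reports_plain: list[EvalReport]
    reports_thresholded: list[EvalReport]


def run_overlap_study(
    config: OverlapSimConfig | None = None,
    *,
    n_repeats: int | None = None,
    seed: int | None = None,
    thresholded: bool = True,
) -> OverlapStudyResult:
    """Run the two-node overlap study over ``n_repeats`` independent repeats.

    Per repeat: simulate, group ICA (2 modes, temporal concatenation), dual
    regression per subject (stages 1-4 when ``thresholded``), netmats, and
    edge/accuracy summaries.  Repeat ``r`` uses seed ``base_seed + r``.
    """
    config = config or OverlapSimConfig()
    n_repeats = n_repeats if n_repeats is not None else config.n_repeats
    base_seed = seed if seed is not None else config.seed

    rows = []
    reports_plain: list[EvalReport] = []
    reports_thr: list[EvalReport] = []
    for rep in range(n_repeats):
        cfg = replace(config, seed=base_seed + rep)
        data, truth = simulate_overlap(cfg)
        decomp = group_ica(data, cfg.n_nodes, seed=base_seed + rep)
        match = match_components(decomp.group_maps, truth.true_group_maps)

        drs = [dual_regression(y, decomp.group_maps, thresholded=thresholded)
               for y in data]
        ts1 = [d.stage1_timeseries for d in drs]
        maps2 = [d.stage2_maps for d in drs]
        rep_plain = accuracy_metrics(ts1, maps2, truth, match)
        reports_plain.append(rep_plain)

        tnets1 = [temporal_netmat(t, s, "stage1") for s, t in enumerate(ts1)]
        snets2 = [spatial_netmat(m, s, "stage2") for s, m in enumerate(maps2)]
        pooled_r = tnet_snet_association(tnets1, snets2)

        ratio_overlap, ratio_non = _overlap_weight_ratios(
            decomp.group_maps, truth, match)

        row = {
            "repeat": rep,
            "true_temporal_edge": float(np.mean(rep_plain.true_temporal_edges)),
            "stage1_temporal_edge": float(np.mean(rep_plain.est_temporal_edges)),
            "true_spatial_edge": float(np.mean(rep_plain.true_spatial_edges)),
            "stage2_spatial_edge": float(np.mean(rep_plain.est_spatial_edges)),
            "tnet_snet_r": pooled_r,
            "overlap_weight_ratio": ratio_overlap,
            "nonoverlap_weight_ratio": ratio_non,
            "timeseries_accuracy": float(np.mean(rep_plain.timeseries_accuracy)),
            "map_accuracy": float(np.mean(rep_plain.map_accuracy)),
        }

        if thresholded:
            ts4 = [d.stage4_timeseries for d in drs]
            maps3 = [d.stage3_maps for d in drs]
            rep_thr = accuracy_metrics(ts4, maps3, truth, match)
            reports_thr.append(rep_thr)
            row.update({
                "stage4_temporal_edge": float(np.mean(rep_thr.est_temporal_edges)),
                "stage3_spatial_edge": float(np.mean(rep_thr.est_spatial_edges)),
                "timeseries_accuracy_thresholded":
                    float(np.mean(rep_thr.timeseries_accuracy)),
                "map_accuracy_thresholded": float(np.mean(rep_thr.map_accuracy)),
            })
        rows.append(row)

    return OverlapStudyResult(
        summary=pd.DataFrame(rows),
        reports_plain=reports_plain,
        reports_thresholded=reports_thr,
    )


@dataclass
class ModesStudyResult:
    summary: pd.DataFrame  # one row per repeat and pipeline
    reports_plain: list[EvalReport]
    reports_thresholded: list[EvalReport]
    positive_edge_mask: np.ndarray  # (n_repeats, n_all_edges), over all mode pairs
    bonferroni_family: int
    n_modes: int

    def _subset(self, which: str, attr: str) -> np.ndarray:
        """Pool (subject, surviving-edge) values of ``attr`` for a pipeline.

        The survival mask is indexed over all mode pairs; each report may
        carry a subset of edges (excluded modes), so report edges are mapped
        to their full-edge ids first.
        """
        reports = self.reports_plain if which == "plain" else self.reports_thresholded
        edge_id = np.full((self.n_modes, self.n_modes), -1)
        iu = np.triu_indices(self.n_modes, k=1)
        edge_id[iu] = np.arange(len(iu[0]))
        out = []
        for rep, report in enumerate(reports):
            ids = edge_id[report.edge_modes[:, 0], report.edge_modes[:, 1]]
            cols = self.positive_edge_mask[rep][ids]
            out.append(getattr(report, attr)[:, cols].ravel())
        return np.concatenate(out)

    def subset_bias(self, which: str) -> np.ndarray:
        """Temporal-edge biases (est - truth) on the positive-spatial-edge subset."""
        return self._subset(which, "temporal_bias")

    def subset_spatial_bias(self, which: str) -> np.ndarray:
        return self._subset(which, "spatial_bias")


def run_modes_study(
    config: ModesSimConfig | None = None,
    *,
    n_repeats: int | None = None,
    seed: int | None = None,
) -> ModesStudyResult:
    """Run the mode-based study over ``n_repeats`` independent repeats.

    Per repeat: simulate; group ICA over all subjects and runs (temporal
    concatenation, in the emitted dtype to bound memory); per subject, dual
    regression on the run-concatenated data (each run temporally demeaned);
    accuracy reports for the plain (stage 1/2) and thresholded (stage 4/3)
    pipelines.  Timeseries accuracy and temporal edges are measured against
    the clean HRF-convolved timecourses — the best any BOLD-level estimator
    can do.
    """
    config = config or ModesSimConfig()
    n_repeats = n_repeats if n_repeats is not None else config.n_repeats
    base_seed = seed if seed is not None else config.seed

    rows = []
    reports_plain: list[EvalReport] = []
    reports_thr: list[EvalReport] = []
    true_spatial_edges: list[np.ndarray] = []

    for rep in range(n_repeats):
        cfg = replace(config, seed=base_seed + rep)
        data, truth = simulate_modes(cfg)

        flat = [run for runs in data for run in runs]
        decomp = group_ica(flat, cfg.n_modes, seed=base_seed + rep)
        del flat

        ts1, maps2, ts4, maps3 = [], [], [], []
        for s in range(cfg.n_subjects):
            y = np.concatenate(
                [run - run.mean(axis=0, keepdims=True) for run in data[s]], axis=0
            ).astype(np.float64)
            dr = dual_regression(y, decomp.group_maps, thresholded=True)
            ts1.append(dr.stage1_timeseries)
            maps2.append(dr.stage2_maps)
            ts4.append(dr.stage4_timeseries)
            maps3.append(dr.stage3_maps)
        del data

        match = match_components(
            decomp.group_maps, truth.true_group_maps,
            est_subject_maps=maps2, true_subject_maps=truth.true_subject_maps,
        )
        bold_ts = truth.extras["bold_timecourses"]
        # edge truths against the clean BOLD-level series
        truth_bold = GroundTruthBundle(
            true_group_maps=truth.true_group_maps,
            true_subject_maps=truth.true_subject_maps,
            true_subject_timecourses=bold_ts,
            true_tnet=truth.extras["bold_tnet"],
            true_snet=truth.true_snet,
            seed=truth.seed, config=cfg, extras=truth.extras,
        )
        rep_plain = accuracy_metrics(ts1, maps2, truth_bold, match)
        rep_thr = accuracy_metrics(ts4, maps3, truth_bold, match)
        reports_plain.append(rep_plain)
        reports_thr.append(rep_thr)
        iu = np.triu_indices(cfg.n_modes, k=1)
        true_spatial_edges.append(
            np.stack([t.values[iu] for t in truth.true_snet]))

        for which, report in (("plain", rep_plain), ("thresholded", rep_thr)):
            rows.append({
                "repeat": rep,
                "pipeline": which,
                "timeseries_accuracy": float(np.mean(report.timeseries_accuracy)),
                "map_accuracy": float(np.mean(report.map_accuracy)),
                "tnet_edge_accuracy": float(np.mean(report.tnet_edge_accuracy)),
                "snet_edge_accuracy": float(np.mean(report.snet_edge_accuracy)),
                "temporal_bias": float(np.mean(report.temporal_bias)),
                "spatial_bias": float(np.mean(report.spatial_bias)),
                "n_included_modes": int(report.included_modes.sum()),
            })

    mask, family = positive_edge_subset(true_spatial_edges)
    return ModesStudyResult(
        summary=pd.DataFrame(rows),
        reports_plain=reports_plain,
        reports_thresholded=reports_thr,
        positive_edge_mask=mask,
        bonferroni_family=family,
        n_modes=config.n_modes,
    )
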
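# overlapdr

Overlap-aware group ICA and **thresholded dual regression** for node-based
resting-state fMRI functional connectivity — with fully ground-truthed
multi-subject simulators for validating both the bias and the fix.

## The problem

Functional brain networks overlap in space. Group spatial ICA forces its
component maps `M = Q'S'` to be independent (uncorrelated) across voxels, so
whatever spatial covariance truly exists between networks cannot live in the
maps — it is pushed into the component timecourses `A = TQ`. Dual regression
then inherits the distortion twice:

- **temporal edges** (Pearson correlations between stage-1 node
  timecourses, `cov(T_X, T_Y)/σσ`) are *inflated* by the true spatial
  covariance, and
- **spatial edges** (correlations between stage-2 node maps,
  `cov(S_X, S_Y)/σσ`) are weighted by `(A'A)⁻¹` — the inverse covariance of
  the inflated timecourses — and come out *negatively biased*,

which also makes temporal and spatial edges negatively correlated across
edges and subjects even when the truth carries no such coupling.

`overlapdr` implements the standard ICA + dual-regression stack, the
four-stage corrective pipeline (stage 3: Gaussian/Gamma mixture-model
thresholding of the subject maps at |z| ≥ 2 of the fitted background;
stage 4: re-regression of the data against the thresholded maps), netmat
construction, component matching and accuracy metrics, and two simulators
that generate everything the estimation stack consumes — no external data
required.

## Worked example

Run a reduced two-node overlap study (5,000 voxels, 20 subjects, two
repeats) from the shell:

```bash
printf 'n_voxels: 5000\nn_subjects: 20\n' > cfg.yaml
overlapdr overlap-study --repeats 2 --seed 1 --config cfg.yaml --out study/
```

which prints (abridged to six key columns):

```
 repeat  true_temporal_edge  stage1_temporal_edge  stage4_temporal_edge  true_spatial_edge  stage2_spatial_edge  tnet_snet_r
      0            0.406992              0.533199              0.464436           0.127801            -0.034800    -0.538543
      1            0.416167              0.515314              0.448400           0.097972            -0.029020    -0.444456
```

Read it like this: the subjects' true node timecourses are correlated at
about r = 0.41, but the plain stage-1 dual-regression estimate reports about
0.52 — the true *spatial* correlation (≈ 0.1) has leaked into the temporal
edge. The stage-2 spatial edges are pushed the other way, to roughly −0.03.
The stage-4 (thresholded) temporal edge moves most of the way back (≈ 0.45,
and closer still at the full 10,000-voxel geometry), the stage-3 spatial
edge (`stage3_spatial_edge`, ≈ 0.09) recovers the true sign and size, and
`tnet_snet_r` — the pooled correlation between temporal and spatial edges,
≈ −0.5 here — shows the diagnostic negative association the plain pipeline
induces. `summary.tsv` and a plot are written to `study/`.

The same library surface is available in Python:

```python
from overlapdr import OverlapSimConfig, simulate_overlap, group_ica, dual_regression
from overlapdr.netmats import temporal_netmat

data, truth = simulate_overlap(OverlapSimConfig(seed=1))
decomp = group_ica(data, n_modes=2, seed=1)
dr = dual_regression(data[0], decomp.group_maps, thresholded=True)
print(temporal_netmat(dr.stage4_timeseries).values[0, 1])   # de-biased edge
```

Other subcommands: `simulate-overlap`, `simulate-modes` (atlas-based
overlapping modes with warps, subject HRFs and structured + heavy-tailed
noise), `group-ica`, `dualreg [--thresholded]`, `netmats --temporal
{stage1|stage4} --spatial {stage2|stage3}`, `evaluate`, and `modes-study`
(plain vs thresholded pipeline accuracy with a positive-spatial-edge subset
analysis). Every command writes a `manifest.json` (config, seed, file
checksums); re-running with the same manifest inputs reproduces outputs
bit-identically.

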
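# Methods

This note documents the models implemented in `overlapdr`, the assumptions
behind them, the defaults of the two synthetic-data generators, and the
numerical choices that matter when reproducing or extending the results.

## The problem

Node-based resting-state fMRI analyses summarise a dataset
`Y` (timepoints × voxels) as an outer product of component timecourses `T`
and spatial maps `S`, `Y ≈ T R S'`, where `R = Q Q'` is a rotation chosen by
the decomposition. Group spatial ICA chooses `Q` so that the estimated maps
`M = Q'S'` are maximally independent across voxels; consequently
`cov(M') ≈ I`, and *all* between-component covariance — including any true
covariance between the spatial maps — is pushed into the timecourse side
`A = T Q`. Two downstream consequences follow for dual regression:

1. **Stage-1 timecourses** (`A`, obtained by spatially regressing each
   timepoint on the group maps) carry a weighted sum of the true temporal
   and true spatial covariance, so temporal network-matrix edges are
   inflated wherever the underlying networks overlap in space.
2. **Stage-2 maps** `S_DR = pinv(A) Y` contain the factor
   `(A'A)^-1` — the inverse covariance of the stage-1 timecourses — so
   spatial overlap (correlation) between subject maps is *negatively*
   weighted by exactly the inflated temporal correlations. Spatial edges
   come out biased negative, and pooled over edges and subjects the
   temporal and spatial edges are negatively correlated.

Both biases are second-order effects: the per-subject maps and timecourses
themselves remain highly correlated with the truth even when the edge
estimates are strongly shifted.

## Thresholded dual regression

The corrective pipeline has four stages per subject:

1. multiple spatial regression of the data on the group maps (timecourses);
2. multiple temporal regression of the data on the stage-1 timecourses
   (maps);
3. per map, fit a three-component mixture — Gaussian background plus
   positive and negative Gamma tails — to the voxelwise weights, shift and
   rescale by the fitted background mean and standard deviation, and zero
   every voxel with |z| < 2 (the boundary |z| = 2 survives);
4. multiple spatial regression of the data on the thresholded maps.

Stage-4 timecourses are the ones to use for temporal network matrices;
stage-3 maps for spatial overlap matrices. Un-thresholded stage-2 maps
remain the right object for voxelwise inference on map shape/amplitude.
Suprathreshold voxels keep their signed z-value rather than the raw weight:
any per-map affine rescaling cancels in the stage-4 regression up to column
scaling and leaves all correlations unchanged.

### The Gaussian/Gamma mixture (GGM)

The mixture density is
`π₀ N(x; μ, σ²) + π₊ Γ(x − δ; k₊, θ₊) + π₋ Γ(δ − x; k₋, θ₋)`,
with both Gamma offsets fixed at `δ`, the robustly initialised background
mean. Fitting is by EM with exact M-steps:

- **Initialisation.** Background moments from the interquartile core of the
  sample, with the truncated-normal correction (the middle 50% of a
  Gaussian has SD 0.3776σ); Gamma moments from the excursions beyond one
  (corrected) SD; mixing (0.9, 0.05, 0.05).
- **M-step.** Gaussian parameters by weighted moments; Gamma shape by
  responsibility-weighted maximum likelihood (Newton on
  `log k − ψ(k) = log m̄ − l̄`). Each Gamma's mean is constrained to at
  least one initial SD from the offset; because the offsets and the
  constraint are fixed up front, every M-step maximises over a fixed
  feasible set and the log-likelihood path is non-decreasing (asserted in
  the tests).
- **Tail dropping.** A tail is removed, and the remaining components refit,
  if its mixing proportion falls below 1e-3, its responsibility-weighted
  voxel count below 10, or its fitted mean lies within 2.5 fitted SDs of
  the background mean. The last rule is the important one: on a map whose
  weights are actually pure Gaussian, unconstrained EM lets the Gammas
  absorb the Gaussian's own tails (shrinking σ̂ by ~8%); a "tail" that
  close to the background is background. Real signal tails in both
  simulators sit at 4–10σ and are unaffected. Note the stage-3 threshold
  uses only μ and σ, so dropping a tail never changes which voxels survive
  except through the refit background.
- **Degenerate inputs.** Maps with fewer than 100 finite values or zero
  spread are rejected. σ is floored at 1e-9 of the data range so that
  refitting an already-thresholded map (background exactly zero) does not
  collapse; this is what makes thresholding idempotent in practice.
- Convergence: relative log-likelihood change below 1e-5, at most 300
  iterations; non-converged fits are used with a warning (the background
  moments stabilise long before the slowly-drifting tail shapes).

## Group spatial ICA

Temporal-concatenation group ICA: per-subject temporal demeaning per voxel,
concatenation along time, PCA to exactly the requested mode count (no
automatic dimensionality estimation), and a FastICA rotation (logcosh
contrast, tol 1e-6) of the whitened spatial basis, so that independence is
enforced across voxels. Restarts (up to 10, fresh random initial rotations)
are consumed only on non-convergence. Component sign is fixed by positive
skewness of the map; components are ordered by explained variance.

The PCA uses an in-package randomized range finder that works entirely in
the input dtype: the concatenated stack is held once (float32 for the
mode-based simulator) and only the small projected problem is solved in
double precision. With 1 CPU and a few GB of memory this keeps the largest
study (36,000 × 10,000 concatenated matrix) comfortably inside budget.

## Simulator 1: two overlapping nodes

The minimal configuration exposing the bias. Defaults (all configurable):
10,000 voxels, 50 subjects, 200 timepoints, 10 repeats; two nodes of 100
voxels each sharing 25% of their support; node weights uniform on [2, 12]
added onto a Laplacian(0, 0.5) background; per-subject map noise Gaussian
with σ = 0.1 × mean node weight; per-node timecourses are unit Gaussians
mixed with a shared Gaussian series with weight √(2/3), restandardised, so
the population true temporal correlation is w²/(1+w²) = 0.4. The group map
(background + weights) is drawn once per repeat; subject maps add noise to
it — there is deliberately no misalignment here. Data are the exact outer
product of the stored timecourses and (noisy) subject maps, so the bundle
reproduces the data bit-identically.

Node supports are contiguous index ranges placed uniformly at random; voxel
geometry is irrelevant to every downstream computation, so a 1-D voxel line
is used throughout. Background noise is additive everywhere, including
inside node supports.

## Simulator 2: atlas-based overlapping modes

Emulates a multi-subject, multi-run rfMRI study with misalignment,
subject-varying HRFs, saturation, and structured + heavy-tailed noise.
Defaults: 10,000 voxels, 30 subjects, 2 runs × 600 timepoints, 100
contiguous atlas parcels (Dirichlet(5) widths, largest-remainder integer
rounding; Gamma(3, 1/3) parcel weights), 15 modes.

- **Modes.** Each mode is a weighted sum of parcels grouped into 1 +
  Poisson(1.5) contiguous regions; the total parcel budget is
  Beta(2,4) × 12; budgets split over regions by a Dirichlet(2); each
  non-dominant region is negated with probability 0.2; parcel weights are
  Gamma(3, 1/3). A mode is redrawn if its group-map correlation with an
  already-drawn mode exceeds 0.5: overlap should be present but weak —
  without the cap, occasional near-duplicate modes (spatial r ≈ 0.8) are
  unidentifiable by *any* decomposition, which is not the regime under
  study. Subjects share parcel identities but jitter the weights
  (log-normal, σ = 0.25), then resample through their warp.
- **Warps.** The warp gradient is boxcar-smoothed (width 500 voxels)
  Gaussian noise squashed through tanh into [−1, 1], so the voxel mapping
  is monotone and invertible; the integrated displacement is rescaled to a
  maximum of one average parcel size (amplitude parameter 1; 0 gives the
  identity). This is the dominant limiter of estimation accuracy at the
  defaults, which is why the evaluation applies the r ≥ 0.5 group-average
  inclusion rule before edge-level metrics.
- **Timecourses.** Random-phase spectra with envelope 1/√(1+(f/0.1 Hz)⁴)
  (TR 1 s), no DC; inter-mode correlations from a Wishart hierarchy —
  group W(I/50, 50), subject centred on the group draw (dof 100), run
  centred on the subject draw (dof 150), normalised to correlation;
  sparsification zeroes timepoints below 0.3 SD (signed), leaving sparse
  bursts of activity. The correlation of the emitted sparse series is
  recorded as the neural ground truth.
- **HRFs.** One kernel per subject: a random combination (coefficients
  Gaussian around [1, 0.2, 0.1]) of a canonical double-gamma response and
  its temporal and dispersion derivatives, normalised to unit peak —
  subject-varying HRF shape with the same role as draws from an empirical
  HRF basis. Timeseries accuracy and temporal-edge truth are measured
  against the HRF-convolved clean series (what a BOLD-level estimator can
  at best recover); the pre-HRF netmats are also stored.
- **Data.** signal = c·tanh(x/c) applied to the outer product with
  c = RMS/0.2 (a weak saturation; strength 0 gives the identity); plus a
  rank-10 Gaussian structured-noise subspace at 10% of signal variance and
  i.i.d. Student-t(10) unstructured noise at 30% ("weakly non-Gaussian" —
  heavier tails actively mislead a non-Gaussianity-seeking spatial ICA,
  which is a property of ICA, not of the bias under study). The Student-t
  field is regenerable bit-identically from a recorded seed, so the
  ground-truth bundle reconstructs the emitted data exactly without
  storing a second copy of it.

### What the generators do and do not emulate

They reproduce the features that drive the estimation problem: overlapping
soft modes, subject variability in weights and (for simulator 2) position,
correlated sparse dynamics, HRF variation, saturation, structured and
heavy-tailed noise. They do not emulate 2-D/3-D geometry, spatial
autocorrelation of the noise, physiological confound spectra, or
multi-session drift. Passing tests therefore demonstrate the *mechanism*
of the overlap bias and its correction under controlled conditions, not
performance guarantees on any particular real dataset.

## Evaluation

Estimated components are matched to truth by the Hungarian algorithm on the
absolute spatial-correlation matrix, with the matched sign applied; truth
modes whose group-average matched subject-map correlation falls below 0.5
are excluded along with their incident edges. Metrics: (i) per-subject
timeseries correlation, (ii) per-subject map correlation, (iii) per-edge
cross-subject correlation of temporal edges, (iv) the same for spatial
edges — (iii)/(iv) on Fisher-z-transformed edges by default — plus raw
bias distributions (estimated − truth). The positive-spatial-edge subset
is found by a one-tailed t-test of true spatial edges > 0 across subjects,
Bonferroni-corrected over the full family of edges × repeats (105 × 10 =
1050 at the default geometry).

## Study sizes used by the test suite and acceptance script

The bundled studies run the full default conditions for the two-node
simulator (10 repeats) and 2–3 repeats of the mode-based simulator (its
per-repeat cost is dominated by one 36,000 × 10,000 decomposition); these
sizes give stable signs and orderings for every reported contrast while
keeping a complete run on a single CPU in the tens of minutes. All sizes
are configuration fields and scale up trivially.

## Known limitations

- The 1-D voxel line cannot express geometric phenomena such as
  interdigitated networks or boundary shifts that differ by direction.
- The GGM assumes the background dominates (≳ 2/3 of voxels); inside a
  small region of interest with mostly "active" voxels the mixture model,
  and hence stage 3, is not valid.
- Wishart-hierarchy correlations are exchangeable across mode pairs; there
  is no community structure in the true temporal netmats.
- FastICA at PCA dimension = mode count can lose the weakest mode under
  realistic noise; the inclusion rule handles this but reduces the edge
  count entering metrics (iii)/(iv).
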
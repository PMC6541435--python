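"""Mode-based simulator: atlas, warps, node maps, timecourses, noise model."""

import dataclasses

import numpy as np
import pytest

from overlapdr import (
    ModesSimConfig,
    assemble_data,
    generate_atlas,
    generate_node_maps,
    generate_timecourses,
    generate_warps,
    hrf_convolve,
    simulate_modes,
)
from overlapdr.sim_modes import make_hrf, reconstruct_unstructured_noise

SMALL = dict(n_voxels=2000, n_subjects=4, n_runs=2, n_timepoints=150,
             n_parcels=40, n_modes=6)


@pytest.fixture(scope="module")
def small_sim():
    cfg = ModesSimConfig(seed=5, **SMALL)
    data, truth = simulate_modes(cfg)
    return cfg, data, truth


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_parcels": 200, "n_voxels": 100},
            {"n_modes": 50, "n_parcels": 20},
            {"wishart_dof_group": 5, "n_modes": 15},
            {"nonlinearity_strength": -1.0},
            {"warp_amplitude": -0.5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModesSimConfig(**kwargs)


class TestAtlas:
    def test_widths_tile_voxels(self, rng):
        cfg = ModesSimConfig(seed=0, **SMALL)
        atlas = generate_atlas(cfg, rng)
        assert atlas.widths.sum() == cfg.n_voxels
        assert np.all(atlas.widths >= 1)
        assert np.all(atlas.weights > 0)
        assert len(atlas.parcel_of_voxel()) == cfg.n_voxels

    def test_high_concentration_gives_equal_widths(self, rng):
        cfg = ModesSimConfig(seed=0, parcel_width_concentration=1e9, **SMALL)
        atlas = generate_atlas(cfg, rng)
        assert np.all(atlas.widths == cfg.n_voxels // cfg.n_parcels)

    def test_deterministic_under_seed(self):
        cfg = ModesSimConfig(seed=0, **SMALL)
        a1 = generate_atlas(cfg, np.random.default_rng(3))
        a2 = generate_atlas(cfg, np.random.default_rng(3))
        np.testing.assert_array_equal(a1.boundaries, a2.boundaries)
        np.testing.assert_array_equal(a1.weights, a2.weights)


class TestWarps:
    def test_zero_amplitude_is_identity(self, rng):
        cfg = ModesSimConfig(seed=0, warp_amplitude=0.0, **SMALL)
        atlas = generate_atlas(cfg, rng)
        warps = generate_warps(cfg, rng, atlas)
        v = np.arange(cfg.n_voxels, dtype=float)
        for w in warps:
            assert w.is_identity
            np.testing.assert_array_equal(w.apply(v), v)

    def test_displacement_bounded_by_average_parcel_size(self, rng):
        cfg = ModesSimConfig(seed=0, **SMALL)
        atlas = generate_atlas(cfg, rng)
        for w in generate_warps(cfg, rng, atlas):
            assert np.abs(w.displacement).max() <= atlas.average_parcel_size + 1e-9

    def test_warp_is_monotone_hence_invertible(self, rng):
        cfg = ModesSimConfig(seed=0, **SMALL)
        atlas = generate_atlas(cfg, rng)
        for w in generate_warps(cfg, rng, atlas):
            coords = np.arange(cfg.n_voxels) + w.displacement
            assert np.all(np.diff(coords) >= 0)


class TestNodeMaps:
    def test_no_negative_regions_gives_nonnegative_maps(self, rng):
        cfg = ModesSimConfig(seed=0, negative_region_prob=0.0, **SMALL)
        atlas = generate_atlas(cfg, rng)
        group, _, _ = generate_node_maps(cfg, rng, atlas)
        assert np.all(group >= 0)

    def test_zero_jitter_identity_warp_reproduces_group_map(self, rng):
        cfg = ModesSimConfig(seed=0, subject_weight_jitter=0.0,
                             warp_amplitude=0.0, **SMALL)
        atlas = generate_atlas(cfg, rng)
        warps = generate_warps(cfg, rng, atlas)
        group, subject, _ = generate_node_maps(cfg, rng, atlas, warps)
        for m in subject:
            np.testing.assert_array_equal(m, group)

    def test_modes_share_parcels_creating_spatial_overlap(self, small_sim):
        """At the default overlap settings at least one pair of modes shares
        a parcel, giving nonzero true spatial correlation (oracle: the stored
        mode -> parcel assignments)."""
        _, _, truth = small_sim
        pw = truth.extras["parcel_weights"]
        support = pw != 0
        shared = (support.astype(int) @ support.T.astype(int))
        np.fill_diagonal(shared, 0)
        assert shared.max() >= 1
        i, j = np.unravel_index(np.argmax(shared), shared.shape)
        assert abs(truth.true_snet[0].values[i, j]) > 0


class TestTimecourses:
    def test_sparsification_boundaries(self, rng):
        cfg = ModesSimConfig(seed=0, sparsify_threshold=-np.inf, **SMALL)
        series, _ = generate_timecourses(cfg, np.random.default_rng(1))
        assert not np.any(series[(0, 0)] == 0)
        cfg_hi = ModesSimConfig(seed=0, sparsify_threshold=np.inf, **SMALL)
        with pytest.raises(ValueError, match="sparsification"):
            generate_timecourses(cfg_hi, np.random.default_rng(1))

    def test_large_wishart_dof_shrinks_correlations(self):
        small = dict(SMALL, n_subjects=2, n_runs=1)
        cfg = ModesSimConfig(seed=0, wishart_dof_group=200_000,
                             wishart_dof_subject=200_000, wishart_dof_run=200_000,
                             sparsify_threshold=-np.inf, n_timepoints=3000,
                             **{k: v for k, v in small.items() if k != "n_timepoints"})
        series, _ = generate_timecourses(cfg, np.random.default_rng(2))
        c = np.corrcoef(series[(0, 0)], rowvar=False)
        off = c[np.triu_indices_from(c, k=1)]
        assert np.abs(off).max() < 0.1

    def test_bundle_tnet_matches_emitted_series(self, small_sim):
        cfg, _, truth = small_sim
        for s in range(cfg.n_subjects):
            emitted = np.concatenate(
                [truth.extras["neural_by_run"][(s, r)] for r in range(cfg.n_runs)],
                axis=0)
            np.testing.assert_allclose(
                truth.true_tnet[s].values,
                np.corrcoef(emitted, rowvar=False), atol=1e-12)


class TestHRF:
    def test_unit_impulse_is_identity(self, rng):
        x = rng.standard_normal((50, 3))
        np.testing.assert_allclose(hrf_convolve(x, np.array([1.0])), x)

    def test_matches_brute_force_convolution(self, rng):
        x = rng.standard_normal((20, 2))
        k = rng.standard_normal(5)
        out = hrf_convolve(x, k)
        brute = np.zeros_like(x)
        for t in range(20):
            for tau in range(5):
                if t - tau >= 0:
                    brute[t] += k[tau] * x[t - tau]
        np.testing.assert_allclose(out, brute, atol=1e-10)

    def test_distinct_kernels_decorrelate_output(self):
        cfg = ModesSimConfig(seed=0, **SMALL)
        rng = np.random.default_rng(4)
        k1, k2 = make_hrf(cfg, rng), make_hrf(cfg, rng)
        assert not np.allclose(k1, k2)
        x = np.random.default_rng(5).standard_normal((150, 1))
        y1, y2 = hrf_convolve(x, k1).ravel(), hrf_convolve(x, k2).ravel()
        assert np.corrcoef(y1, y2)[0, 1] < 1.0 - 1e-6

    def test_nonfinite_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            hrf_convolve(rng.standard_normal((30, 2)), np.array([1.0, np.nan]))


class TestAssembly:
    def test_zero_nonlinearity_zero_noise_is_exact_outer_product(self, rng):
        cfg = ModesSimConfig(seed=0, nonlinearity_strength=0.0,
                             structured_noise_var_frac=0.0,
                             unstructured_var_frac=0.0, emit_dtype="float64",
                             **SMALL)
        ts = rng.standard_normal((100, cfg.n_modes))
        maps = rng.standard_normal((cfg.n_modes, cfg.n_voxels))
        data, _ = assemble_data(ts, maps, cfg, rng)
        np.testing.assert_array_equal(data, ts @ maps)

    def test_noise_variance_fraction_matches_configuration(self, rng):
        """Recorded components partition the variance as configured (5%)."""
        cfg = ModesSimConfig(seed=0, nonlinearity_strength=0.0,
                             structured_noise_var_frac=0.3,
                             unstructured_var_frac=1.0, emit_dtype="float64",
                             **dict(SMALL, n_timepoints=600))
        ts = rng.standard_normal((600, cfg.n_modes))
        maps = rng.standard_normal((cfg.n_modes, cfg.n_voxels))
        data, rec = assemble_data(ts, maps, cfg, rng)
        noise = data - ts @ maps
        ratio = noise.var() / rec["signal_var"]
        assert ratio == pytest.approx(1.3, rel=0.05)

    def test_full_reconstruction_from_recorded_components(self, small_sim):
        """saturate(T @ M) + structured + regenerated unstructured noise
        reproduces the emitted data bit-identically."""
        cfg, data, truth = small_sim
        s, r = 1, 0
        rec = truth.extras["noise_records"][(s, r)]
        bold = truth.extras["bold_by_run"][(s, r)]
        signal = bold @ truth.true_subject_maps[s]
        c = np.sqrt(np.mean(signal**2)) / cfg.nonlinearity_strength
        recon = c * np.tanh(signal / c)
        recon = recon + rec["structured_ts"] @ rec["structured_maps"] * rec["structured_scale"]
        recon = recon + reconstruct_unstructured_noise(cfg, rec, signal.shape)
        np.testing.assert_array_equal(recon.astype(cfg.emit_dtype), data[s][r])


def test_simulate_modes_deterministic():
    cfg = ModesSimConfig(seed=9, **dict(SMALL, n_subjects=2))
    d1, t1 = simulate_modes(cfg)
    d2, t2 = simulate_modes(dataclasses.replace(cfg))
    np.testing.assert_array_equal(d1[1][1], d2[1][1])
    np.testing.assert_array_equal(t1.true_group_maps, t2.true_group_maps)


def test_no_warp_no_jitter_removes_between_subject_spatial_variance():
    cfg = ModesSimConfig(seed=2, warp_amplitude=0.0, subject_weight_jitter=0.0,
                         **SMALL)
    _, truth = simulate_modes(cfg)
    edges = np.stack([t.values[np.triu_indices(cfg.n_modes, 1)]
                      for t in truth.true_snet])
    assert edges.std(axis=0).max() == 0
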
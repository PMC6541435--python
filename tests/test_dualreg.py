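"""Dual regression stages 1-4 and the Gaussian/Gamma mixture model."""

import numpy as np
import pytest

from overlapdr import fit_ggm, stage1, stage2, stage3_threshold, stage4
from overlapdr.dualreg import MixtureFit, dual_regression


def _demean_rows(m):
    return m - m.mean(axis=1, keepdims=True)


class TestStage1:
    def test_orthonormal_maps_recover_timecourses_exactly(self, rng):
        g = np.linalg.qr(rng.standard_normal((500, 3)))[0].T  # orthonormal rows
        g = _demean_rows(g)
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        a = rng.standard_normal((40, 3))
        y = a @ g
        np.testing.assert_allclose(stage1(y, g), a, atol=1e-9)

    def test_matches_explicit_normal_equations(self):
        """3-voxel, 2-map toy solved by hand-written normal equations."""
        g = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        y = np.array([[2.0, 3.0, 5.0]])
        gd = _demean_rows(g)
        yd = y - y.mean()
        expected = np.linalg.solve(gd @ gd.T, gd @ yd.T).T
        np.testing.assert_allclose(stage1(y, g), expected, atol=1e-12)

    def test_collinear_maps_rejected_naming_pair(self, rng):
        base = rng.standard_normal(200)
        g = np.vstack([base, 2.0 * base, rng.standard_normal(200)])
        y = rng.standard_normal((10, 200))
        with pytest.raises(np.linalg.LinAlgError, match=r"\(0, 1\)"):
            stage1(y, g)

    def test_voxel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            stage1(rng.standard_normal((10, 30)), rng.standard_normal((2, 40)))


class TestStage2:
    def test_orthonormal_timeseries_recover_maps_exactly(self, rng):
        a = np.linalg.qr(rng.standard_normal((100, 3)))[0]
        a = a - a.mean(axis=0)
        m = rng.standard_normal((3, 200))
        y = a @ m
        out = stage2(y, a, normalize=False)
        # y is regenerated from zero-mean a, so demeaning is a no-op
        np.testing.assert_allclose(out, m - m.mean(axis=0) * 0, atol=1e-9)

    def test_matches_per_voxel_least_squares(self, rng):
        """Equals an independent voxel-by-voxel normal-equation solve."""
        ts = rng.standard_normal((60, 3))
        y = rng.standard_normal((60, 50))
        out = stage2(y, ts)
        a = ts - ts.mean(axis=0)
        a = a / a.std(axis=0)
        yd = y - y.mean(axis=0)
        brute = np.empty((3, 50))
        for v in range(50):
            brute[:, v] = np.linalg.lstsq(a, yd[:, v], rcond=None)[0]
        np.testing.assert_allclose(out, brute, atol=1e-8)

    def test_map_operator_left_factor_is_inverse_covariance(self, rng):
        """With zero-mean unit-variance timeseries the stage-2 operator is
        inv(cov(ts)) @ ts' — so spatial maps are weighted by the inverse
        (negative partial) correlation structure of the timeseries."""
        ts = rng.standard_normal((2000, 3)) @ np.linalg.cholesky(
            np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])).T
        y = rng.standard_normal((2000, 40))
        a = ts - ts.mean(axis=0)
        a = a / a.std(axis=0)
        expected = np.linalg.inv(a.T @ a / len(a)) @ (a.T @ (y - y.mean(axis=0))) / len(a)
        np.testing.assert_allclose(stage2(y, ts), expected, atol=1e-10)

    def test_rank_deficient_timeseries_rejected(self, rng):
        t = rng.standard_normal((50, 1))
        ts = np.hstack([t, t, rng.standard_normal((50, 1))])
        with pytest.raises(np.linalg.LinAlgError):
            stage2(rng.standard_normal((50, 30)), ts)


class TestMixtureModel:
    def test_pure_gaussian_recovers_moments_and_drops_tails(self):
        rng = np.random.default_rng(100)
        x = rng.normal(5.0, 2.0, 100_000)
        fit = fit_ggm(x)
        assert 4.95 < fit.mu < 5.05
        assert 1.95 < fit.sigma < 2.05
        assert fit.mixing[1] < 0.02 and fit.mixing[2] < 0.02

    def test_known_mixture_parameter_recovery(self):
        """80% N(0,1) + 15% Gamma(3,2) + 5% -Gamma(3,2), n = 100k."""
        rng = np.random.default_rng(0)
        n = 100_000
        lab = rng.choice(3, size=n, p=[0.8, 0.15, 0.05])
        x = np.where(lab == 0, rng.normal(0, 1, n),
                     np.where(lab == 1, rng.gamma(3, 2, n), -rng.gamma(3, 2, n)))
        fit = fit_ggm(x)
        assert abs(fit.mu) < 0.05
        assert abs(fit.sigma - 1.0) < 0.05
        np.testing.assert_allclose(fit.mixing, [0.8, 0.15, 0.05], atol=0.03)
        assert fit.pos_shape == pytest.approx(3.0, abs=0.4)
        assert fit.pos_scale == pytest.approx(2.0, abs=0.3)

    def test_em_loglikelihood_is_monotone(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 20_000), rng.gamma(4, 1.5, 2_000)])
        fit = fit_ggm(x)
        deltas = np.diff(fit.loglik_path)
        assert np.all(deltas >= -1e-7 * np.abs(fit.loglik_path[:-1]))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_ggm(np.ones(5000))
        with pytest.raises(ValueError):
            fit_ggm(np.arange(50, dtype=float))  # too few values


class TestStage3:
    def _flat_fit(self, mu=0.0, sigma=1.0):
        return MixtureFit(mu=mu, sigma=sigma, pos_shape=2, pos_scale=1,
                          pos_offset=mu, neg_shape=2, neg_scale=1, neg_offset=mu,
                          mixing=np.array([1.0, 0.0, 0.0]),
                          log_likelihood=0.0, loglik_path=np.zeros(1),
                          n_iter=1, converged=True, components_dropped=True)

    def test_all_subthreshold_map_zeroed_and_flagged(self):
        maps = np.array([[0.5, -1.0, 1.5, 0.0]])
        out, flags = stage3_threshold(maps, [self._flat_fit()])
        np.testing.assert_array_equal(out, 0.0)
        assert flags[0]

    def test_boundary_z_equal_2_survives(self):
        maps = np.array([[2.0, 1.999999, -2.0, 0.1]])
        out, _ = stage3_threshold(maps, [self._flat_fit()])
        np.testing.assert_allclose(out[0], [2.0, 0.0, -2.0, 0.0])

    def test_planted_signal_voxels_exactly_survive(self):
        """9950 background voxels ~ N(0.5, 2) plus 50 voxels at weight 20:
        exactly the planted voxels survive (their background z is 9.75)."""
        rng = np.random.default_rng(12)
        bg = rng.normal(0.5, 2.0, 9950)
        assert np.abs((bg - 0.5) / 2.0).max() < 2 * 2.4  # sanity on the draw
        m = np.concatenate([bg, np.full(50, 20.0)])
        fit = fit_ggm(m)
        out, _ = stage3_threshold(m[None, :], [fit])
        survived = np.nonzero(out[0])[0]
        # allow for the occasional |z|>=2 background voxel under the fit
        assert set(range(9950, 10_000)) <= set(survived)
        extra = [v for v in survived if v < 9950]
        assert len(extra) <= np.sum(np.abs((bg - fit.mu) / fit.sigma) >= 2)

    def test_zero_sigma_rejected(self):
        fit = self._flat_fit(sigma=0.0)
        with pytest.raises(ValueError):
            stage3_threshold(np.ones((1, 4)), [fit])

    def test_thresholding_is_idempotent_on_separated_maps(self):
        rng = np.random.default_rng(5)
        m = np.concatenate([rng.normal(0, 1, 9000), rng.normal(8, 1, 1000)])
        fit1 = fit_ggm(m)
        out1, _ = stage3_threshold(m[None, :], [fit1])
        fit2 = fit_ggm(out1[0])
        out2, _ = stage3_threshold(out1, [fit2])
        changed = np.mean((out1[0] != 0) != (out2[0] != 0))
        assert changed < 0.01


class TestStage4:
    def test_all_zero_map_rejected(self, rng):
        maps = np.vstack([rng.standard_normal(100), np.zeros(100)])
        with pytest.raises(ValueError, match="modes \\[1\\]"):
            stage4(rng.standard_normal((10, 100)), maps)

    def test_true_maps_recover_true_timecourses(self, rng):
        """Thresholded maps equal to (z-scored) true maps on noiseless data:
        stage-4 timeseries match truth at |r| > 0.999."""
        maps = np.zeros((2, 400))
        maps[0, :50] = rng.uniform(2, 8, 50)
        maps[1, 350:] = rng.uniform(2, 8, 50)
        ts = rng.standard_normal((80, 2))
        y = ts @ maps
        zmaps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
        out = stage4(y, zmaps)
        for m in range(2):
            r = np.corrcoef(out[:, m], ts[:, m])[0, 1]
            assert abs(r) > 0.999

    def test_unthresholded_maps_reproduce_stage1_subspace(self, rng):
        """Stage 4 on raw stage-2 maps spans the same timecourse subspace as
        stage 1 (canonical correlations ~ 1)."""
        from scipy.linalg import subspace_angles
        maps = rng.standard_normal((3, 300)) + 2
        ts = rng.standard_normal((100, 3))
        y = ts @ maps + 0.1 * rng.standard_normal((100, 300))
        a1 = stage1(y, maps)
        m2 = stage2(y, a1)
        a4 = stage4(y, m2)
        angles = subspace_angles(a1 - a1.mean(axis=0), a4 - a4.mean(axis=0))
        assert np.cos(angles).min() > 1 - 1e-8


def test_dual_regression_orchestrator_runs_all_stages(rng):
    maps = np.zeros((2, 2000))
    maps[0, :200] = rng.uniform(2, 8, 200)
    maps[1, 1800:] = rng.uniform(2, 8, 200)
    ts = rng.standard_normal((150, 2))
    y = ts @ maps + 0.5 * rng.standard_normal((150, 2000))
    res = dual_regression(y, maps, thresholded=True)
    assert res.stage1_timeseries.shape == (150, 2)
    assert res.stage2_maps.shape == (2, 2000)
    assert res.stage3_maps is not None and res.stage4_timeseries is not None
    assert len(res.mixture_fits) == 2
    # stage-3 maps are stage-2 maps with a subset of entries exactly zeroed
    nz = res.stage3_maps != 0
    assert 0 < nz.sum() < nz.size
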
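"""Order selection, PCA reduction, Infomax/ICASSO, and dual regression."""

import numpy as np
import pytest
import scipy.linalg as sla
from scipy.linalg import subspace_angles

from gicafc import ica


def _whiten(x):
    xc = x - x.mean(axis=1, keepdims=True)
    return np.linalg.inv(sla.sqrtm(np.cov(xc))) @ xc


def _laplacian_mixture(rng, c=3, n=2000):
    src = rng.laplace(size=(c, n))
    mix = rng.standard_normal((c, c))
    return src, _whiten(mix @ src)


class TestMDL:
    def test_recovers_planted_order(self, rng):
        # 5 strong sources in white noise, voxel-rich regime
        t_len, v, k = 200, 8000, 5
        s = rng.laplace(size=(k, v))
        a = rng.standard_normal((t_len, k))
        x = a @ s
        x = x / x.std() * 5 + rng.standard_normal((t_len, v))
        run = ica.BOLDRun(data=x, tr=2.0, subject="s")
        assert ica.estimate_order_mdl([run]) == 5

    def test_white_noise_gives_order_at_most_one(self, rng):
        run = ica.BOLDRun(data=rng.standard_normal((126, 8000)), tr=2.0, subject="n")
        assert ica.estimate_order_mdl([run]) <= 1

    def test_exact_low_rank_returns_rank(self, rng):
        x = rng.standard_normal((50, 3)) @ rng.standard_normal((3, 400))
        assert ica.estimate_order_mdl([ica.BOLDRun(data=x, tr=2.0, subject="r")]) == 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ica.estimate_order_mdl([])


class TestTwoStepPCA:
    def test_noiseless_cohort_retains_all_variance(self, noiseless_cohort):
        red = ica.two_step_pca(noiseless_cohort.runs, noiseless_cohort.config.n_components)
        assert ica.retained_variance(noiseless_cohort.runs, red) == pytest.approx(1.0, abs=1e-8)

    def test_single_subject_degenerate_two_step_matches_direct_pca(self, rng):
        x = rng.standard_normal((40, 300))
        run = ica.BOLDRun(data=x, tr=2.0, subject="s")
        red = ica.two_step_pca([run], order=5, subject_order=5)
        xc = x - x.mean(axis=0)
        xc = xc - xc.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        angles = subspace_angles(red.reduced.T, vt[:5].T)
        assert np.max(angles) < 1e-8

    def test_group_subspace_contains_truth_maps(self, default_cohort):
        red = ica.two_step_pca(default_cohort.runs, 6)
        # project truth maps onto the reduced row space; the non-degraded
        # components must be captured almost exactly
        a, *_ = np.linalg.lstsq(red.reduced.T, default_cohort.truth.spatial_maps.T,
                                rcond=None)
        proj = (red.reduced.T @ a).T
        for i in range(6):
            r = np.corrcoef(proj[i], default_cohort.truth.spatial_maps[i])[0, 1]
            assert abs(r) > 0.9

    def test_order_exceeding_retention_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            ica.two_step_pca(default_cohort.runs, order=10, subject_order=6)

    def test_whitened_output_has_unit_covariance(self, default_cohort):
        red = ica.two_step_pca(default_cohort.runs, 6)
        cov = red.reduced @ red.reduced.T / red.reduced.shape[1]
        np.testing.assert_allclose(cov, np.eye(6), atol=1e-8)


class TestInfomax:
    def test_recovers_laplacian_sources(self, rng):
        src, xw = _laplacian_mixture(rng)
        maps, _, converged = ica.infomax_ica(xw, seed=5)
        assert converged
        _, corr = ica.match_components(maps.maps, src)
        assert np.all(corr >= 0.99)

    def test_deterministic_under_seed(self, rng):
        _, xw = _laplacian_mixture(rng)
        m1, _, _ = ica.infomax_ica(xw, seed=11)
        m2, _, _ = ica.infomax_ica(xw, seed=11)
        np.testing.assert_array_equal(m1.maps, m2.maps)

    def test_maps_have_positive_skew(self, rng):
        from scipy.stats import skew
        _, xw = _laplacian_mixture(rng)
        maps, _, _ = ica.infomax_ica(xw, seed=2)
        assert np.all(skew(maps.maps, axis=1) >= 0)


class TestIcasso:
    def test_stable_recovery_of_supergaussian_sources(self, rng):
        src, xw = _laplacian_mixture(rng)
        res = ica.icasso(xw, 3, n_runs=10, seed=0)
        assert np.all(res.stability >= 0.9)
        _, corr = ica.match_components(res.maps.maps, src)
        assert np.all(corr >= 0.99)

    def test_single_run_is_degenerate(self, rng):
        _, xw = _laplacian_mixture(rng)
        res = ica.icasso(xw, 3, n_runs=1, seed=0)
        assert np.all(res.stability == 1.0)
        assert res.maps.order == 3

    def test_gaussian_sources_less_stable_than_structured(self, rng):
        # rotation of Gaussian sources is unidentifiable, so restarts
        # disagree and the cluster-quality index drops
        _, xw = _laplacian_mixture(rng)
        g = _whiten(rng.standard_normal((3, 2000)))
        stable = ica.icasso(xw, 3, n_runs=8, seed=1).stability.mean()
        unstable = ica.icasso(g, 3, n_runs=8, seed=1).stability.mean()
        assert unstable < stable


class TestDualRegression:
    def test_noiseless_identity(self, noiseless_cohort):
        truth = noiseless_cohort.truth
        y = ica.GroupSpatialMaps(maps=truth.spatial_maps)
        run = noiseless_cohort.runs[0]
        dec = ica.dual_regression(run, y)
        np.testing.assert_allclose(dec.temporal, truth.mixing_timecourses[run.subject],
                                   atol=1e-9)
        np.testing.assert_allclose(dec.spatial, truth.spatial_maps, atol=1e-9)
        rec = dec.temporal @ dec.spatial
        rel = np.linalg.norm(run.data - rec) / np.linalg.norm(run.data)
        assert rel < 1e-10

    def test_orthonormal_maps_reduce_to_projection(self, rng):
        y = np.linalg.qr(rng.standard_normal((500, 4)))[0].T  # orthonormal rows
        x = rng.standard_normal((30, 500))
        run = ica.BOLDRun(data=x, tr=2.0, subject="s")
        dec = ica.dual_regression(run, ica.GroupSpatialMaps(maps=y), intercept=False)
        np.testing.assert_allclose(dec.temporal, x @ y.T, atol=1e-10)

    def test_noisy_cohort_subject_maps_recover_truth(self, default_cohort):
        y = ica.GroupSpatialMaps(maps=default_cohort.truth.spatial_maps)
        run = default_cohort.runs[0]
        dec = ica.dual_regression(run, y)
        _, corr = ica.match_components(dec.spatial, default_cohort.truth.spatial_maps)
        assert np.all(corr >= 0.9)

    def test_rank_deficient_maps_rejected(self, rng):
        y = np.ones((3, 100))
        x = rng.standard_normal((20, 100))
        with pytest.raises(ValueError, match="rank deficient"):
            ica.dual_regression(ica.BOLDRun(data=x, tr=2.0, subject="s"),
                                ica.GroupSpatialMaps(maps=y))

    def test_scale_indeterminacy_of_zscored_maps(self, default_cohort):
        # multiplying group maps by a positive diagonal leaves the
        # z-scored subject maps invariant
        truth = default_cohort.truth.spatial_maps
        run = default_cohort.runs[0]
        d1 = ica.zscore_components(
            ica.dual_regression(run, ica.GroupSpatialMaps(maps=truth)))
        scaled = truth * np.array([0.5, 2.0, 1.3, 0.1, 5.0, 1.0])[:, None]
        d2 = ica.zscore_components(
            ica.dual_regression(run, ica.GroupSpatialMaps(maps=scaled)))
        np.testing.assert_allclose(d1.spatial, d2.spatial, atol=1e-8)


class TestZscore:
    def test_standardizes_rows_and_columns(self, rng):
        dec = ica.SubjectDecomposition(temporal=rng.standard_normal((50, 4)),
                                       spatial=rng.standard_normal((4, 200)))
        z = ica.zscore_components(dec)
        np.testing.assert_allclose(z.spatial.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(z.spatial.std(axis=1), 1, atol=1e-10)
        np.testing.assert_allclose(z.temporal.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(z.temporal.std(axis=0), 1, atol=1e-10)

    def test_idempotent(self, rng):
        dec = ica.SubjectDecomposition(temporal=rng.standard_normal((50, 4)),
                                       spatial=rng.standard_normal((4, 200)))
        z1 = ica.zscore_components(dec)
        z2 = ica.zscore_components(z1)
        np.testing.assert_allclose(z1.spatial, z2.spatial, atol=1e-12)

    def test_constant_map_rejected(self, rng):
        dec = ica.SubjectDecomposition(temporal=rng.standard_normal((50, 2)),
                                       spatial=np.vstack([np.ones(100),
                                                          rng.standard_normal(100)]))
        with pytest.raises(ValueError, match="spatial"):
            ica.zscore_components(dec)
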
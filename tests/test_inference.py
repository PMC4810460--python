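"""Covariate-adjusted tests, AlphaSim calibration, and partial correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gicafc import inference as inf
from gicafc.fields import standardized_noise_field


class TestAdjustedGroupT:
    def test_reduces_to_pooled_t_without_covariate_effects(self, rng):
        n = 40
        cov = pd.DataFrame({"group": ["a"] * 20 + ["b"] * 20,
                            "age": np.zeros(n), "gender": ["M"] * n,
                            "education": np.zeros(n)})
        # constant covariates are collinear with the intercept; use
        # balanced random covariates independent of y instead
        cov["age"] = np.tile(rng.normal(50, 5, 20), 2)
        cov["gender"] = list(rng.choice(["M", "F"], 20)) * 2
        cov["education"] = np.tile(rng.normal(12, 2, 20), 2)
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(1, 1, 20)])
        t_adj, _, _ = inf.adjusted_group_t(y, cov)
        t_plain = stats.ttest_ind(y[20:], y[:20]).statistic
        # balanced, orthogonalized-by-tiling covariates leave the group
        # estimate untouched; small df difference shifts t slightly
        assert t_adj == pytest.approx(t_plain, rel=0.1)

    def test_summary_expansion_reproduces_printed_age_t(self):
        # deterministic two-point expansion matching mean and SD exactly
        def expand(mean, sd, n):
            base = np.resize([-1.0, 1.0], n)
            base = (base - base.mean()) / base.std(ddof=1)
            return mean + sd * base
        pat = expand(54.15, 8.78, 20)
        con = expand(51.58, 6.19, 19)
        t = stats.ttest_ind(pat, con, equal_var=True).statistic
        assert t == pytest.approx(1.052, rel=0.01)

    def test_confound_fully_explaining_group_difference(self, rng):
        n = 40
        age = np.concatenate([rng.normal(45, 3, 20), rng.normal(60, 3, 20)])
        y = 0.5 * age + rng.normal(0, 0.01, n)   # group difference is all age
        cov = pd.DataFrame({"group": ["a"] * 20 + ["b"] * 20, "age": age,
                            "gender": rng.choice(["M", "F"], n),
                            "education": rng.normal(12, 2, n)})
        t, p, _ = inf.adjusted_group_t(y, cov)
        assert abs(t) < 2.1
        t_plain = stats.ttest_ind(y[20:], y[:20]).statistic
        assert abs(t_plain) > 10

    def test_invariant_to_affine_covariate_rescaling(self, covariates_39, rng):
        y = rng.normal(size=39)
        t1, p1, _ = inf.adjusted_group_t(y, covariates_39)
        cov2 = covariates_39.copy()
        cov2["age"] = cov2["age"] * 12.0 + 100.0
        cov2["education"] = cov2["education"] / 3.0 - 2.0
        t2, p2, _ = inf.adjusted_group_t(y, cov2)
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_collinear_covariates_rejected(self, covariates_39, rng):
        cov = covariates_39.copy()
        cov["education"] = cov["age"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            inf.adjusted_group_t(rng.normal(size=39), cov)

    def test_group_swap_negates_t(self, covariates_39, rng):
        y = rng.normal(size=39)
        t1, _, _ = inf.adjusted_group_t(y, covariates_39)
        flipped = covariates_39.copy()
        flipped["group"] = flipped["group"].map(
            {"control": "patient", "patient": "control"})
        t2, _, _ = inf.adjusted_group_t(y, flipped)
        assert t1 == pytest.approx(-t2, abs=1e-9)


class TestConnectivity:
    def test_radius_five_with_3mm_voxels_is_18_connectivity(self):
        s = inf.connectivity_structure(5.0, 3.0)
        assert s.sum() == 19  # center + 6 faces + 12 edges, corners excluded
        assert not s[0, 0, 0] and not s[2, 2, 2]

    def test_tiny_radius_gives_face_connectivity_only(self):
        s = inf.connectivity_structure(3.0, 3.0)
        assert s.sum() == 7


class TestAlphaSim:
    def test_matches_independent_voxel_oracle_without_smoothing(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        spec = inf.AlphaSimSpec(voxel_p=0.01, n_sim=1000, fwhm_mm=0.0, seed=42)
        k = inf.alphasim_threshold(mask, spec)
        k_oracle = inf.alphasim_oracle_independent(mask, spec)
        assert abs(k - k_oracle) <= 1

    def test_threshold_nondecreasing_in_smoothing(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        k0 = inf.alphasim_threshold(mask, inf.AlphaSimSpec(n_sim=400, fwhm_mm=0.0, seed=1))
        k6 = inf.alphasim_threshold(mask, inf.AlphaSimSpec(n_sim=400, fwhm_mm=6.0, seed=1))
        assert k6 >= k0

    def test_saturated_threshold_flagged_unreachable(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        spec = inf.AlphaSimSpec(voxel_p=0.999, n_sim=200, fwhm_mm=0.0, seed=0)
        with pytest.warns(UserWarning, match="unreachable"):
            k = inf.alphasim_threshold(mask, spec)
        assert k > mask.sum()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            inf.alphasim_threshold(np.zeros((3, 3, 3), dtype=bool),
                                   inf.AlphaSimSpec(n_sim=100))


class TestVoxelwiseGroupCompare:
    def test_planted_deficit_found_as_single_cluster(self, covariates_39):
        from gicafc.synthetic import planted_deficit_maps
        shape = (14, 14, 10)
        grid = np.stack(np.meshgrid(*map(np.arange, shape), indexing="ij"), -1)
        d2 = np.sum((grid - np.array([7, 7, 5])) ** 2, -1)
        region = np.argsort(d2.ravel())[:30]
        maps, _ = planted_deficit_maps(20, 19, shape, region, effect_d=1.5,
                                       fwhm_mm=6.0, voxel_size_mm=3.0, seed=5)
        spec = inf.AlphaSimSpec(n_sim=1000, seed=3)
        tab = inf.voxelwise_group_compare(maps, np.ones(shape, bool),
                                          covariates_39, spec)
        sig = tab.clusters[tab.clusters.significant]
        assert len(sig) == 1
        detected = np.isin(tab.labels.ravel(), sig["cluster"].to_numpy())
        planted = np.zeros(np.prod(shape), bool)
        planted[region] = True
        dice = 2 * (detected & planted).sum() / (detected.sum() + planted.sum())
        assert dice >= 0.5

    def test_null_data_rarely_yields_significant_cluster(self, covariates_39, rng):
        shape = (10, 10, 8)
        mask = np.ones(shape, bool)
        spec = inf.AlphaSimSpec(n_sim=400, seed=9)
        k_star = inf.alphasim_threshold(mask, spec)
        hits = 0
        n_trials = 40
        for _ in range(n_trials):
            maps = np.stack([standardized_noise_field(shape, 6.0, 3.0, mask, rng).ravel()
                             for _ in range(39)])
            tab = inf.voxelwise_group_compare(maps, mask, covariates_39, spec,
                                              k_star=k_star)
            hits += int(len(tab.clusters) and tab.clusters.significant.any())
        assert hits / n_trials <= 0.2

    def test_empty_mask_returns_empty_table(self, covariates_39, rng):
        maps = rng.standard_normal((39, 27))
        with pytest.warns(UserWarning):
            tab = inf.voxelwise_group_compare(maps, np.zeros((3, 3, 3), bool),
                                              covariates_39,
                                              inf.AlphaSimSpec(n_sim=100))
        assert len(tab.clusters) == 0


class TestInterFCGroupCompare:
    def test_planted_decoupling_detected(self, covariates_39, rng):
        from gicafc.synthetic import correlated_timecourse_pair
        from gicafc.fc import fisher_z
        n_sub = 39
        z_mats = np.zeros((n_sub, 2, 2))
        for i in range(n_sub):
            rho = 0.5 if i < 20 else np.tanh(fisher_z(0.5) - 0.4)
            tc = correlated_timecourse_pair(60, rho, rng)
            z = fisher_z(np.corrcoef(tc.T)[0, 1])
            z_mats[i, 0, 1] = z_mats[i, 1, 0] = z
        tab = inf.inter_fc_group_compare(z_mats, covariates_39)
        assert len(tab) == 1
        assert tab.loc[0, "p"] < 0.05
        assert tab.loc[0, "t"] < 0  # patients (second level) decoupled

    def test_group_swap_negates_pair_t(self, covariates_39, rng):
        z_mats = rng.standard_normal((39, 2, 2)) * 0.1
        tab1 = inf.inter_fc_group_compare(z_mats, covariates_39)
        flipped = covariates_39.copy()
        flipped["group"] = flipped["group"].map(
            {"control": "patient", "patient": "control"})
        tab2 = inf.inter_fc_group_compare(z_mats, flipped)
        assert tab1.loc[0, "t"] == pytest.approx(-tab2.loc[0, "t"], abs=1e-9)


class TestPartialCorr:
    def test_no_covariates_equals_plain_pearson(self, rng):
        x, y = rng.standard_normal((2, 50))
        r, _ = inf.partial_corr(x, y, None)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_three_variable_closed_form(self, rng):
        x, y, z = rng.standard_normal((3, 200))
        x = x + 0.5 * z
        y = y + 0.8 * z
        r_p, _ = inf.partial_corr(x, y, z.reshape(-1, 1))
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        closed = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert r_p == pytest.approx(closed, abs=1e-10)

    def test_variable_in_covariate_span_rejected(self, rng):
        # residualizing a variable on itself leaves numerical dust, not a
        # meaningful correlation
        z = rng.standard_normal(60)
        x = rng.standard_normal(60)
        with pytest.raises(ValueError, match="constant residuals"):
            inf.partial_corr(x, z, z.reshape(-1, 1))

    def test_matches_independent_implementation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = pd.DataFrame(rng.standard_normal((80, 4)),
                          columns=["x", "y", "c1", "c2"])
        df["x"] += 0.5 * df["c1"]
        df["y"] += 0.4 * df["c1"] - 0.3 * df["c2"]
        ours_r, ours_p = inf.partial_corr(df["x"], df["y"], df[["c1", "c2"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert ours_r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert ours_p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-8)
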
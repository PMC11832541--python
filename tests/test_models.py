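import numpy as np
import pandas as pd
import pytest

import redunet as r


def make_records(n=120, seed=0, betas=(14.39, -0.03, -0.15, -0.74, 1.02, 0.0),
                 noise_sd=0.0, outcome="PC1"):
    rng = np.random.default_rng(seed + 777)
    t = r.gen_subject_table(n, seed=seed)
    t["bfr"] = rng.uniform(0.05, 0.95, n)
    t["gm_volume_norm"] = t["gm_volume"] / t["tiv"]
    t[outcome] = r.gen_moderated_outcome(
        t["cortical_thickness"].to_numpy(),
        t["bfr"].to_numpy(),
        t["site"].to_numpy(),
        t["sex"].to_numpy(),
        betas,
        noise_sd=noise_sd,
        seed=seed + 1,
    )
    return t


class TestNormalizeGMVolume:
    def test_simple_ratio(self):
        assert r.normalize_gm_volume(600_000, 1_500_000) == pytest.approx(0.4)

    def test_scale_invariance(self):
        for x in (1.0, 123.0, 9e5):
            assert r.normalize_gm_volume(x, 2 * x) == pytest.approx(0.5)

    def test_gm_not_smaller_than_tiv_rejected(self):
        with pytest.raises(ValueError):
            r.normalize_gm_volume(10.0, 10.0)
        with pytest.raises(ValueError):
            r.normalize_gm_volume(-1.0, 10.0)


class TestExcludeByMotion:
    def test_seven_over_threshold_leaves_294_of_301(self):
        disp = np.full(301, 1.0)
        disp[:7] = 3.0
        subjects = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(301)], "max_displacement": disp}
        )
        assert len(r.exclude_by_motion(subjects)) == 294

    def test_exactly_at_threshold_is_retained(self):
        subjects = pd.DataFrame(
            {"subject_id": ["a", "b"], "max_displacement": [2.5, 2.500001]}
        )
        kept = r.exclude_by_motion(subjects)
        assert list(kept["subject_id"]) == ["a"]

    def test_all_below_threshold_is_identity(self):
        subjects = pd.DataFrame(
            {"subject_id": ["a", "b"], "max_displacement": [0.3, 1.2]}
        )
        assert len(r.exclude_by_motion(subjects)) == 2

    def test_missing_displacement_rejected(self):
        subjects = pd.DataFrame(
            {"subject_id": ["a"], "max_displacement": [np.nan]}
        )
        with pytest.raises(ValueError):
            r.exclude_by_motion(subjects)


class TestFitModeration:
    def test_noiseless_cohort_recovers_betas_exactly(self):
        records = make_records(noise_sd=0.0)
        fit = r.fit_moderation(records, "thickness")
        b = {row["predictor"]: row["beta"] for _, row in
             fit.coefficients.iterrows()}
        assert b["cortical_thickness"] == pytest.approx(14.39, abs=1e-8)
        assert b["bfr"] == pytest.approx(-0.03, abs=1e-8)
        assert b["cortical_thickness:bfr"] == pytest.approx(-0.15, abs=1e-8)
        assert b["site"] == pytest.approx(-0.74, abs=1e-8)
        assert b["sex"] == pytest.approx(1.02, abs=1e-8)

    def test_brain_age_model_includes_chronological_age(self):
        records = make_records()
        fit = r.fit_moderation(records, "brain_age")
        assert "age" in set(fit.coefficients["predictor"])
        fit2 = r.fit_moderation(records, "thickness")
        assert "age" not in set(fit2.coefficients["predictor"])

    def test_residuals_orthogonal_to_design(self):
        records = make_records(noise_sd=1.5, seed=4)
        fit = r.fit_moderation(records, "thickness")
        design = pd.DataFrame(
            {
                "Intercept": 1.0,
                "bc": records["cortical_thickness"],
                "bfr": records["bfr"],
                "int": records["cortical_thickness"] * records["bfr"],
                "site": records["site"].astype(float),
                "sex": records["sex"].astype(float),
            }
        )
        import statsmodels.api as sm

        res = sm.OLS(records["PC1"], design).fit()
        cols = design.to_numpy()
        cols = cols / np.linalg.norm(cols, axis=0)
        assert np.max(np.abs(cols.T @ res.resid.to_numpy())) < 1e-8

    def test_coefficient_unbiasedness_across_replicates(self):
        """Mean estimate over 500 noisy replicates stays within Monte-Carlo
        error of the generating coefficients."""
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        n = 260
        t = r.gen_subject_table(n, seed=10)
        bfr = rng.uniform(0.05, 0.95, n)
        bc = t["cortical_thickness"].to_numpy()
        site = t["site"].to_numpy().astype(float)
        sex = t["sex"].to_numpy().astype(float)
        X = np.column_stack([np.ones(n), bc, bfr, bc * bfr, site, sex])
        betas = (14.39, -0.03, -0.15, -0.74, 1.02, 0.0)
        ests = []
        for rep in range(500):
            y = r.gen_moderated_outcome(
                bc, bfr, site, sex, betas, noise_sd=1.71, seed=1000 + rep
            )
            ests.append(np.linalg.lstsq(X, y, rcond=None)[0])
        mean_est = np.mean(ests, axis=0)
        se_mean = np.std(ests, axis=0, ddof=1) / np.sqrt(500)
        truth = np.array([0.0, 14.39, -0.03, -0.15, -0.74, 1.02])
        assert np.all(np.abs(mean_est - truth) < 4 * se_mean + 1e-9)

    def test_age_covariate_attenuates_confounded_bfr_effect(self):
        """When age drives both BFR and the outcome, adding chronological
        age shrinks the spurious BFR coefficient."""
        rng = np.random.default_rng(5)
        n = 300
        records = make_records(n, seed=5, betas=(1.0, 0.0, 0.0, 0.2, 0.1, 0.0),
                               noise_sd=0.5)
        records["bfr"] = np.clip(
            0.8 - 0.008 * (records["age"] - 18) + rng.normal(0, 0.05, n), 0, 1
        )
        records["PC1"] = records["PC1"] - 0.05 * records["age"]
        without = r.fit_moderation(records, "thickness", include_chron_age=False)
        with_age = r.fit_moderation(records, "thickness", include_chron_age=True)
        b_without = abs(without.coef("PC1", "bfr")["beta"])
        b_with = abs(with_age.coef("PC1", "bfr")["beta"])
        assert b_with < b_without

    def test_collinear_design_rejected(self):
        records = make_records(seed=6)
        records["site"] = records["sex"]  # exact collinearity
        with pytest.raises(ValueError, match="ollinear|ingular"):
            r.fit_moderation(records, "thickness")

    def test_insufficient_sample_rejected(self):
        records = make_records(n=120, seed=7).head(12)
        with pytest.raises(ValueError):
            r.fit_moderation(records, "thickness")

    def test_fit_statistics_reported_per_outcome(self):
        records = make_records(noise_sd=1.0, seed=8)
        records["PC2"] = records["PC1"] * 0.2 + 1.0
        fit = r.fit_moderation(records, "thickness", outcomes=["PC1", "PC2"])
        assert set(fit.fit["outcome"]) == {"PC1", "PC2"}
        assert {"resid_se", "r_squared", "adj_r_squared", "f_stat", "model_p"} <= set(
            fit.fit.columns
        )
        assert fit.residual_covariance.shape == (2, 2)


class TestSplits:
    def test_mean_split_boundary_goes_high(self):
        groups = r.mean_split([1.0, 2.0, 3.0])
        assert list(groups) == ["low", "high", "high"]

    def test_all_equal_values_are_high(self):
        assert (r.mean_split([2.0, 2.0, 2.0]) == "high").all()

    def test_group_means_straddle_grand_mean(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=200)
        groups = r.mean_split(v)
        assert v[groups == "low"].mean() < v.mean() <= v[groups == "high"].mean()

    def test_threshold_split_boundary_and_sizes(self):
        out = r.threshold_split([0.1, 0.29, 0.30, 0.9], cut=0.30)
        assert (out["n_low"], out["n_high"]) == (2, 2)

    def test_threshold_zero_rejected(self):
        with pytest.raises(ValueError):
            r.threshold_split([0.5], cut=0.0)

    def test_splits_partition_the_sample(self):
        rng = np.random.default_rng(10)
        v = rng.uniform(0, 1, 97)
        for groups in (r.mean_split(v), r.threshold_split(v, 0.3)["groups"]):
            assert ((groups == "low") | (groups == "high")).all()
            assert (groups == "low").sum() + (groups == "high").sum() == 97

    def test_negative_interaction_steepens_low_bfr_slope(self):
        """With a negative interaction, the brain-change -> outcome slope is
        steeper in the low-BFR stratum."""
        rng = np.random.default_rng(11)
        n = 400
        bc = rng.normal(0.0, 1.0, n)
        bfr = rng.uniform(0.0, 1.0, n)
        y = r.gen_moderated_outcome(
            bc, bfr, np.zeros(n), np.zeros(n), (2.0, 0.0, -3.0, 0.0, 0.0, 0.0),
            noise_sd=0.1, seed=11,
        )
        out = r.threshold_split(bfr, 0.5, brain_change=bc, outcome=y)
        assert out["slopes"]["low"] > out["slopes"]["high"]
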
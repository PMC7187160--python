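"""Nested random-intercept REML: oracles, adjustment, interaction tests."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import cohortpower as cp
from cohortpower.cohort import CohortConfig
from cohortpower.lmm import NestedLMM, RankDeficientError, build_design
from conftest import make_region, make_study


def _simple_longitudinal(rng, k=8, m=6, v=3, sc=0.8, sp=1.2, se=0.9, slope=0.5):
    cen = np.repeat(np.arange(k), m * v)
    par = np.repeat(np.arange(k * m), v)
    t = np.tile(np.arange(v), k * m).astype(float)
    y = (
        5.0
        + slope * t
        + rng.normal(0, sc, k)[cen]
        + rng.normal(0, sp, k * m)[par]
        + rng.normal(0, se, k * m * v)
    )
    X = np.column_stack([np.ones_like(t), t])
    return X, y, cen, par


class TestREMLEngine:
    def test_zero_variance_data_reduces_to_ols(self, rng):
        # when the between-cluster sample variation is below its iid
        # expectation the variance ratios hit the boundary exactly and the
        # GLS fit coincides with ordinary least squares; centering the draws
        # within participants makes the boundary certain rather than a coin
        # flip of sampling noise
        X, y, cen, par = _simple_longitudinal(rng, sc=0.0, sp=0.0, se=1.0)
        pm = pd.Series(y).groupby(par).transform("mean").to_numpy()
        y = y - pm
        fit = NestedLMM(X, y, cen, par, column_names=["intercept", "time"]).fit()
        assert fit.sigma2_center < 1e-6 * fit.sigma2_resid
        assert fit.sigma2_subject < 1e-6 * fit.sigma2_resid
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(
            fit.params.to_numpy(), beta_ols, rtol=1e-6, atol=1e-9
        )

    def test_matches_statsmodels_mixedlm(self, rng):
        statsmodels = pytest.importorskip("statsmodels.formula.api")
        X, y, cen, par = _simple_longitudinal(rng)
        fit = NestedLMM(X, y, cen, par, column_names=["intercept", "time"]).fit()
        df = pd.DataFrame({"y": y, "t": X[:, 1], "c": cen, "p": par})
        sm_fit = statsmodels.mixedlm(
            "y ~ t", df, groups="c", re_formula="1", vc_formula={"p": "0 + C(p)"}
        ).fit(reml=True)
        np.testing.assert_allclose(
            fit.params.to_numpy(), sm_fit.fe_params.to_numpy(), atol=1e-6
        )
        assert fit.sigma2_center == pytest.approx(sm_fit.cov_re.iloc[0, 0], abs=1e-4)
        assert fit.sigma2_subject == pytest.approx(sm_fit.vcomp[0], abs=1e-4)
        assert fit.sigma2_resid == pytest.approx(sm_fit.scale, abs=1e-4)

    def test_shift_equivariance(self, rng):
        X, y, cen, par = _simple_longitudinal(rng)
        f0 = NestedLMM(X, y, cen, par, column_names=["intercept", "time"]).fit()
        f1 = NestedLMM(X, y + 10.0, cen, par, column_names=["intercept", "time"]).fit()
        assert f1.params["intercept"] == pytest.approx(f0.params["intercept"] + 10.0)
        assert f1.params["time"] == pytest.approx(f0.params["time"], abs=1e-8)
        assert f1.sigma2_resid == pytest.approx(f0.sigma2_resid, rel=1e-6)

    def test_single_center_fixes_center_variance(self, rng):
        X, y, cen, par = _simple_longitudinal(rng, k=1, m=30)
        fit = NestedLMM(X, y, cen, par).fit()
        assert fit.sigma2_center == 0.0
        assert fit.converged


class TestFitLmm:
    def test_parameter_recovery_group_offset(self):
        cfg = CohortConfig(
            studies=[make_study(n_centers=10, hc=120, prehd=120)],
            regions={
                "r": make_region(
                    offsets={"HC": 0.0, "PreHD": -0.4},
                    slopes={"HC": -0.05, "PreHD": -0.05},
                    sigma_center=0.15,
                    sigma_subject=0.5,
                    sigma_resid=0.3,
                    coef_age=-0.02,
                    coef_tiv=2.0,
                )
            },
            scanner_effect_scale=0.0,
        )
        coh = cp.generate_cohort(cfg, seed=21)
        spec = cp.ModelSpec(response="r")
        fit = cp.fit_lmm(coh.data, spec)
        assert fit.converged
        assert abs(fit.params["group[PreHD]"] - (-0.4)) < 3 * fit.bse["group[PreHD]"]
        assert abs(fit.params["time"] - (-0.05)) < 3 * fit.bse["time"]

    def test_rank_deficiency_names_columns(self, small_cohort):
        df = small_cohort.data.copy()
        df["tiv"] = 1.0  # constant -> collinear with intercept
        with pytest.raises(RankDeficientError, match="tiv"):
            cp.fit_lmm(df, cp.ModelSpec(response="caudate"))

    def test_result_json_roundtrip(self, small_cohort):
        import json

        fit = cp.fit_lmm(
            small_cohort.data,
            cp.ModelSpec(response="caudate", fixed_terms=("intercept", "time", "group")),
        )
        payload = json.loads(fit.to_json())
        assert payload["n_obs"] == fit.n_obs
        assert payload["beta"]["time"]["estimate"] == pytest.approx(
            float(fit.params["time"])
        )


class TestAdjustBaseline:
    def test_no_nuisance_terms_returns_observed(self, small_cohort):
        spec = cp.ModelSpec(
            response="caudate", fixed_terms=("intercept", "time", "group")
        )
        fit = cp.fit_lmm(small_cohort.data, spec)
        adj = cp.adjust_baseline(fit, small_cohort.data, spec)
        base = small_cohort.baseline().set_index("participant")["caudate"]
        np.testing.assert_allclose(
            adj.set_index("participant")["adjusted_baseline"], base[adj["participant"]]
        )

    def test_noise_free_covariates_fully_removed(self):
        # exact generative model with a TIV effect and no noise: adjustment
        # must equalize participants who differ only in covariates
        cfg = CohortConfig(
            studies=[make_study(n_centers=3, hc=30, prehd=30)],
            regions={
                "r": make_region(
                    offsets={"HC": 0.0, "PreHD": -0.4},
                    slopes={"HC": -0.02, "PreHD": -0.02},
                    sigma_center=0.0,
                    sigma_subject=0.0,
                    sigma_resid=0.0,
                    coef_age=-0.015,
                    coef_sex=0.25,
                    coef_tiv=2.0,
                )
            },
            scanner_effect_scale=0.0,
        )
        coh = cp.generate_cohort(cfg, seed=13)
        spec = cp.ModelSpec(
            response="r",
            fixed_terms=("intercept", "time", "age", "sex", "tiv", "group"),
        )
        fit = cp.fit_lmm(coh.data, spec)
        adj = cp.adjust_baseline(fit, coh.data, spec)
        for g in ("HC", "PreHD"):
            vals = adj.loc[adj["group"] == g, "adjusted_baseline"]
            assert vals.std() < 1e-8
        diff = (
            adj.loc[adj["group"] == "PreHD", "adjusted_baseline"].mean()
            - adj.loc[adj["group"] == "HC", "adjusted_baseline"].mean()
        )
        assert diff == pytest.approx(-0.4, abs=1e-8)

    def test_group_mean_difference_tracks_beta(self):
        cfg = CohortConfig(
            studies=[make_study(n_centers=6, hc=90, prehd=90)],
            regions={
                "r": make_region(
                    offsets={"HC": 0.0, "PreHD": -0.4},
                    slopes={"HC": -0.03, "PreHD": -0.03},
                    sigma_center=0.1,
                    sigma_subject=0.4,
                    sigma_resid=0.3,
                )
            },
            scanner_effect_scale=0.0,
        )
        coh = cp.generate_cohort(cfg, seed=31)
        spec = cp.ModelSpec(
            response="r", fixed_terms=("intercept", "time", "group")
        )
        fit = cp.fit_lmm(coh.data, spec)
        adj = cp.adjust_baseline(fit, coh.data, spec)
        diff = (
            adj.loc[adj["group"] == "PreHD", "adjusted_baseline"].mean()
            - adj.loc[adj["group"] == "HC", "adjusted_baseline"].mean()
        )
        # baseline-only means carry extra residual noise relative to the
        # all-visit GLS estimate; bound from the generative residual SD
        n_per_group = 90
        extra_sd = np.sqrt(2 * 0.3**2 * (1 - 1 / 3) / n_per_group)
        assert diff == pytest.approx(fit.params["group[PreHD]"], abs=4 * extra_sd)


class TestStudyGroupInteraction:
    def test_single_study_gives_empty_map(self, small_cohort):
        one = small_cohort.data[small_cohort.data["study"] == "ALPHA"]
        assert cp.test_study_group_interaction(one, cp.ModelSpec("caudate")) == {}

    def test_injected_offset_detected(self):
        region = make_region(
            offsets={"HC": 0.0, "PreHD": -0.3, "HD": -0.8},
            slopes={"HC": -0.02, "PreHD": -0.02, "HD": -0.02},
            sigma_center=0.05,
            sigma_subject=0.4,
            sigma_resid=0.25,
        )
        shifted = dataclasses.replace(
            region, offsets={"HC": 0.0, "PreHD": -0.3, "HD": -0.8 - 3 * 0.25}
        )
        cfg_a = CohortConfig(
            studies=[make_study("A", n_centers=5, hc=80, prehd=80, hd=80)],
            regions={"r": region},
            scanner_effect_scale=0.0,
        )
        cfg_b = CohortConfig(
            studies=[make_study("B", n_centers=5, hc=80, prehd=80, hd=80)],
            regions={"r": shifted},
            scanner_effect_scale=0.0,
        )
        data = pd.concat(
            [
                cp.generate_cohort(cfg_a, seed=41).data,
                cp.generate_cohort(cfg_b, seed=42).data,
            ],
            ignore_index=True,
        )
        pmap = cp.test_study_group_interaction(data, cp.ModelSpec("r"))
        assert pmap[("A", "B", "HD")] < 0.05
        assert pmap[("A", "B", "PreHD")] > 0.05

    def test_null_type_i_error(self):
        # two studies generated from identical parameters: the (single)
        # interaction contrast should reject at roughly the nominal rate
        region = make_region(
            offsets={"HC": 0.0, "PreHD": -0.3},
            slopes={"HC": -0.02, "PreHD": -0.02},
            sigma_center=0.05,
            sigma_subject=0.4,
            sigma_resid=0.25,
        )
        rejections = 0
        n_rep = 120
        for r in range(n_rep):
            frames = []
            for sid, seed in (("A", 2 * r), ("B", 2 * r + 1)):
                cfg = CohortConfig(
                    studies=[make_study(sid, n_centers=3, hc=15, prehd=15)],
                    regions={"r": region},
                    scanner_effect_scale=0.0,
                )
                frames.append(cp.generate_cohort(cfg, seed=seed).data)
            data = pd.concat(frames, ignore_index=True)
            pmap = cp.test_study_group_interaction(data, cp.ModelSpec("r"))
            assert len(pmap) == 1  # one contrast -> Bonferroni factor 1
            rejections += next(iter(pmap.values())) < 0.05
        rate = rejections / n_rep
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestHyperparameters:
    def test_field_mapping(self, small_cohort):
        fit = cp.fit_lmm(small_cohort.data, cp.ModelSpec("caudate"))
        hyper = cp.extract_hyperparameters(fit, treated_fraction_sd=0.1)
        assert hyper.baseline_mean == pytest.approx(float(fit.params["intercept"]))
        assert hyper.placebo_slope == pytest.approx(float(fit.params["time"]))
        assert hyper.sigma2_resid == pytest.approx(fit.sigma2_resid)
        assert hyper.tau_treatment == 0.1

    def test_refuses_nonconverged(self, small_cohort):
        fit = cp.fit_lmm(small_cohort.data, cp.ModelSpec("caudate"))
        bad = dataclasses.replace(fit, converged=False)
        with pytest.raises(ValueError):
            cp.extract_hyperparameters(bad)

    def test_roundtrip_recovery_through_simulation(self):
        hyper = cp.TrialHyperparameters(
            baseline_mean=6.5,
            placebo_slope=-0.12,
            sigma2_center=0.02,
            sigma2_subject=0.3,
            sigma2_resid=0.09,
        )
        design = cp.TrialDesign(n_centers=25, n_per_center=40, delta=0.0, n_sim=100)
        data = cp.simulate_trial(design, hyper, seed=17)
        X, names, _ = build_design(
            data, cp.ModelSpec("y", fixed_terms=("intercept", "time"))
        )
        fit = NestedLMM(
            X,
            data["y"].to_numpy(),
            data["center"].to_numpy(),
            data["participant"].to_numpy(),
            column_names=names,
        ).fit()
        back = cp.extract_hyperparameters(fit)
        assert back.baseline_mean == pytest.approx(6.5, abs=3 * float(fit.bse["intercept"]))
        assert back.placebo_slope == pytest.approx(-0.12, abs=3 * float(fit.bse["time"]))
        assert back.sigma2_subject == pytest.approx(0.3, rel=0.25)
        assert back.sigma2_resid == pytest.approx(0.09, rel=0.1)
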
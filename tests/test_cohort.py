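"""Synthetic cohort generator and derived-variable utilities."""

import numpy as np
import pandas as pd
import pytest

import cohortpower as cp
from cohortpower.cohort import (
    REF_AGE,
    REF_SEX,
    REF_TIV,
    CohortConfig,
    CohortConfigError,
    PairingError,
    RegionParams,
)
from conftest import make_region, make_study


class TestBurdenScore:
    @pytest.mark.parametrize(
        "age,cag,expected",
        [(40, 35.5, 0.0), (40, 43, 300.0), (30, 40, 135.0)],
    )
    def test_hand_examples(self, age, cag, expected):
        assert cp.burden_score(age, cag) == pytest.approx(expected)

    def test_requires_positive_age(self):
        with pytest.raises(ValueError):
            cp.burden_score(0, 42)


class TestTotalIntracranialVolume:
    def test_zero_and_sum(self):
        assert cp.total_intracranial_volume(0, 0, 0, 0) == 0.0
        assert cp.total_intracranial_volume(300, 500, 60, 500) == 1360.0

    def test_symmetric_in_components(self):
        vals = (312.5, 480.0, 58.2, 520.3)
        perms = {cp.total_intracranial_volume(*p) for p in
                 [(vals[i], vals[j], vals[k], vals[l])
                  for i, j, k, l in [(0, 1, 2, 3), (3, 2, 1, 0), (1, 0, 3, 2)]]}
        assert len(perms) == 1

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            cp.total_intracranial_volume(-1, 0, 0, 0)


class TestCombineBilateral:
    def test_pair_sum_and_midline(self):
        out = cp.combine_bilateral(
            {"Left-Caudate": 3.1, "Right-Caudate": 3.3, "Brain-Stem": 20.0}
        )
        assert out == {"Caudate": pytest.approx(6.4), "Brain-Stem": 20.0}

    def test_missing_partner_raises(self):
        with pytest.raises(PairingError):
            cp.combine_bilateral({"Left-Caudate": 3.1})

    def test_atlas_sized_input(self):
        # 73 left/right pairs plus 10 midline structures = 156 inputs -> 83
        volumes = {}
        for i in range(73):
            volumes[f"Left-R{i:03d}"] = 1.0 + i
            volumes[f"Right-R{i:03d}"] = 2.0 + i
        for i in range(10):
            volumes[f"Mid{i}"] = 5.0
        assert len(volumes) == 156
        out = cp.combine_bilateral(volumes)
        assert len(out) == 83
        assert out["R010"] == pytest.approx(23.0)


class TestConfigValidation:
    def test_negative_sigma_rejected(self, small_config):
        cfg = CohortConfig(
            studies=[make_study()],
            regions={"r": make_region(sigma_resid=-1.0)},
        )
        with pytest.raises(CohortConfigError):
            cfg.validate()

    def test_empty_groups_rejected(self):
        st = make_study(hc=0, prehd=0, hd=0)
        st.group_sizes = {"HC": 0}
        with pytest.raises(CohortConfigError):
            CohortConfig(studies=[st]).validate()

    def test_nonincreasing_visits_rejected(self):
        cfg = CohortConfig(studies=[make_study()], visit_times=(0.0, 1.0, 1.0))
        with pytest.raises(CohortConfigError):
            cfg.validate()

    def test_roundtrip_through_dict(self, small_config):
        clone = CohortConfig.from_dict(small_config.to_dict())
        assert clone.to_dict() == small_config.to_dict()


class TestGenerator:
    def test_seed_determinism(self, small_config):
        a = cp.generate_cohort(small_config, seed=5)
        b = cp.generate_cohort(small_config, seed=5)
        c = cp.generate_cohort(small_config, seed=6)
        pd.testing.assert_frame_equal(a.data, b.data)
        assert not a.data.equals(c.data)

    def test_structure_invariants(self, small_cohort):
        data = small_cohort.data
        per_part = data.groupby("participant")
        assert (per_part["visit"].count() == 3).all()
        assert (per_part["scanner"].nunique() == 1).all()
        assert set(data["group"]) <= {"HC", "PreHD", "HD"}
        assert (data[small_cohort.regions] > 0).all().all()
        # study sizes as configured
        sizes = data.groupby("study")["participant"].nunique()
        assert sizes["ALPHA"] == 100 and sizes["BETA"] == 75

    def test_hc_cag_below_cutoff(self, small_cohort):
        hc = small_cohort.data[small_cohort.data["group"] == "HC"]
        assert (hc["cag"] < 36).all()

    def test_demographics_match_config(self):
        # PreHD age distribution drawn as configured (TRACK-like 41.1 +/- 8.8)
        cfg = CohortConfig(
            studies=[make_study(n_centers=4, hc=0, prehd=105, hd=0, age=(41.1, 8.8))],
            regions={"r": make_region()},
        )
        coh = cp.generate_cohort(cfg, seed=2)
        ages = coh.baseline()["age"]
        se = 8.8 / np.sqrt(105)
        assert abs(ages.mean() - 41.1) < 3 * se

    def test_identical_groups_give_null_effect(self):
        cfg = CohortConfig(
            studies=[make_study(n_centers=4, hc=300, prehd=300)],
            regions={
                "r": make_region(
                    offsets={"HC": 0.0, "PreHD": 0.0},
                    slopes={"HC": -0.01, "PreHD": -0.01},
                    sigma_center=0.0,
                    sigma_subject=0.0,
                    sigma_resid=0.4,
                )
            },
            scanner_effect_scale=0.0,
        )
        coh = cp.generate_cohort(cfg, seed=3)
        base = coh.baseline()
        hc = base.loc[base["group"] == "HC", "r"]
        pre = base.loc[base["group"] == "PreHD", "r"]
        t = (hc.mean() - pre.mean()) / pre.std(ddof=1)
        mc_se = np.sqrt(1 / 300 + 1 / 300)
        assert abs(t) < 3 * mc_se

    def test_half_sigma_offset_recovers_effect_half(self):
        # group offset = 0.5 sigma_resid with no other variance -> t ~ 0.5
        cfg = CohortConfig(
            studies=[make_study(n_centers=4, hc=2000, prehd=2000)],
            regions={
                "r": make_region(
                    offsets={"HC": 0.0, "PreHD": -0.2},
                    slopes={"HC": 0.0, "PreHD": 0.0},
                    sigma_center=0.0,
                    sigma_subject=0.0,
                    sigma_resid=0.4,
                )
            },
            scanner_effect_scale=0.0,
        )
        coh = cp.generate_cohort(cfg, seed=4)
        base = coh.baseline()
        hc = base.loc[base["group"] == "HC", "r"]
        pre = base.loc[base["group"] == "PreHD", "r"]
        t = (hc.mean() - pre.mean()) / pre.std(ddof=1)
        n = 2000
        mc_se = np.sqrt(2 / n + 0.25 / (2 * n))
        assert t == pytest.approx(0.5, abs=3 * mc_se)

    def test_variance_decomposition(self):
        cfg = CohortConfig(
            studies=[make_study(n_centers=60, hc=1200, prehd=0)],
            regions={
                "r": make_region(
                    offsets={"HC": 0.0},
                    slopes={"HC": 0.0},
                    sigma_center=0.5,
                    sigma_subject=1.0,
                    sigma_resid=0.7,
                )
            },
            scanner_effect_scale=0.0,
        )
        coh = cp.generate_cohort(cfg, seed=9)
        df = coh.data
        # residual: within-participant variance around participant means
        within = df.groupby("participant")["r"].var(ddof=1).mean()
        pm = df.groupby(["center", "participant"])["r"].mean().reset_index()
        subject = pm.groupby("center")["r"].var(ddof=1).mean() - within / 3
        center = pm.groupby("center")["r"].mean().var(ddof=1) - (
            subject + within / 3
        ) / 20
        assert within == pytest.approx(0.49, rel=0.15)
        assert subject == pytest.approx(1.0, rel=0.2)
        # only 60 center draws: 3 MC SDs is roughly 70% relative
        assert center == pytest.approx(0.25, rel=0.7)

    def test_zero_random_sds_is_deterministic_mean(self):
        cfg = CohortConfig(
            studies=[make_study(n_centers=3, hc=10, prehd=10)],
            regions={
                "r": RegionParams(
                    baseline_mean=5.0,
                    coef_age=-0.01,
                    coef_sex=0.2,
                    coef_tiv=1.0,
                    offsets={"HC": 0.0, "PreHD": -0.4},
                    slopes={"HC": -0.01, "PreHD": -0.05},
                )
            },
            scanner_effect_scale=0.0,
        )
        coh = cp.generate_cohort(cfg, seed=11)
        df = coh.data
        expected = (
            5.0
            - 0.01 * (df["age"] - REF_AGE)
            + 0.2 * (df["sex"] - REF_SEX)
            + 1.0 * (df["tiv"] - REF_TIV)
            + np.where(df["group"] == "PreHD", -0.4, 0.0)
            + np.where(df["group"] == "PreHD", -0.05, -0.01) * df["time"]
        )
        np.testing.assert_allclose(df["r"], expected, rtol=1e-12)


class TestCsvRoundTrip:
    def test_write_read_identity(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        cp.write_cohort_csv(small_cohort, path)
        back = cp.read_cohort_csv(path)
        assert back.regions == small_cohort.regions
        assert back.markers == small_cohort.markers
        pd.testing.assert_frame_equal(back.data, small_cohort.data)

    def test_missing_column_rejected(self, small_cohort, tmp_path):
        path = tmp_path / "bad.csv"
        small_cohort.data.drop(columns=["tiv"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="tiv"):
            cp.read_cohort_csv(path)
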
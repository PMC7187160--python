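import numpy as np
import pytest

import cohortpower as cp
from cohortpower.cohort import CohortConfig, MarkerParams, RegionParams, StudyDesign


def make_study(
    study_id="S1",
    n_centers=5,
    hc=40,
    prehd=40,
    hd=0,
    age=(45.0, 10.0),
    cag_prehd=(42.5, 2.5),
):
    groups = {"HC": hc, "PreHD": prehd, "HD": hd}
    return StudyDesign(
        study_id=study_id,
        n_centers=n_centers,
        group_sizes={g: n for g, n in groups.items() if n > 0},
        age={g: age for g in groups},
        sex_male={g: 0.5 for g in groups},
        cag={"HC": (20.3, 3.3), "PreHD": cag_prehd, "HD": (43.0, 3.0)},
    )


def make_region(
    baseline=6.9,
    offsets=None,
    slopes=None,
    sigma_center=0.1,
    sigma_subject=0.5,
    sigma_resid=0.3,
    **coefs,
):
    return RegionParams(
        baseline_mean=baseline,
        offsets=offsets or {"HC": 0.0, "PreHD": -0.45, "HD": -1.2},
        slopes=slopes or {"HC": -0.005, "PreHD": -0.1, "HD": -0.16},
        sigma_center=sigma_center,
        sigma_subject=sigma_subject,
        sigma_resid=sigma_resid,
        **coefs,
    )


@pytest.fixture(scope="session")
def small_config():
    """Two studies, a handful of centers, two regions and one marker."""
    return CohortConfig(
        studies=[
            make_study("ALPHA", n_centers=5, hc=40, prehd=40, hd=20),
            make_study("BETA", n_centers=3, hc=30, prehd=30, hd=15),
        ],
        regions={
            "caudate": make_region(
                coef_age=-0.02, coef_sex=0.3, coef_tiv=2.6, coef_time_age=-0.0008
            ),
            "brain_stem": make_region(
                baseline=22.0,
                offsets={"HC": 0.0, "PreHD": -0.05, "HD": -0.1},
                slopes={"HC": -0.004, "PreHD": -0.006, "HD": -0.008},
                sigma_center=0.2,
                sigma_subject=1.8,
                sigma_resid=0.8,
                coef_tiv=8.0,
            ),
        },
        markers={
            "tms": MarkerParams(
                intercept=2.2,
                offsets={"HC": 0.0, "PreHD": 1.6, "HD": 19.0},
                slopes={"HC": 0.05, "PreHD": 0.75, "HD": 1.6},
                sigma_center=0.6,
                sigma_subject=3.6,
                sigma_resid=3.8,
            )
        },
        seed=0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return cp.generate_cohort(small_config, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
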
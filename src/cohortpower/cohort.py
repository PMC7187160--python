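"""Synthetic multicenter longitudinal cohorts of regional brain volumes.

Generates long-format participant-visit tables with the hierarchical
structure the downstream analysis assumes: participants nested in centers
nested in studies, three visits per participant, group structure
HC / PreHD / HD, demographic covariates (age, sex, TIV, CAG), per-scanner
additive offsets, and regional volumes built from fixed covariate effects,
group-dependent baseline offsets and atrophy slopes, plus Gaussian center,
participant and residual variance components.  Clinical markers (TMS, SDMT,
SWRT analogues) use the same nested error structure but a much smaller
slope-to-noise ratio, mimicking noisy clinical measures of progression.

Also houses the small deterministic derived-variable utilities: the disease
burden score, total intracranial volume, and bilateral region combination.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._random import rng_for

__all__ = [
    "RegionParams",
    "MarkerParams",
    "StudyDesign",
    "CohortConfig",
    "Cohort",
    "CohortConfigError",
    "PairingError",
    "default_cohort_config",
    "generate_cohort",
    "burden_score",
    "total_intracranial_volume",
    "combine_bilateral",
    "write_cohort_csv",
    "read_cohort_csv",
    "BASE_COLUMNS",
]

GROUPS = ("HC", "PreHD", "HD")

#: fixed leading column order of the cohort CSV contract
BASE_COLUMNS = (
    "study",
    "center",
    "participant",
    "visit",
    "time",
    "age",
    "sex",
    "tiv",
    "group",
    "scanner",
    "cag",
)

# covariate reference values used by the generative model so that
# ``baseline_mean`` is the expected HC volume at the reference covariates
REF_AGE = 45.0
REF_SEX = 0.5
REF_TIV = 1.39


class CohortConfigError(ValueError):
    """Invalid cohort configuration (negative variance, empty group, ...)."""


class PairingError(ValueError):
    """A lateralized region is missing its contralateral partner."""


@dataclass
class RegionParams:
    """Generative parameters of one regional volume (mL, years)."""

    baseline_mean: float
    coef_age: float = 0.0  # mL per year of baseline age
    coef_sex: float = 0.0  # mL for male vs female
    coef_tiv: float = 0.0  # mL per liter of TIV
    coef_time_age: float = 0.0  # mL/year of slope per year of age
    offsets: dict = field(default_factory=dict)  # group -> mL at baseline
    slopes: dict = field(default_factory=dict)  # group -> mL/year
    sigma_center: float = 0.0
    sigma_subject: float = 0.0
    sigma_resid: float = 0.0


@dataclass
class MarkerParams:
    """Generative parameters of one clinical marker (score units, years)."""

    intercept: float
    offsets: dict = field(default_factory=dict)
    slopes: dict = field(default_factory=dict)
    sigma_center: float = 0.0
    sigma_subject: float = 0.0
    sigma_resid: float = 0.0


@dataclass
class StudyDesign:
    """One study block: centers, per-group totals, and demographics.

    ``group_sizes`` are study totals; participants are dealt to centers
    round-robin, so per-center counts differ by at most one.  ``age``,
    ``sex_male`` and ``cag`` are per-group maps; ``age``/``cag`` values are
    ``(mean, sd)`` pairs, ``sex_male`` the fraction of male participants.
    """

    study_id: str
    n_centers: int
    group_sizes: dict
    age: dict
    sex_male: dict
    cag: dict


@dataclass
class CohortConfig:
    studies: list
    visit_times: tuple = (0.0, 1.0, 2.0)
    tiv_mean: float = 1.39
    tiv_sd: float = 0.14
    regions: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)
    #: per-(scanner, region) offsets drawn from N(0, (scale * sigma_resid)^2)
    scanner_effect_scale: float = 0.5
    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if not self.studies:
            raise CohortConfigError("at least one study block is required")
        times = np.asarray(self.visit_times, dtype=float)
        if times.size < 2 or np.any(np.diff(times) <= 0):
            raise CohortConfigError("visit_times must be strictly increasing")
        for st in self.studies:
            if st.n_centers < 1:
                raise CohortConfigError(f"{st.study_id}: n_centers must be >= 1")
            if not st.group_sizes or all(n == 0 for n in st.group_sizes.values()):
                raise CohortConfigError(f"{st.study_id}: no participants configured")
            for g, n in st.group_sizes.items():
                if g not in GROUPS:
                    raise CohortConfigError(f"{st.study_id}: unknown group {g!r}")
                if n < 0:
                    raise CohortConfigError(f"{st.study_id}: negative count for {g}")
                if n > 0 and (g not in st.age or g not in st.sex_male or g not in st.cag):
                    raise CohortConfigError(
                        f"{st.study_id}: demographics missing for group {g}"
                    )
        for name, p in {**self.regions, **self.markers}.items():
            for attr in ("sigma_center", "sigma_subject", "sigma_resid"):
                if getattr(p, attr) < 0:
                    raise CohortConfigError(f"{name}: {attr} must be >= 0")
        if self.tiv_sd < 0 or self.scanner_effect_scale < 0:
            raise CohortConfigError("scale parameters must be >= 0")

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["visit_times"] = list(self.visit_times)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        d["studies"] = [
            s if isinstance(s, StudyDesign) else StudyDesign(**s) for s in d["studies"]
        ]
        d["regions"] = {
            k: (v if isinstance(v, RegionParams) else RegionParams(**v))
            for k, v in d.get("regions", {}).items()
        }
        d["markers"] = {
            k: (v if isinstance(v, MarkerParams) else MarkerParams(**v))
            for k, v in d.get("markers", {}).items()
        }
        if "visit_times" in d:
            d["visit_times"] = tuple(float(t) for t in d["visit_times"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        text = open(path).read()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass
class Cohort:
    """Long-format cohort table plus the names of its outcome columns."""

    data: pd.DataFrame
    regions: list
    markers: list

    def baseline(self) -> pd.DataFrame:
        return self.data[self.data["visit"] == 0]


# ---------------------------------------------------------------------------
# deterministic derived-variable utilities
# ---------------------------------------------------------------------------


def burden_score(age: float, cag: float):
    """Disease burden score, age x (CAG - 35.5), a lifetime-exposure proxy."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    out = age * (np.asarray(cag, dtype=float) - 35.5)
    return float(out) if out.ndim == 0 else out


def total_intracranial_volume(csf, cortical_gm, deep_gm, wm):
    """TIV as the sum of CSF, cortical gray, deep gray and white matter."""
    parts = [np.asarray(v, dtype=float) for v in (csf, cortical_gm, deep_gm, wm)]
    if any(np.any(p < 0) for p in parts):
        raise ValueError("tissue volumes must be non-negative")
    out = parts[0] + parts[1] + parts[2] + parts[3]
    return float(out) if np.ndim(out) == 0 else out


_LAT_RE = re.compile(r"^(left|right)[\s_-]+(.+)$", re.IGNORECASE)


def combine_bilateral(volumes: Mapping[str, float]) -> dict:
    """Sum left/right region pairs under the base name; pass midline through.

    Region names may carry a ``Left``/``Right`` tag separated by space,
    hyphen or underscore (any case); untagged names are treated as midline.
    """
    combined: dict = {}
    sides: dict = {}
    for name, value in volumes.items():
        m = _LAT_RE.match(name)
        if m:
            side = m.group(1).lower()
            base = m.group(2)
            sides.setdefault(base, {})[side] = value
        else:
            if name in combined:
                raise PairingError(f"duplicate midline region {name!r}")
            combined[name] = value
    for base, pair in sides.items():
        if set(pair) != {"left", "right"}:
            missing = ({"left", "right"} - set(pair)).pop()
            raise PairingError(f"region {base!r} is missing its {missing} side")
        if base in combined:
            raise PairingError(f"region {base!r} appears both lateralized and midline")
        combined[base] = pair["left"] + pair["right"]
    return combined


# ---------------------------------------------------------------------------
# default configuration: three studies mirroring published multicenter
# HD observational cohorts (totals 265 / 294 / 65 over 20 / 4 / 1 centers)
# ---------------------------------------------------------------------------


def _default_regions() -> dict:
    # Bilateral-combined volumes in mL.  Offsets/slopes chosen so the
    # HC-vs-PreHD standardized effect (offset / residual SD) is large for
    # the striatal and insular-WM regions and nonventricular CSF, and small
    # for the two distractor regions.
    return {
        "caudate": RegionParams(
            baseline_mean=6.9,
            coef_age=-0.020,
            coef_sex=0.30,
            coef_tiv=2.6,
            coef_time_age=-0.0008,
            offsets={"HC": 0.0, "PreHD": -0.45, "HD": -1.30},
            slopes={"HC": -0.004, "PreHD": -0.10, "HD": -0.16},
            sigma_center=0.10,
            sigma_subject=0.60,
            sigma_resid=0.32,
        ),
        "pallidum": RegionParams(
            baseline_mean=3.3,
            coef_age=-0.008,
            coef_sex=0.15,
            coef_tiv=1.3,
            coef_time_age=-0.0004,
            offsets={"HC": 0.0, "PreHD": -0.28, "HD": -0.70},
            slopes={"HC": -0.002, "PreHD": -0.050, "HD": -0.080},
            sigma_center=0.05,
            sigma_subject=0.30,
            sigma_resid=0.20,
        ),
        "putamen": RegionParams(
            baseline_mean=9.0,
            coef_age=-0.028,
            coef_sex=0.40,
            coef_tiv=3.2,
            coef_time_age=-0.0010,
            offsets={"HC": 0.0, "PreHD": -0.58, "HD": -1.60},
            slopes={"HC": -0.006, "PreHD": -0.11, "HD": -0.18},
            sigma_center=0.12,
            sigma_subject=0.85,
            sigma_resid=0.55,
        ),
        "insula_white_matter": RegionParams(
            baseline_mean=2.4,
            coef_age=-0.005,
            coef_sex=0.10,
            coef_tiv=0.9,
            coef_time_age=-0.0002,
            offsets={"HC": 0.0, "PreHD": -0.14, "HD": -0.34},
            slopes={"HC": -0.001, "PreHD": -0.022, "HD": -0.040},
            sigma_center=0.04,
            sigma_subject=0.24,
            sigma_resid=0.16,
        ),
        "nonventricular_csf": RegionParams(
            baseline_mean=310.0,
            coef_age=1.10,
            coef_sex=12.0,
            coef_tiv=110.0,
            coef_time_age=0.030,
            offsets={"HC": 0.0, "PreHD": 14.0, "HD": 36.0},
            slopes={"HC": 0.6, "PreHD": 3.2, "HD": 5.5},
            sigma_center=4.0,
            sigma_subject=26.0,
            sigma_resid=18.0,
        ),
        # distractors: essentially disease-insensitive
        "brain_stem": RegionParams(
            baseline_mean=22.0,
            coef_age=-0.020,
            coef_sex=1.0,
            coef_tiv=8.0,
            offsets={"HC": 0.0, "PreHD": -0.08, "HD": -0.20},
            slopes={"HC": -0.004, "PreHD": -0.008, "HD": -0.012},
            sigma_center=0.25,
            sigma_subject=1.9,
            sigma_resid=0.80,
        ),
        "superior_frontal_gyrus": RegionParams(
            baseline_mean=31.0,
            coef_age=-0.075,
            coef_sex=1.4,
            coef_tiv=11.0,
            coef_time_age=-0.0015,
            offsets={"HC": 0.0, "PreHD": -0.35, "HD": -1.0},
            slopes={"HC": -0.020, "PreHD": -0.050, "HD": -0.090},
            sigma_center=0.40,
            sigma_subject=2.8,
            sigma_resid=1.40,
        ),
    }


def _default_markers() -> dict:
    # Noisy clinical analogues: slope-to-residual-SD ratios are an order of
    # magnitude below the imaging regions', so they are weak progression
    # markers even though group offsets are clearly nonzero.
    return {
        "tms": MarkerParams(
            intercept=2.2,
            offsets={"HC": 0.0, "PreHD": 1.6, "HD": 19.5},
            slopes={"HC": 0.05, "PreHD": 0.75, "HD": 1.6},
            sigma_center=0.6,
            sigma_subject=3.6,
            sigma_resid=3.8,
        ),
        "sdmt": MarkerParams(
            intercept=52.0,
            offsets={"HC": 0.0, "PreHD": -2.5, "HD": -14.0},
            slopes={"HC": -0.10, "PreHD": -0.65, "HD": -1.4},
            sigma_center=1.2,
            sigma_subject=8.5,
            sigma_resid=5.5,
        ),
        "swrt": MarkerParams(
            intercept=98.0,
            offsets={"HC": 0.0, "PreHD": -4.0, "HD": -22.0},
            slopes={"HC": -0.15, "PreHD": -1.0, "HD": -2.2},
            sigma_center=2.0,
            sigma_subject=15.0,
            sigma_resid=10.0,
        ),
    }


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Three-study multicenter configuration with published-style demographics.

    Study sizes and per-group demographic means/SDs follow the baseline
    demographic tables of the three large HD observational cohorts
    (PREDICT-like 20 centers / 265 participants, TRACK-like 4 / 294,
    IMAGE-like 1 / 65); HC CAG is truncated below 36.
    """
    studies = [
        StudyDesign(
            study_id="PREDICT",
            n_centers=20,
            group_sizes={"HC": 56, "PreHD": 205, "HD": 4},
            age={"HC": (45.1, 12.1), "PreHD": (41.8, 10.8), "HD": (46.8, 10.7)},
            sex_male={"HC": 36 / 56, "PreHD": 129 / 205, "HD": 3 / 4},
            cag={"HC": (20.3, 3.3), "PreHD": (42.3, 2.6), "HD": (43.0, 4.2)},
        ),
        StudyDesign(
            study_id="TRACK",
            n_centers=4,
            group_sizes={"HC": 106, "PreHD": 105, "HD": 83},
            age={"HC": (46.3, 10.2), "PreHD": (41.1, 8.8), "HD": (49.1, 9.5)},
            sex_male={"HC": 61 / 106, "PreHD": 56 / 105, "HD": 44 / 83},
            cag={"HC": (20.3, 3.3), "PreHD": (43.0, 2.3), "HD": (43.6, 3.1)},
        ),
        StudyDesign(
            study_id="IMAGE",
            n_centers=1,
            group_sizes={"HC": 23, "PreHD": 22, "HD": 20},
            age={"HC": (44.4, 13.9), "PreHD": (43.4, 8.3), "HD": (53.4, 8.8)},
            sex_male={"HC": 16 / 23, "PreHD": 16 / 22, "HD": 7 / 20},
            cag={"HC": (20.3, 3.3), "PreHD": (42.0, 2.0), "HD": (42.9, 2.4)},
        ),
    ]
    return CohortConfig(
        studies=studies,
        regions=_default_regions(),
        markers=_default_markers(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def _draw_cag(rng: np.random.Generator, group: str, mean: float, sd: float, n: int):
    vals = rng.normal(mean, sd, size=n)
    if group == "HC":
        # rejection sampling below the pathogenic cutoff
        for _ in range(1000):
            bad = vals >= 36.0
            if not bad.any():
                break
            vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        vals = np.minimum(vals, 35.9)
    return np.round(np.clip(vals, 9.0, None), 0)


def generate_cohort(config: CohortConfig, seed: int | None = None) -> Cohort:
    """Generate a multicenter longitudinal cohort table.

    Each region volume is built as::

        baseline_mean + b_age (age - 45) + b_sex (sex - 0.5) + b_tiv (TIV - 1.39)
        + group offset + [group slope + b_ta (age - 45)] t
        + scanner offset + u_center + u_subject + eps

    with ``u_center ~ N(0, sigma_center^2)``, ``u_subject ~ N(0,
    sigma_subject^2)`` and ``eps ~ N(0, sigma_resid^2)`` i.i.d. per visit.
    Deterministic given ``seed`` (falls back to ``config.seed``).
    """
    config.validate()
    master = config.seed if seed is None else int(seed)
    times = np.asarray(config.visit_times, dtype=float)
    n_visits = times.size

    rows = []
    region_names = list(config.regions)
    marker_names = list(config.markers)

    # per-(scanner, outcome) additive offsets, drawn once
    scanner_rng = rng_for(master, "scanner-offsets")
    scanner_offsets: dict = {}

    for st in config.studies:
        centers = [f"{st.study_id}_c{j + 1:02d}" for j in range(st.n_centers)]
        scanners = {c: f"{c}_scanner" for c in centers}
        for c in centers:
            offs = {}
            for r, p in config.regions.items():
                offs[r] = scanner_rng.normal(
                    0.0, config.scanner_effect_scale * p.sigma_resid
                )
            for m, p in config.markers.items():
                offs[m] = scanner_rng.normal(
                    0.0, config.scanner_effect_scale * p.sigma_resid
                )
            scanner_offsets[scanners[c]] = offs

        # nested random intercepts per center, per outcome
        center_rng = rng_for(master, st.study_id, "centers")
        u_center = {
            c: {
                name: center_rng.normal(0.0, p.sigma_center)
                for name, p in {**config.regions, **config.markers}.items()
            }
            for c in centers
        }

        pid_counter = 0
        for group in GROUPS:
            n_g = int(st.group_sizes.get(group, 0))
            if n_g == 0:
                continue
            grng = rng_for(master, st.study_id, group)
            age_mean, age_sd = st.age[group]
            cag_mean, cag_sd = st.cag[group]
            ages = grng.normal(age_mean, age_sd, size=n_g)
            sexes = (grng.random(n_g) < st.sex_male[group]).astype(int)
            tivs = grng.normal(config.tiv_mean, config.tiv_sd, size=n_g)
            cags = _draw_cag(grng, group, cag_mean, cag_sd, n_g)
            # deal participants to centers round-robin
            center_of = [centers[k % st.n_centers] for k in range(n_g)]
            for k in range(n_g):
                pid_counter += 1
                pid = f"{st.study_id}_p{pid_counter:04d}"
                center = center_of[k]
                scanner = scanners[center]
                age, sex, tiv, cag = ages[k], sexes[k], tivs[k], cags[k]
                u_subj = {
                    name: grng.normal(0.0, p.sigma_subject)
                    for name, p in {**config.regions, **config.markers}.items()
                }
                eps = {
                    name: grng.normal(0.0, p.sigma_resid, size=n_visits)
                    for name, p in {**config.regions, **config.markers}.items()
                }
                for v, t in enumerate(times):
                    rec = {
                        "study": st.study_id,
                        "center": center,
                        "participant": pid,
                        "visit": v,
                        "time": float(t),
                        "age": float(age),
                        "sex": int(sex),
                        "tiv": float(tiv),
                        "group": group,
                        "scanner": scanner,
                        "cag": float(cag),
                    }
                    for r, p in config.regions.items():
                        slope = p.slopes.get(group, 0.0) + p.coef_time_age * (
                            age - REF_AGE
                        )
                        rec[r] = (
                            p.baseline_mean
                            + p.coef_age * (age - REF_AGE)
                            + p.coef_sex * (sex - REF_SEX)
                            + p.coef_tiv * (tiv - REF_TIV)
                            + p.offsets.get(group, 0.0)
                            + slope * t
                            + scanner_offsets[scanner][r]
                            + u_center[center][r]
                            + u_subj[r]
                            + eps[r][v]
                        )
                    for m, p in config.markers.items():
                        rec[m] = (
                            p.intercept
                            + p.offsets.get(group, 0.0)
                            + p.slopes.get(group, 0.0) * t
                            + scanner_offsets[scanner][m]
                            + u_center[center][m]
                            + u_subj[m]
                            + eps[m][v]
                        )
                    rows.append(rec)

    data = pd.DataFrame(rows, columns=list(BASE_COLUMNS) + region_names + marker_names)
    return Cohort(data=data, regions=region_names, markers=marker_names)


# ---------------------------------------------------------------------------
# CSV I/O (long format, fixed leading columns, outcomes after `cag`)
# ---------------------------------------------------------------------------

KNOWN_MARKERS = ("tms", "sdmt", "swrt")


def write_cohort_csv(cohort: Cohort, path) -> None:
    cols = list(BASE_COLUMNS) + cohort.regions + cohort.markers
    cohort.data[cols].to_csv(path, index=False)


def read_cohort_csv(path, markers: Sequence[str] = KNOWN_MARKERS) -> Cohort:
    """Read a cohort CSV; outcome columns after ``cag`` are split into
    regions and clinical markers (any column named in ``markers``)."""
    data = pd.read_csv(path)
    missing = [c for c in BASE_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"cohort CSV missing required column(s): {missing}")
    extra = [c for c in data.columns if c not in BASE_COLUMNS]
    marker_cols = [c for c in extra if c in set(markers)]
    region_cols = [c for c in extra if c not in set(markers)]
    return Cohort(data=data, regions=region_cols, markers=marker_cols)
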
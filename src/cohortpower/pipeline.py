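"""End-to-end orchestration: generate/load -> fit -> effect sizes -> power.

A :class:`RunConfig` (YAML/JSON) names either a cohort CSV or an inline
generator configuration, the regions and markers to analyze, effect-size
settings, and power-grid settings.  :func:`run_pipeline` executes every
stage per region with per-stage structured logging, isolates per-region
failures, and writes a deterministic report bundle (CSV/JSON, floats
rounded to 6 significant digits) keyed by a master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._random import rng_for
from .cohort import (
    Cohort,
    CohortConfig,
    default_cohort_config,
    generate_cohort,
    read_cohort_csv,
    write_cohort_csv,
)
from .effects import (
    EffectSizeResult,
    EffectSizeStatistic,
    bootstrap_ci,
    effect_size_table,
    normalize_effect_map,
    select_regions,
    weighted_mean_effect,
)
from .lmm import (
    ModelSpec,
    adjust_baseline,
    extract_hyperparameters,
    fit_lmm,
    test_study_group_interaction,
)
from .power import power_curve, power_curve_table, sample_size_threshold

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "load_cohort_csv", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    output_dir: str
    input_csv: str | None = None
    generator: CohortConfig | None = None
    regions: list | None = None  # None -> all regions in the cohort
    markers: list = field(default_factory=list)
    n_boot: int = 2000
    ci_level: float = 0.95
    selection_threshold: float = 0.5
    deltas: tuple = (0.2, 0.4)
    power_modes: tuple = ("vary_centers", "vary_per_center")
    power_grids: dict = field(default_factory=dict)  # mode -> [(nc, npc), ...]
    alpha: float = 0.05
    n_sim: int = 1000
    tau_fraction: float = 0.25  # tau = tau_fraction * delta
    n_cap: int = 2000
    power_outcomes: list | None = None  # None -> selected regions + markers
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self):
        if (self.input_csv is None) == (self.generator is None):
            raise ValueError(
                "exactly one of input_csv / generator must be provided"
            )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        )
        if data.get("generator") is not None:
            data["generator"] = CohortConfig.from_dict(data["generator"])
        for key in ("deltas", "power_modes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["deltas"] = list(self.deltas)
        d["power_modes"] = list(self.power_modes)
        return d


@dataclass
class RunReport:
    output_dir: Path
    effect_sizes: pd.DataFrame
    selection: dict
    normalized: dict
    thresholds: list
    power_curves: pd.DataFrame
    models: dict
    errors: dict

    @property
    def ok(self) -> bool:
        return not self.errors


def load_cohort_csv(path) -> Cohort:
    """Read and validate a cohort CSV.

    Participants without a complete set of visits (one record per distinct
    visit time, 3 by default in generated cohorts) are excluded with a log
    entry, mirroring the complete-case inclusion rule; a scanner change
    within a participant is an error reported with row numbers.
    """
    cohort = read_cohort_csv(path)
    data = cohort.data
    if data.empty:
        raise ValueError(f"cohort CSV {path} contains no records")

    n_visits = data["visit"].nunique()
    counts = data.groupby("participant")["visit"].nunique()
    bad = counts[counts < n_visits].index
    if len(bad):
        logger.info(
            "load_cohort_csv: excluded %d participant(s) without all %d visits: %s",
            len(bad), n_visits, list(bad)[:10],
        )
        data = data[~data["participant"].isin(bad)]
    scanners = data.groupby("participant")["scanner"].nunique()
    changed = scanners[scanners > 1].index
    if len(changed):
        rows = data.index[data["participant"].isin(changed)].tolist()
        raise ValueError(
            f"scanner changes within participant(s) {list(changed)[:5]} "
            f"(rows {rows[:10]})"
        )
    vol_cols = cohort.regions
    nonpos = (data[vol_cols] <= 0).any(axis=1)
    if nonpos.any():
        raise ValueError(
            f"non-positive region volume(s) at rows {data.index[nonpos].tolist()[:10]}"
        )
    return Cohort(data=data.reset_index(drop=True), regions=cohort.regions,
                  markers=cohort.markers)


def _round_sig(df: pd.DataFrame, digits: int = 6) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: float(f"{v:.{digits}g}") if pd.notna(v) else v)
    return out

def _volume_spec(response: str, study_df: pd.DataFrame) -> ModelSpec:
    terms = ["intercept", "time", "age", "sex", "tiv", "group", "time:age"]
    if study_df["scanner"].nunique() > 1:
        terms.append("scanner")
    return ModelSpec(response=response, fixed_terms=tuple(terms))


def _progression_spec(response: str, table: pd.DataFrame, marker: bool) -> ModelSpec:
    terms = (
        ["intercept", "time", "age", "sex", "group"]
        if marker
        else ["intercept", "time", "age", "sex", "tiv", "group", "time:age"]
    )
    if table["scanner"].nunique() > 1:
        terms.append("scanner")
    return ModelSpec(response=response, fixed_terms=tuple(terms))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages and write the report bundle to ``output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir / "run.log", config.verbosity)

    # 1. cohort
    if config.input_csv is not None:
        cohort = load_cohort_csv(config.input_csv)
    else:
        cohort = generate_cohort(config.generator, seed=config.seed)
        write_cohort_csv(
            Cohort(_round_sig(cohort.data), cohort.regions, cohort.markers),
            outdir / "cohort.csv",
        )
    regions = config.regions or cohort.regions
    markers = config.markers or []
    studies = list(pd.unique(cohort.data["study"]))
    logger.info(
        "stage=cohort studies=%d centers=%d participants=%d regions=%d markers=%d",
        len(studies),
        cohort.data["center"].nunique(),
        cohort.data["participant"].nunique(),
        len(regions),
        len(markers),
    )

    errors: dict = {}
    models: dict = {}
    es_results: list = []
    statistic = EffectSizeStatistic()

    # 2. per-region, per-study fits and effect sizes
    for region in regions:
        try:
            per_study_t: dict = {}
            per_study_n: dict = {}
            for study in studies:
                sdf = cohort.data[cohort.data["study"] == study]
                spec = _volume_spec(region, sdf)
                fit = fit_lmm(sdf, spec)
                models[f"{region}:{study}"] = fit
                adj = adjust_baseline(fit, sdf, spec)
                hc = adj[adj["group"] == "HC"]
                pre = adj[adj["group"] == "PreHD"]
                t = statistic(adj)
                ci_lo, ci_hi = bootstrap_ci(
                    adj,
                    statistic,
                    n_boot=config.n_boot,
                    level=config.ci_level,
                    seed=int(
                        rng_for(config.seed, "bootstrap", region, study).integers(2**31)
                    ),
                )
                es_results.append(
                    EffectSizeResult(
                        region=region,
                        study_id=study,
                        t=t,
                        ci_low=ci_lo,
                        ci_high=ci_hi,
                        n_hc=len(hc),
                        n_prehd=len(pre),
                    )
                )
                per_study_t[study] = t
                per_study_n[study] = len(hc) + len(pre)
            logger.info("stage=effects region=%s studies=%d", region, len(studies))
        except Exception as exc:  # isolate per-region failures
            logger.exception("region %s failed", region)
            errors[region] = f"{type(exc).__name__}: {exc}"

    es_df = effect_size_table(es_results)

    # 3. cross-study summaries
    weighted: dict = {}
    for region in es_df["region"].unique():
        sub = es_df[es_df["region"] == region]
        weighted[region] = weighted_mean_effect(
            dict(zip(sub["study"], sub["t"])),
            dict(zip(sub["study"], sub["n_hc"] + sub["n_prehd"])),
        )
    selection = select_regions(weighted, config.selection_threshold) if weighted else None
    normalized = (
        normalize_effect_map(
            {f"{r.study_id}:{r.region}": r.t for r in es_results}
        )
        if es_results and any(r.t != 0 for r in es_results)
        else {}
    )
    if selection:
        logger.info(
            "stage=selection threshold=%.2f selected=%d",
            config.selection_threshold,
            len(selection.selected),
        )

    # 4. power over outcomes
    outcomes = (
        config.power_outcomes
        if config.power_outcomes is not None
        else (selection.selected if selection else []) + markers
    )
    thresholds: list = []
    curves: list = []
    for outcome in outcomes:
        try:
            is_marker = outcome in cohort.markers
            carriers = cohort.data[cohort.data["group"].isin(["PreHD", "HD"])]
            spec = _progression_spec(outcome, carriers, is_marker)
            fit = fit_lmm(carriers, spec)
            models[f"{outcome}:pooled"] = fit
            for delta in config.deltas:
                hyper = extract_hyperparameters(
                    fit, treated_fraction_sd=config.tau_fraction * delta
                )
                for mode in config.power_modes:
                    curve = power_curve(
                        mode,
                        hyper,
                        delta=delta,
                        alpha=config.alpha,
                        n_sim=config.n_sim,
                        seed=int(
                            rng_for(config.seed, "power", outcome, mode).integers(2**31)
                        ),
                        grid=config.power_grids.get(mode),
                        n_cap=config.n_cap,
                    )
                    curves.append((f"{outcome}|delta={delta}", curve))
                    thr = sample_size_threshold(curve)
                    thresholds.append(
                        {
                            "outcome": outcome,
                            "delta": delta,
                            "mode": mode,
                            "threshold_total_n": thr,
                        }
                    )
                    logger.info(
                        "stage=power outcome=%s delta=%.2f mode=%s n_sim=%d threshold=%s",
                        outcome, delta, mode, config.n_sim, thr,
                    )
        except Exception as exc:
            logger.exception("power stage for %s failed", outcome)
            errors[f"power:{outcome}"] = f"{type(exc).__name__}: {exc}"

    curve_df = power_curve_table(curves)

    # 5. write bundle
    _round_sig(es_df).to_csv(outdir / "effect_sizes.csv", index=False)
    if selection:
        (outdir / "selection.json").write_text(
            json.dumps(
                {
                    "threshold": selection.threshold,
                    "selected": selection.selected,
                    "weighted_t": {
                        k: float(f"{v:.6g}") for k, v in selection.weighted_t.items()
                    },
                },
                indent=2,
            )
        )
    (outdir / "normalized_effects.json").write_text(
        json.dumps({k: float(f"{v:.6g}") for k, v in normalized.items()}, indent=2)
    )
    if not curve_df.empty:
        _round_sig(curve_df).to_csv(outdir / "power_curves.csv", index=False)
    (outdir / "thresholds.json").write_text(json.dumps(thresholds, indent=2))
    models_json = {k: json.loads(m.to_json()) for k, m in models.items()}
    (outdir / "models.json").write_text(json.dumps(models_json, indent=2, sort_keys=True))
    (outdir / "config_resolved.json").write_text(
        json.dumps(_config_echo(config), indent=2, sort_keys=True, default=str)
    )
    if errors:
        (outdir / "errors.json").write_text(json.dumps(errors, indent=2))

    return RunReport(
        output_dir=outdir,
        effect_sizes=es_df,
        selection={
            "threshold": selection.threshold if selection else None,
            "selected": selection.selected if selection else [],
            "weighted_t": selection.weighted_t if selection else {},
        },
        normalized=normalized,
        thresholds=thresholds,
        power_curves=curve_df,
        models=models,
        errors=errors,
    )


def _config_echo(config: RunConfig) -> dict:
    d = config.to_dict()
    return d


def _setup_logging(logfile: Path, level: str) -> None:
    root = logging.getLogger("cohortpower")
    root.setLevel(getattr(logging, level.upper(), logging.INFO))
    for h in list(root.handlers):
        if isinstance(h, logging.FileHandler):
            root.removeHandler(h)
            h.close()
    fh = logging.FileHandler(logfile, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root.addHandler(fh)
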
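"""Simulation-based power analysis for multicenter longitudinal trials.

Trials are simulated from :class:`~cohortpower.lmm.TrialHyperparameters`:
participants nested in centers, three visits by default, and a treatment
that slows the placebo atrophy slope by a center-specific fraction

    delta_c ~ Normal(delta, tau^2) truncated to [0, 1],

so ``tau > 0`` induces between-center treatment-effect heterogeneity.  Each
simulated trial is refitted with the nested random-intercept mixed model
(fixed terms intercept, time, arm, arm x time) and the treatment effect is
judged by the two-sided Wald t test on the arm x time coefficient, using
between-within degrees of freedom.  Power is the rejection fraction over
Monte-Carlo replicates; design grids (varying centers at fixed per-center
size, or vice versa) yield power curves with an isotonic-smoothed copy used
for the power > 80% sample-size threshold search.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from ._random import rng_for
from .lmm import ModelSpec, NestedLMM, TrialHyperparameters, build_design

logger = logging.getLogger(__name__)

__all__ = [
    "TrialDesign",
    "PowerEstimate",
    "PowerCurve",
    "simulate_trial",
    "test_treatment",
    "estimate_power",
    "power_curve",
    "sample_size_threshold",
    "power_curve_table",
    "DEFAULT_N_CAP",
]

DEFAULT_N_CAP = 2000
TRIAL_TERMS = ("intercept", "time", "arm", "arm:time")


@dataclass
class TrialDesign:
    """Geometry and analysis settings of one simulated trial design."""

    n_centers: int
    n_per_center: int
    outcome: str = "volume"
    delta: float = 0.2  # fractional slowing of the placebo slope
    allocation: float = 0.5
    visit_times: tuple = (0.0, 1.0, 2.0)
    alpha: float = 0.05
    n_sim: int = 1000

    def __post_init__(self):
        if self.n_centers < 2 or self.n_per_center < 2:
            raise ValueError("need n_centers >= 2 and n_per_center >= 2")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.allocation < 1.0:
            raise ValueError("allocation must be in (0, 1)")
        if len(self.visit_times) < 2:
            raise ValueError("need at least two visits")

    @property
    def total_n(self) -> int:
        return self.n_centers * self.n_per_center


@dataclass
class PowerEstimate:
    n_centers: int
    n_per_center: int
    total_n: int
    power: float
    mc_se: float
    n_sim: int
    converged_fraction: float = 1.0
    flagged: bool = False


@dataclass
class PowerCurve:
    mode: str  # "vary_centers" | "vary_per_center"
    grid: list  # PowerEstimates ordered by total_n
    smoothed: np.ndarray = field(default=None, repr=False)
    n_cap: int = DEFAULT_N_CAP

    @property
    def totals(self) -> np.ndarray:
        return np.array([g.total_n for g in self.grid])

    @property
    def raw_powers(self) -> np.ndarray:
        return np.array([g.power for g in self.grid])


# ---------------------------------------------------------------------------


def _draw_center_effect_fraction(
    rng: np.random.Generator, delta: float, tau: float, n_centers: int
) -> np.ndarray:
    if tau == 0.0:
        return np.full(n_centers, delta)
    a, b = (0.0 - delta) / tau, (1.0 - delta) / tau
    return stats.truncnorm.rvs(
        a, b, loc=delta, scale=tau, size=n_centers, random_state=rng
    )


def simulate_trial(
    design: TrialDesign, hyper: TrialHyperparameters, seed: int = 0
) -> pd.DataFrame:
    """Simulate one multicenter trial; returns a long-format frame.

    Columns: center, participant, arm (0 control / 1 treated), time, visit,
    y.  Treated participants progress at ``placebo_slope * (1 - delta_c)``
    with ``delta_c`` the center's treatment-effect fraction.  Allocation is
    randomized within center at the design fraction.
    """
    rng = rng_for(seed, "trial")
    return _arrays_to_frame(design, *_simulate_arrays(design, hyper, rng))


def _simulate_arrays(
    design: TrialDesign, hyper: TrialHyperparameters, rng: np.random.Generator
):
    """Draw one trial as flat arrays (center code, arm, y) in row order
    center-major, participant-major, visit-minor."""
    nc, npc = design.n_centers, design.n_per_center
    times = np.asarray(design.visit_times, dtype=float)
    nv = times.size
    n = nc * npc

    if hyper.tau_treatment > 0 and nc < 2:
        warnings.warn(
            "tau_treatment > 0 with a single center: treatment-effect "
            "variance is inestimable",
            stacklevel=2,
        )

    delta_c = _draw_center_effect_fraction(
        rng, design.delta, hyper.tau_treatment, nc
    )
    u_c = rng.normal(0.0, np.sqrt(hyper.sigma2_center), size=nc)
    u_i = rng.normal(0.0, np.sqrt(hyper.sigma2_subject), size=n)

    # randomized allocation within center at the stated fraction
    n_treat = int(round(design.allocation * npc))
    arm = np.empty(n, dtype=int)
    base = np.zeros(npc, dtype=int)
    base[:n_treat] = 1
    for c in range(nc):
        a = base.copy()
        rng.shuffle(a)
        arm[c * npc : (c + 1) * npc] = a

    center_of = np.repeat(np.arange(nc), npc)
    slope = np.where(
        arm == 1,
        hyper.placebo_slope * (1.0 - delta_c[center_of]),
        hyper.placebo_slope,
    )
    eps = rng.normal(0.0, np.sqrt(hyper.sigma2_resid), size=(n, nv))
    y = (
        hyper.baseline_mean
        + u_c[center_of][:, None]
        + u_i[:, None]
        + slope[:, None] * times[None, :]
        + eps
    )
    return center_of, arm, y.ravel()


def _arrays_to_frame(design: TrialDesign, center_of, arm, y) -> pd.DataFrame:
    nc, npc = design.n_centers, design.n_per_center
    times = np.asarray(design.visit_times, dtype=float)
    nv = times.size
    n = nc * npc
    return pd.DataFrame(
        {
            "center": np.repeat([f"c{c + 1:03d}" for c in range(nc)], npc * nv),
            "participant": np.repeat([f"p{i + 1:05d}" for i in range(n)], nv),
            "arm": np.repeat(arm, nv),
            "time": np.tile(times, n),
            "visit": np.tile(np.arange(nv), n),
            "y": y,
        }
    )


def test_treatment(dataset: pd.DataFrame, df_method: str = "between_within"):
    """Two-sided Wald p-value for the arm-by-time coefficient.

    Fits the nested random-intercept model with fixed terms intercept, time,
    arm and arm:time.  Returns ``(p_value, converged)``; a non-converged fit
    yields ``(nan, False)``.
    """
    if dataset["arm"].nunique() < 2:
        raise ValueError("both trial arms must be present")
    spec = ModelSpec(
        response="y", fixed_terms=TRIAL_TERMS, df_method=df_method
    )
    X, names, _ = build_design(dataset, spec)
    model = NestedLMM(
        X,
        dataset["y"].to_numpy(float),
        centers=dataset["center"].to_numpy(),
        participants=dataset["participant"].to_numpy(),
        column_names=names,
    )
    fit = model.fit()
    if not fit.converged:
        return float("nan"), False
    if df_method == "between_within":
        from .lmm import _between_within_df

        fit.df_by_column = _between_within_df(
            X, names, dataset["participant"].to_numpy()
        )
    return float(fit.pvalues["arm:time"]), True


def estimate_power(
    design: TrialDesign,
    hyper: TrialHyperparameters,
    seed: int = 0,
    grid_tag: int = 0,
) -> PowerEstimate:
    """Monte-Carlo power at one design point.

    Power is the fraction of converged simulated trials with p < alpha; the
    result is flagged when more than 10% of fits fail to converge.
    Replicate r draws from a generator keyed by (seed, grid_tag, r), so the
    same replicate sees the same noise across treatment-effect settings
    (common random numbers).
    """
    if design.n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    nc, npc = design.n_centers, design.n_per_center
    times = np.asarray(design.visit_times, dtype=float)
    nv = times.size
    n = nc * npc
    n_obs = n * nv
    center_codes = np.repeat(np.arange(nc), npc * nv)
    part_codes = np.repeat(np.arange(n), nv)
    time_col = np.tile(times, n)
    ones = np.ones(n_obs)
    # between-within df: time and arm:time vary within participants,
    # intercept and arm do not
    df_within = float(max(n_obs - n - 2, 1))
    names = ["intercept", "time", "arm", "arm:time"]

    n_reject = 0
    n_ok = 0
    for r in range(design.n_sim):
        rng = rng_for(seed, "power", grid_tag, r)
        center_of, arm, y = _simulate_arrays(design, hyper, rng)
        arm_col = np.repeat(arm, nv).astype(float)
        X = np.column_stack((ones, time_col, arm_col, arm_col * time_col))
        model = NestedLMM(
            X, y, center_codes, part_codes, column_names=names
        )
        fit = model.fit()
        if fit.converged:
            n_ok += 1
            t_stat = fit.params["arm:time"] / fit.bse["arm:time"]
            p = float(2.0 * stats.t.sf(abs(t_stat), df_within))
            if p < design.alpha:
                n_reject += 1
    if n_ok == 0:
        raise RuntimeError("no simulated trial converged")
    power = n_reject / n_ok
    frac = n_ok / design.n_sim
    flagged = frac < 0.9
    if flagged:
        logger.warning(
            "power estimate flagged: only %.0f%% of fits converged", 100 * frac
        )
    return PowerEstimate(
        n_centers=design.n_centers,
        n_per_center=design.n_per_center,
        total_n=design.total_n,
        power=power,
        mc_se=float(np.sqrt(power * (1.0 - power) / n_ok)),
        n_sim=design.n_sim,
        converged_fraction=frac,
        flagged=flagged,
    )


def _default_grid(mode: str):
    if mode == "vary_centers":
        return [(nc, 20) for nc in range(6, 101, 2)]
    if mode == "vary_per_center":
        return [(4, npc) for npc in range(30, 501, 10)]
    raise ValueError("mode must be 'vary_centers' or 'vary_per_center'")


def power_curve(
    mode: str,
    hyper: TrialHyperparameters,
    delta: float = 0.2,
    alpha: float = 0.05,
    n_sim: int = 1000,
    seed: int = 0,
    grid=None,
    n_cap: int = DEFAULT_N_CAP,
    visit_times=(0.0, 1.0, 2.0),
) -> PowerCurve:
    """Power over a design grid, with an isotonic-smoothed copy.

    ``grid`` is a list of (n_centers, n_per_center) pairs; the default grids
    vary centers in {6..100} step 2 at 20 participants per center, or
    participants per center in {30..500} step 10 at 4 centers.  Points whose
    total exceeds ``n_cap`` (default 2,000) are dropped with a warning.  The
    smoothed curve is the isotonic regression of raw power on total n and is
    what the threshold search uses; raw estimates are always retained.
    """
    pairs = list(grid) if grid is not None else _default_grid(mode)
    if not pairs:
        raise ValueError("empty design grid")
    kept = [(nc, npc) for nc, npc in pairs if nc * npc <= n_cap]
    if len(kept) < len(pairs):
        warnings.warn(
            f"{len(pairs) - len(kept)} grid point(s) beyond the cap of "
            f"{n_cap} participants were dropped",
            stacklevel=2,
        )
    kept.sort(key=lambda t: t[0] * t[1])
    totals = [nc * npc for nc, npc in kept]
    if len(set(totals)) != len(totals):
        raise ValueError("grid totals must be strictly increasing")

    estimates = []
    for gi, (nc, npc) in enumerate(kept):
        design = TrialDesign(
            n_centers=nc,
            n_per_center=npc,
            delta=delta,
            alpha=alpha,
            n_sim=n_sim,
            visit_times=tuple(visit_times),
        )
        estimates.append(
            estimate_power(design, hyper, seed=seed, grid_tag=_grid_tag(mode, nc, npc))
        )
        logger.info(
            "power grid [%s] Nc=%d Nppc=%d total=%d power=%.3f",
            mode, nc, npc, nc * npc, estimates[-1].power,
        )

    raw = np.array([e.power for e in estimates])
    tot = np.array([e.total_n for e in estimates], dtype=float)
    if raw.size > 1:
        smoothed = IsotonicRegression(increasing=True).fit_transform(tot, raw)
    else:
        smoothed = raw.copy()
    return PowerCurve(mode=mode, grid=estimates, smoothed=smoothed, n_cap=n_cap)


def _grid_tag(mode: str, nc: int, npc: int) -> int:
    # stable per-grid-point tag independent of delta/tau so that common
    # random numbers couple curves across treatment-effect settings
    return (nc << 16) | npc


def sample_size_threshold(curve: PowerCurve, target: float = 0.8):
    """Smallest grid total n whose smoothed power exceeds ``target``.

    Returns ``None`` when the target is never exceeded within the cap
    (reported as a dash in the published threshold tables).
    """
    for total, sm in zip(curve.totals, curve.smoothed):
        if sm > target:
            return int(total)
    return None


def power_curve_table(curves) -> pd.DataFrame:
    """CSV-ready frame for a list of (label, PowerCurve) pairs."""
    rows = []
    for label, curve in curves:
        for est, sm in zip(curve.grid, curve.smoothed):
            rows.append(
                {
                    "outcome": label,
                    "mode": curve.mode,
                    "n_centers": est.n_centers,
                    "n_per_center": est.n_per_center,
                    "total_n": est.total_n,
                    "power": est.power,
                    "power_smoothed": float(sm),
                    "mc_se": est.mc_se,
                    "n_sim": est.n_sim,
                    "converged_fraction": est.converged_fraction,
                }
            )
    return pd.DataFrame(rows)
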
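"""Standardized effect sizes between control and premanifest groups.

The effect size for a region in one study is the difference of the
covariate-adjusted baseline group means divided by the residual standard
deviation in the PreHD group,

    t = (mean_HC - mean_PreHD) / sd_resid(PreHD),

so atrophied regions come out positive and enlarging compartments (CSF)
negative.  Confidence intervals come from a stratified participant-level
percentile bootstrap; cross-study summaries use participant-count weights,
a strict |t| > 0.5 selection rule, and max-|t| normalization for effect
maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._random import rng_for

logger = logging.getLogger(__name__)

__all__ = [
    "EffectSizeResult",
    "RegionSelection",
    "standardized_effect_size",
    "EffectSizeStatistic",
    "bootstrap_ci",
    "effect_size_difference_test",
    "weighted_mean_effect",
    "select_regions",
    "normalize_effect_map",
    "effect_size_table",
]


@dataclass
class EffectSizeResult:
    region: str
    study_id: str
    t: float
    ci_low: float
    ci_high: float
    n_hc: int
    n_prehd: int


@dataclass
class RegionSelection:
    weighted_t: dict
    threshold: float
    selected: list


def standardized_effect_size(hc_values, prehd_values, prehd_resid_sd: float) -> float:
    """(mean(HC) - mean(PreHD)) / residual SD in the PreHD group."""
    hc = np.asarray(hc_values, dtype=float)
    pre = np.asarray(prehd_values, dtype=float)
    if hc.size == 0 or pre.size == 0:
        raise ValueError("both groups must be non-empty")
    if prehd_resid_sd <= 0:
        raise ValueError("PreHD residual SD must be positive")
    return float((hc.mean() - pre.mean()) / prehd_resid_sd)


class EffectSizeStatistic:
    """Effect-size functional on per-participant adjusted data.

    Operates on a frame with columns ``group``, ``adjusted_baseline`` and
    ``residual``.  ``sd_source`` selects the denominator: ``"conditional"``
    (default) uses the SD of the PreHD conditional residuals,
    ``"marginal"`` the SD of the PreHD adjusted baselines themselves.
    """

    def __init__(self, sd_source: str = "conditional"):
        if sd_source not in ("conditional", "marginal"):
            raise ValueError("sd_source must be 'conditional' or 'marginal'")
        self.sd_source = sd_source

    def _sd(self, pre_adj: np.ndarray, pre_resid: np.ndarray) -> float:
        vals = pre_resid if self.sd_source == "conditional" else pre_adj
        return float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0

    def from_arrays(self, hc_adj, pre_adj, pre_resid) -> float:
        sd = self._sd(np.asarray(pre_adj), np.asarray(pre_resid))
        return standardized_effect_size(hc_adj, pre_adj, sd)

    def __call__(self, data: pd.DataFrame) -> float:
        hc = data[data["group"] == "HC"]
        pre = data[data["group"] == "PreHD"]
        return self.from_arrays(
            hc["adjusted_baseline"].to_numpy(float),
            pre["adjusted_baseline"].to_numpy(float),
            pre["residual"].to_numpy(float),
        )


def bootstrap_ci(
    data: pd.DataFrame,
    statistic,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    max_redraws: int = 100,
):
    """Stratified percentile bootstrap CI over participants.

    HC and PreHD participants are resampled with replacement separately,
    preserving group sizes.  A degenerate resample (zero PreHD residual SD)
    is redrawn, with the count logged.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = rng_for(seed, "bootstrap")
    alpha = 1.0 - level

    if isinstance(statistic, EffectSizeStatistic):
        stats_arr = _fast_effect_size_bootstrap(data, statistic, n_boot, rng)
    else:
        groups = {g: data[data["group"] == g] for g in pd.unique(data["group"])}
        stats_arr = np.empty(n_boot)
        redraws = 0
        for b in range(n_boot):
            for _ in range(max_redraws + 1):
                parts = [
                    g.iloc[rng.integers(0, len(g), size=len(g))]
                    for g in groups.values()
                ]
                sample = pd.concat(parts, ignore_index=True)
                try:
                    stats_arr[b] = statistic(sample)
                    break
                except ValueError:
                    redraws += 1
            else:
                raise RuntimeError("bootstrap: too many degenerate resamples")
        if redraws:
            logger.info("bootstrap: %d degenerate resample(s) redrawn", redraws)
    lo, hi = np.quantile(stats_arr, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def _fast_effect_size_bootstrap(
    data: pd.DataFrame, statistic: EffectSizeStatistic, n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized stratified bootstrap of the default effect-size statistic."""
    hc = data.loc[data["group"] == "HC", "adjusted_baseline"].to_numpy(float)
    pre_df = data[data["group"] == "PreHD"]
    pre_adj = pre_df["adjusted_baseline"].to_numpy(float)
    pre_res = pre_df["residual"].to_numpy(float)
    n_h, n_p = hc.size, pre_adj.size
    if n_h < 1 or n_p < 2:
        raise ValueError("need >=1 HC and >=2 PreHD participants")

    if np.ptp(pre_adj) == 0 and np.ptp(pre_res) == 0 and np.ptp(hc) == 0:
        # fully degenerate data: zero-width interval at the point estimate
        point = statistic(data)
        return np.full(n_boot, point)

    out = np.empty(n_boot)
    filled = 0
    redraws = 0
    while filled < n_boot:
        todo = n_boot - filled
        ih = rng.integers(0, n_h, size=(todo, n_h))
        ip = rng.integers(0, n_p, size=(todo, n_p))
        hc_mean = hc[ih].mean(axis=1)
        pre_mean = pre_adj[ip].mean(axis=1)
        sd_vals = pre_res[ip] if statistic.sd_source == "conditional" else pre_adj[ip]
        sd = sd_vals.std(axis=1, ddof=1)
        good = sd > 0
        n_good = int(good.sum())
        out[filled : filled + n_good] = (
            (hc_mean[good] - pre_mean[good]) / sd[good]
        )
        redraws += todo - n_good
        filled += n_good
        if redraws > 100 * n_boot:
            raise RuntimeError("bootstrap: too many degenerate resamples")
    if redraws:
        logger.info("bootstrap: %d degenerate resample(s) redrawn", redraws)
    return out


def effect_size_difference_test(
    data_a: pd.DataFrame,
    data_b: pd.DataFrame,
    statistic=None,
    n_boot: int = 2000,
    seed: int = 0,
) -> float:
    """Bootstrap test that two studies' effect sizes differ.

    Resamples each study independently (stratified by group), forms the
    bootstrap distribution of t_a - t_b, and returns the two-sided p-value
    ``2 min(P(diff < 0), P(diff > 0))`` (unadjusted).
    """
    statistic = statistic or EffectSizeStatistic()
    rng_a = rng_for(seed, "es-diff-a")
    rng_b = rng_for(seed, "es-diff-b")
    sa = _fast_effect_size_bootstrap(data_a, statistic, n_boot, rng_a)
    sb = _fast_effect_size_bootstrap(data_b, statistic, n_boot, rng_b)
    diff = sa - sb
    p_lo = float(np.mean(diff < 0.0))
    p_hi = float(np.mean(diff > 0.0))
    return min(1.0, 2.0 * min(p_lo, p_hi) + 2.0 * np.mean(diff == 0.0))


def weighted_mean_effect(per_study_t: dict, per_study_n: dict) -> float:
    """Participant-count-weighted mean of per-study effect sizes."""
    if set(per_study_t) != set(per_study_n):
        raise ValueError("per_study_t and per_study_n must share keys")
    if not per_study_t:
        raise ValueError("empty input")
    if any(n <= 0 for n in per_study_n.values()):
        raise ValueError("all weights must be positive")
    num = sum(per_study_n[s] * per_study_t[s] for s in per_study_t)
    den = sum(per_study_n.values())
    return float(num / den)


def select_regions(weighted_t: dict, threshold: float = 0.5) -> RegionSelection:
    """Regions with |weighted t| strictly above threshold, descending |t|.

    Ties in |t| are broken lexicographically by region name.
    """
    if not weighted_t:
        raise ValueError("empty effect-size map")
    selected = sorted(
        (r for r, t in weighted_t.items() if abs(t) > threshold),
        key=lambda r: (-abs(weighted_t[r]), r),
    )
    return RegionSelection(
        weighted_t=dict(weighted_t), threshold=threshold, selected=selected
    )


def normalize_effect_map(t_by_study_region: dict) -> dict:
    """Divide every entry by the maximum |t| across all studies and regions."""
    if not t_by_study_region:
        raise ValueError("empty effect map")
    max_abs = max(abs(v) for v in t_by_study_region.values())
    if max_abs == 0:
        raise ValueError("all effect sizes are zero; cannot normalize")
    return {k: v / max_abs for k, v in t_by_study_region.items()}


def effect_size_table(results) -> pd.DataFrame:
    """Tidy CSV-ready frame from an iterable of :class:`EffectSizeResult`."""
    return pd.DataFrame(
        [
            {
                "region": r.region,
                "study": r.study_id,
                "t": r.t,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_hc": r.n_hc,
                "n_prehd": r.n_prehd,
            }
            for r in results
        ]
    )
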
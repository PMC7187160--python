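"""Nested random-intercept linear mixed models fitted by REML.

The model for outcome :math:`y_{cit}` of participant *i* in center *c* is

.. math::

    y_{cit} = x_{cit}' \\beta + u_c + u_{i(c)} + \\varepsilon_{cit},

with independent Gaussian random intercepts :math:`u_c \\sim N(0,
\\sigma^2_{center})`, :math:`u_{i(c)} \\sim N(0, \\sigma^2_{subject})` and
residuals :math:`\\varepsilon \\sim N(0, \\sigma^2_{resid})`.  The residual
variance is profiled out of the REML criterion and the two variance ratios
:math:`\\gamma = \\sigma^2 / \\sigma^2_{resid}` are optimized on the log
scale, with the three boundary sub-models (either or both ratios at zero)
fitted explicitly so boundary estimates are exact zeros rather than tiny
positives.  The nested structure makes every per-center covariance block
invertible in closed form (Sherman-Morrison within participants, then
within centers), so each criterion evaluation is a handful of dense
matrix products — cheap enough to refit thousands of simulated trials.

Wald inference uses t statistics with either residual degrees of freedom
(``n_obs - rank(X)``, the default) or a between-within partition that gives
within-participant contrasts (time, treatment-by-time) the degrees of
freedom of the participant-level slope analysis.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "NestedLMM",
    "NestedLMMResult",
    "TrialHyperparameters",
    "RankDeficientError",
    "fit_lmm",
    "adjust_baseline",
    "test_study_group_interaction",
    "extract_hyperparameters",
]


class RankDeficientError(ValueError):
    """Fixed-effect design is rank deficient; message names collinear columns."""


# ---------------------------------------------------------------------------
# model specification & design matrices
# ---------------------------------------------------------------------------

VOLUME_DEFAULT_TERMS = ("intercept", "time", "age", "sex", "tiv", "group", "time:age")


@dataclass
class ModelSpec:
    """Fixed and random structure of one outcome model.

    ``fixed_terms`` is an ordered subset of {intercept, time, age, sex, tiv,
    group, time:age, scanner, voxel_size, study:group, arm, arm:time};
    categorical terms expand to indicator contrasts against the first level
    observed.  The random structure is always the two nested intercepts
    (center, participant-in-center); ``random_participant=False`` drops the
    participant level (used for single-observation layouts).
    """

    response: str
    fixed_terms: tuple = VOLUME_DEFAULT_TERMS
    random_participant: bool = True
    reml: bool = True
    df_method: str = "residual"  # or "between_within"

    def __post_init__(self):
        if "intercept" not in self.fixed_terms:
            raise ValueError("model must include an intercept")
        self.fixed_terms = tuple(self.fixed_terms)

    def to_json(self) -> str:
        return json.dumps(
            {
                "response": self.response,
                "fixed_terms": list(self.fixed_terms),
                "random_participant": self.random_participant,
                "reml": self.reml,
                "df_method": self.df_method,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        d["fixed_terms"] = tuple(d["fixed_terms"])
        return cls(**d)


_CATEGORICAL = {"group": "group", "scanner": "scanner", "study": "study", "arm": "arm"}


def _dummy_columns(values: pd.Series, term: str):
    levels = list(pd.unique(values))
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((values == lev).to_numpy(dtype=float))
        names.append(f"{term}[{lev}]")
    return cols, names, levels[0]


def build_design(table: pd.DataFrame, spec: ModelSpec):
    """Return (X, column names, meta) for the fixed-effect design.

    ``meta`` records, per column, the source term and whether the column is
    a nuisance covariate for baseline adjustment (age, sex, tiv, scanner,
    voxel_size, time:age — everything except intercept, time, group and
    study:group terms).
    """
    cols: list = []
    names: list = []
    term_of: list = []
    references: dict = {}
    for term in spec.fixed_terms:
        if term == "intercept":
            cols.append(np.ones(len(table)))
            names.append("intercept")
            term_of.append(term)
        elif term in ("time", "age", "tiv", "voxel_size"):
            cols.append(table[term].to_numpy(dtype=float))
            names.append(term)
            term_of.append(term)
        elif term == "sex":
            cols.append(table["sex"].to_numpy(dtype=float))
            names.append("sex")
            term_of.append(term)
        elif term == "time:age":
            cols.append(
                table["time"].to_numpy(dtype=float) * table["age"].to_numpy(dtype=float)
            )
            names.append("time:age")
            term_of.append(term)
        elif term == "arm:time":
            cols.append(
                table["arm"].to_numpy(dtype=float) * table["time"].to_numpy(dtype=float)
            )
            names.append("arm:time")
            term_of.append(term)
        elif term in ("group", "scanner"):
            c, n, ref = _dummy_columns(table[term], term)
            cols.extend(c)
            names.extend(n)
            term_of.extend([term] * len(n))
            references[term] = ref
        elif term == "arm":
            cols.append(table["arm"].to_numpy(dtype=float))
            names.append("arm")
            term_of.append(term)
        elif term == "study:group":
            studies = list(pd.unique(table["study"]))
            groups = list(pd.unique(table["group"]))
            references["study"] = studies[0]
            for s in studies[1:]:
                for g in groups[1:]:
                    col = (
                        (table["study"] == s) & (table["group"] == g)
                    ).to_numpy(dtype=float)
                    cols.append(col)
                    names.append(f"study[{s}]:group[{g}]")
                    term_of.append(term)
            if "study" not in spec.fixed_terms:
                # interaction requires study main-effect contrasts
                for s in studies[1:]:
                    cols.append((table["study"] == s).to_numpy(dtype=float))
                    names.append(f"study[{s}]")
                    term_of.append("study")
        elif term == "study":
            c, n, ref = _dummy_columns(table[term], term)
            cols.extend(c)
            names.extend(n)
            term_of.extend(["study"] * len(n))
            references["study"] = ref
        else:
            raise ValueError(f"unknown fixed term {term!r}")
    X = np.column_stack(cols) if cols else np.empty((len(table), 0))

    # full-rank check naming the offending columns
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise RankDeficientError(
            f"fixed-effect design is rank deficient; collinear column(s): {bad}"
        )

    nuisance = {"age", "sex", "tiv", "time:age", "scanner", "voxel_size"}
    meta = {
        "term_of": term_of,
        "nuisance": [t in nuisance for t in term_of],
        "references": references,
    }
    return X, names, meta


# ---------------------------------------------------------------------------
# fitted model container
# ---------------------------------------------------------------------------


@dataclass
class TrialHyperparameters:
    """Generative parameters for trial power simulation.

    ``tau_treatment`` is the between-center SD of the treatment-effect
    fraction (dimensionless); all variances are on the outcome scale.
    """

    baseline_mean: float
    placebo_slope: float
    sigma2_center: float
    sigma2_subject: float
    sigma2_resid: float
    tau_treatment: float = 0.0

    def __post_init__(self):
        for a in ("sigma2_center", "sigma2_subject", "sigma2_resid", "tau_treatment"):
            if getattr(self, a) < 0:
                raise ValueError(f"{a} must be >= 0")


@dataclass
class NestedLMMResult:
    """REML estimates of the nested random-intercept model."""

    params: pd.Series
    bse: pd.Series
    sigma2_center: float
    sigma2_subject: float
    sigma2_resid: float
    reml_loglik: float
    converged: bool
    n_obs: int
    n_centers: int
    n_participants: int
    df_resid: float
    column_names: list
    cov_params: np.ndarray = field(repr=False)
    meta: dict = field(default_factory=dict, repr=False)
    df_by_column: pd.Series | None = field(default=None, repr=False)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        df = (
            self.df_by_column
            if self.df_by_column is not None
            else pd.Series(self.df_resid, index=self.params.index)
        )
        t = self.tvalues
        return pd.Series(
            2.0 * stats.t.sf(np.abs(t.to_numpy()), df.to_numpy()), index=t.index
        )

    def wald_contrast(self, contrast: Mapping[str, float], df: float | None = None):
        """t statistic and 2-sided p for the linear contrast c'beta = 0."""
        c = np.zeros(len(self.params))
        for name, w in contrast.items():
            c[self.params.index.get_loc(name)] = w
        est = float(c @ self.params.to_numpy())
        se = float(np.sqrt(c @ self.cov_params @ c))
        if df is None:
            df = self.df_resid
        t = est / se
        return est, se, t, float(2.0 * stats.t.sf(abs(t), df))

    def to_json(self) -> str:
        return json.dumps(
            {
                "beta": {
                    k: {"estimate": float(self.params[k]), "se": float(self.bse[k])}
                    for k in self.params.index
                },
                "sigma2_center": self.sigma2_center,
                "sigma2_subject": self.sigma2_subject,
                "sigma2_resid": self.sigma2_resid,
                "reml_loglik": self.reml_loglik,
                "converged": self.converged,
                "n_obs": self.n_obs,
                "n_centers": self.n_centers,
                "n_participants": self.n_participants,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# REML engine
# ---------------------------------------------------------------------------


class NestedLMM:
    """REML fitter for a fixed design with two nested random intercepts.

    The constructor precomputes the grouping layout; :meth:`fit` may be
    called repeatedly (e.g. with new simulated outcomes via ``refit``)
    without rebuilding the structure.
    """

    #: relative REML-criterion change declared converged
    REML_RTOL = 1e-8

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        centers: np.ndarray,
        participants: np.ndarray,
        column_names: Sequence[str] | None = None,
        include_center: bool = True,
        include_participant: bool = True,
    ):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = y.size
        if X.shape[0] != n:
            raise ValueError("X and y row mismatch")
        # sort rows so participants are contiguous within centers
        c_codes, self.center_levels = pd.factorize(np.asarray(centers))
        p_codes, self.participant_levels = pd.factorize(np.asarray(participants))
        order = np.lexsort((p_codes, c_codes))
        self.order = order
        self.X = X[order]
        self.y = y[order]
        self.c = c_codes[order]
        self.p = p_codes[order]
        self.n = n
        self.k = len(self.center_levels)
        self.m = len(self.participant_levels)
        self.column_names = (
            list(column_names)
            if column_names is not None
            else [f"x{j}" for j in range(X.shape[1])]
        )

        # participant blocks (contiguous after sorting)
        change_p = np.nonzero(np.diff(self.p))[0] + 1
        self.p_starts = np.concatenate(([0], change_p))
        self.n_per_p = np.diff(np.concatenate((self.p_starts, [n])))
        # center blocks over participants
        p_center = self.c[self.p_starts]  # center code of each participant block
        change_c = np.nonzero(np.diff(p_center))[0] + 1
        self.c_starts_p = np.concatenate(([0], change_c))  # starts in participant axis
        self.p_of_row = np.repeat(
            np.arange(self.p_starts.size), self.n_per_p
        )  # row -> participant block
        self.c_of_pblock = p_center[self.c_starts_p]  # center code per center block
        n_cblocks = self.c_starts_p.size
        self.cblock_of_p = np.repeat(
            np.arange(n_cblocks),
            np.diff(np.concatenate((self.c_starts_p, [self.p_starts.size]))),
        )  # participant block -> center block

        self.include_center = include_center and self.k >= 2
        if include_center and self.k < 2:
            logger.warning(
                "only %d center(s): center variance fixed to 0", self.k
            )
        self.include_participant = include_participant

    # -- criterion ----------------------------------------------------------
    def _refresh_cache(self) -> None:
        # quantities constant across criterion evaluations for a given y
        T = np.column_stack((self.X, self.y))
        self._TtT = T.T @ T
        self._Psum = np.add.reduceat(T, self.p_starts, axis=0)
        self._ni = self.n_per_p.astype(float)

    def _profiled(self, gamma_c: float, gamma_p: float, grad: bool = False):
        """Profiled REML deviance (and optionally its analytic gradient).

        The gradient of the profiled criterion with respect to each variance
        ratio gamma_j is  tr(W^{-1} Z_j Z_j')
        - tr((X'W^{-1}X)^{-1} X'W^{-1}Z_j Z_j'W^{-1}X)
        - (n - p) |Z_j' W^{-1} r|^2 / RSS,  all available in closed form
        from the per-block Sherman-Morrison inverses.
        """
        n, p = self.n, self.X.shape[1]
        TtT, Psum, ni = self._TtT, self._Psum, self._ni

        denom_p = 1.0 + gamma_p * ni
        ap = gamma_p / denom_p
        M = TtT - (Psum * ap[:, None]).T @ Psum

        # center level
        q = Psum / denom_p[:, None]
        Q = np.add.reduceat(q, self.c_starts_p, axis=0)
        s = np.add.reduceat(ni / denom_p, self.c_starts_p)
        denom_c = 1.0 + gamma_c * s
        bc = gamma_c / denom_c
        G = M - (Q * bc[:, None]).T @ Q

        logdetW = float(np.sum(np.log(denom_p)) + np.sum(np.log(denom_c)))

        Gxx = G[:p, :p]
        Gxy = G[:p, p]
        Gyy = G[p, p]
        try:
            L = np.linalg.cholesky(Gxx)
        except np.linalg.LinAlgError:
            return None
        beta = np.linalg.solve(Gxx, Gxy)
        rss = float(Gyy - Gxy @ beta)
        if rss <= 0:
            rss = np.finfo(float).tiny
        logdetGxx = 2.0 * float(np.log(np.diag(L)).sum())
        sigma2 = rss / (n - p)
        dev = (n - p) * math.log(sigma2) + logdetW + logdetGxx
        out = {
            "dev": dev,
            "beta": beta,
            "sigma2": sigma2,
            "Gxx": Gxx,
            "gamma_c": gamma_c,
            "gamma_p": gamma_p,
        }
        if not grad:
            return out

        cb = self.cblock_of_p
        t_i = ni / denom_p
        # Z' W^{-1} T at both random-effect levels
        Up = q - (t_i[:, None] * (bc[:, None] * Q)[cb])
        Uc = Q / denom_c[:, None]
        zpr = Up[:, p] - Up[:, :p] @ beta
        zcr = Uc[:, p] - Uc[:, :p] @ beta
        tr_p = float(np.sum(t_i - bc[cb] * t_i**2))
        tr_c = float(np.sum(s / denom_c))
        rhs = np.concatenate((Up[:, :p], Uc[:, :p]), axis=0).T
        S = np.linalg.solve(Gxx, rhs)
        m_blocks = Up.shape[0]
        trG_p = float(np.sum(rhs[:, :m_blocks] * S[:, :m_blocks]))
        trG_c = float(np.sum(rhs[:, m_blocks:] * S[:, m_blocks:]))
        # perfect fits (rss ~ 0) have no meaningful gradient contribution
        scale = (n - p) / rss if rss > 1e-290 else 0.0
        out["grad_p"] = tr_p - trG_p - scale * float(np.sum(zpr**2))
        out["grad_c"] = tr_c - trG_c - scale * float(np.sum(zcr**2))
        return out

    def _dev(self, gamma_c: float, gamma_p: float) -> float:
        out = self._profiled(gamma_c, gamma_p)
        return np.inf if out is None else out["dev"]

    # -- optimization -------------------------------------------------------
    _LOG_LO, _LOG_HI = -25.0, 12.0

    def _opt_1d(self, which: str) -> tuple:
        def fg(theta):
            g = math.exp(theta[0])
            out = (
                self._profiled(g, 0.0, grad=True)
                if which == "c"
                else self._profiled(0.0, g, grad=True)
            )
            if out is None:
                return np.inf, np.zeros(1)
            d = out["grad_c"] if which == "c" else out["grad_p"]
            return out["dev"], np.array([d * g])

        res = optimize.minimize(
            fg, np.zeros(1), jac=True, method="L-BFGS-B",
            bounds=[(self._LOG_LO, self._LOG_HI)],
            options={"ftol": 1e-13, "gtol": 1e-8, "maxiter": 100},
        )
        if not res.success:
            f = lambda th: fg(np.array([th]))[0]
            alt = optimize.minimize_scalar(
                f, bounds=(self._LOG_LO, self._LOG_HI), method="bounded",
                options={"xatol": 1e-10},
            )
            if alt.fun < res.fun:
                res = alt
                res.x = np.array([alt.x])
        g = math.exp(float(res.x[0]))
        return (g, 0.0, res.fun) if which == "c" else (0.0, g, res.fun)

    def _opt_2d(self, starts, boundary_best: float = np.inf) -> tuple:
        """2-D search on the log scale with analytic gradients; a
        Nelder-Mead polish runs only when L-BFGS-B stops abnormally at a
        point that would beat the already optimized boundary sub-models
        (those cover premature stops toward a boundary)."""

        def fg(theta):
            gc, gp = math.exp(theta[0]), math.exp(theta[1])
            out = self._profiled(gc, gp, grad=True)
            if out is None:
                return np.inf, np.zeros(2)
            return out["dev"], np.array([out["grad_c"] * gc, out["grad_p"] * gp])

        bounds = [(self._LOG_LO, self._LOG_HI)] * 2
        best = None
        for x0 in starts:
            res = optimize.minimize(
                fg, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-13, "gtol": 1e-8, "maxiter": 100},
            )
            if best is None or res.fun < best.fun:
                best = res
        if not best.success and best.fun < boundary_best - 1e-7:
            res = optimize.minimize(
                lambda th: fg(th)[0], best.x, method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400},
            )
            if res.fun < best.fun:
                best = res
        return math.exp(best.x[0]), math.exp(best.x[1]), best.fun

    def fit(self, y: np.ndarray | None = None, n_restarts: int = 2) -> NestedLMMResult:
        """Maximize the REML criterion; boundary variances reported as 0."""
        if y is not None:
            y = np.asarray(y, dtype=float)
            self.y = y[self.order]
        self._refresh_cache()

        candidates = []  # (gamma_c, gamma_p, dev)
        candidates.append((0.0, 0.0, self._dev(0.0, 0.0)))
        if self.include_center and self.include_participant:
            gc2, gp2, dev2 = self._opt_2d(
                [np.array([-1.0, -1.0])], boundary_best=candidates[0][2]
            )
            candidates.append((gc2, gp2, dev2))
            # a ratio driven to the box edge means a boundary optimum:
            # refine the corresponding one-ratio profile exactly
            edge = math.exp(self._LOG_LO + 1e-6)
            if gc2 <= edge:
                candidates.append(self._opt_1d("p"))
            if gp2 <= edge:
                candidates.append(self._opt_1d("c"))
        elif self.include_center:
            candidates.append(self._opt_1d("c"))
        elif self.include_participant:
            candidates.append(self._opt_1d("p"))

        candidates.sort(key=lambda t: t[2])
        gc, gp, dev = candidates[0]
        converged = math.isfinite(dev)
        if not converged and n_restarts > 0:
            rng = np.random.default_rng(0)
            extra = [rng.normal(0.0, 2.0, size=2) for _ in range(n_restarts)]
            gc, gp, dev = self._opt_2d(extra)
            converged = math.isfinite(dev)

        # snap near-boundary ratios to exact zero when not worse
        snap_c = 0.0 if gc < 1e-7 else gc
        snap_p = 0.0 if gp < 1e-7 else gp
        if (snap_c, snap_p) != (gc, gp):
            d = self._dev(snap_c, snap_p)
            if d <= dev + 1e-9 * max(1.0, abs(dev)):
                gc, gp, dev = snap_c, snap_p, d

        prof = self._profiled(gc, gp)
        p = self.X.shape[1]
        sigma2 = prof["sigma2"]
        beta = prof["beta"]
        cov = sigma2 * np.linalg.inv(prof["Gxx"])
        bse = np.sqrt(np.diag(cov))
        df_resid = self.n - p
        loglik = -0.5 * (dev + df_resid * (1.0 + math.log(2.0 * math.pi)))

        self._fitted_gammas = (gc, gp)
        self._fitted_sigma2 = sigma2
        self._fitted_beta = beta

        return NestedLMMResult(
            params=pd.Series(beta, index=self.column_names),
            bse=pd.Series(bse, index=self.column_names),
            sigma2_center=gc * sigma2,
            sigma2_subject=gp * sigma2,
            sigma2_resid=sigma2,
            reml_loglik=loglik,
            converged=bool(converged),
            n_obs=self.n,
            n_centers=self.k,
            n_participants=self.m,
            df_resid=float(df_resid),
            column_names=list(self.column_names),
            cov_params=cov,
            meta={"gamma_center": gc, "gamma_participant": gp},
        )

    # -- BLUPs and fitted values -------------------------------------------
    def _winv_apply(self, r: np.ndarray, gamma_c: float, gamma_p: float):
        """W^{-1} r for the sorted residual vector r."""
        ni = self.n_per_p.astype(float)
        denom_p = 1.0 + gamma_p * ni
        Psum = np.add.reduceat(r, self.p_starts)
        a_row = (gamma_p / denom_p)[self.p_of_row]
        Ar = r - a_row * Psum[self.p_of_row]
        onesAr_c = np.add.reduceat(Psum / denom_p, self.c_starts_p)
        s = np.add.reduceat(ni / denom_p, self.c_starts_p)
        bc = gamma_c / (1.0 + gamma_c * s)
        cblock_of_p = np.repeat(
            np.arange(self.c_starts_p.size),
            np.diff(np.concatenate((self.c_starts_p, [self.p_starts.size]))),
        )
        cblock_of_row = cblock_of_p[self.p_of_row]
        Winv_r = Ar - (bc * onesAr_c)[cblock_of_row] / denom_p[self.p_of_row]
        return Winv_r, cblock_of_row

    def predict_random_effects(self):
        """BLUPs (u_center per row, u_participant per row), in input row order."""
        gc, gp = self._fitted_gammas
        r = self.y - self.X @ self._fitted_beta
        Winv_r, cblock_of_row = self._winv_apply(r, gc, gp)
        psum = np.add.reduceat(Winv_r, self.p_starts)
        u_p = gp * psum
        u_c = gc * np.add.reduceat(psum, self.c_starts_p)
        u_c_rows = u_c[cblock_of_row]
        u_p_rows = u_p[self.p_of_row]
        out_c = np.empty(self.n)
        out_p = np.empty(self.n)
        out_c[self.order] = u_c_rows
        out_p[self.order] = u_p_rows
        return out_c, out_p

    def fitted_values(self, conditional: bool = True) -> np.ndarray:
        """Fitted y in input row order, with (default) or without BLUPs."""
        mean = np.empty(self.n)
        mean[self.order] = self.X @ self._fitted_beta
        if conditional:
            u_c, u_p = self.predict_random_effects()
            mean = mean + u_c + u_p
        return mean


# ---------------------------------------------------------------------------
# high-level operations on cohort tables
# ---------------------------------------------------------------------------


def _between_within_df(X: np.ndarray, names, participants: np.ndarray) -> pd.Series:
    """Between-within degrees of freedom per fixed-effect column.

    Columns that vary within at least one participant are 'within' and get
    ``n_obs - n_participants - n_within_columns`` df; the rest are 'between'
    with ``n_participants - n_between_columns`` df.
    """
    codes, _ = pd.factorize(participants)
    n, p = X.shape
    m = codes.max() + 1
    order = np.argsort(codes, kind="stable")
    Xs = X[order]
    starts = np.concatenate(([0], np.nonzero(np.diff(codes[order]))[0] + 1))
    span = np.maximum.reduceat(Xs, starts, axis=0) - np.minimum.reduceat(
        Xs, starts, axis=0
    )
    within = (span > 0).any(axis=0)
    n_w = int(within.sum())
    n_b = p - n_w
    df_w = max(n - m - n_w, 1)
    df_b = max(m - n_b, 1)
    return pd.Series(np.where(within, df_w, df_b), index=list(names), dtype=float)


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> NestedLMMResult:
    """Fit the nested random-intercept model for ``spec.response``.

    With fewer than two centers the center variance is fixed at zero (with a
    logged warning); a rank-deficient design raises :class:`RankDeficientError`
    naming the collinear columns.
    """
    df = table.dropna(subset=[spec.response]).reset_index(drop=True)
    X, names, meta = build_design(df, spec)
    y = df[spec.response].to_numpy(dtype=float)
    model = NestedLMM(
        X,
        y,
        centers=df["center"].to_numpy(),
        participants=df["participant"].to_numpy(),
        column_names=names,
        include_participant=spec.random_participant,
    )
    result = model.fit()
    result.meta.update(meta)
    result.meta["model"] = model
    result.meta["fit_table_index"] = df.index
    result.meta["spec"] = spec
    if spec.df_method == "between_within":
        result.df_by_column = _between_within_df(X, names, df["participant"].to_numpy())
    if not result.converged:
        logger.warning("REML fit for %s did not converge", spec.response)
    return result


def adjust_baseline(
    result: NestedLMMResult, table: pd.DataFrame, spec: ModelSpec
) -> pd.DataFrame:
    """Covariate-adjusted baseline volumes per participant.

    The adjusted value is the observed baseline volume minus the fitted
    nuisance contributions (age, sex, TIV, scanner, voxel size, time-by-age),
    each evaluated relative to the sample mean of its column over baseline
    rows, so the group contribution is retained and adjusted values are
    comparable across groups.  ``residual`` is observed minus the full
    conditional fit (fixed effects plus predicted random intercepts).
    """
    if not result.converged:
        raise ValueError("cannot adjust from a non-converged fit")
    df = table.dropna(subset=[spec.response]).reset_index(drop=True)
    model: NestedLMM = result.meta["model"]
    X, names, meta = build_design(df, spec)
    resid = df[spec.response].to_numpy(dtype=float) - model.fitted_values(
        conditional=True
    )

    base_mask = df["time"] == df["time"].min()
    n_missing = df["participant"].nunique() - df.loc[base_mask, "participant"].nunique()
    if n_missing:
        logger.info("adjust_baseline: %d participant(s) missing baseline", n_missing)
    Xb = X[base_mask.to_numpy()]
    nuisance = np.asarray(meta["nuisance"])
    beta = result.params.to_numpy()
    adj = df.loc[base_mask, spec.response].to_numpy(dtype=float).copy()
    if nuisance.any():
        Xn = Xb[:, nuisance]
        centered = Xn - Xn.mean(axis=0)
        adj = adj - centered @ beta[nuisance]
    out = pd.DataFrame(
        {
            "participant": df.loc[base_mask, "participant"].to_numpy(),
            "group": df.loc[base_mask, "group"].to_numpy(),
            "study": df.loc[base_mask, "study"].to_numpy()
            if "study" in df.columns
            else "",
            "adjusted_baseline": adj,
            "residual": resid[base_mask.to_numpy()],
        }
    )
    return out.reset_index(drop=True)


def test_study_group_interaction(
    table: pd.DataFrame, spec: ModelSpec, min_cell: int = 2
) -> dict:
    """Bonferroni-adjusted Wald p-values for study-by-group contrasts.

    For every pair of studies and every non-reference group present in both,
    tests whether the group offset differs between the studies.  Returns
    ``{(study_a, study_b, group): adjusted p}``; empty when fewer than two
    studies share two groups.  Cells with fewer than ``min_cell``
    participants are skipped (logged).
    """
    studies = list(pd.unique(table["study"]))
    groups = list(pd.unique(table["group"]))
    if len(studies) < 2 or len(groups) < 2:
        return {}
    terms = tuple(
        t for t in spec.fixed_terms if t not in ("study:group", "study")
    ) + ("study:group",)
    ispec = ModelSpec(
        response=spec.response,
        fixed_terms=terms,
        random_participant=spec.random_participant,
        df_method=spec.df_method,
    )
    fit = fit_lmm(table, ispec)
    ref_study = studies[0]
    names = set(fit.params.index)

    cell_n = table.groupby(["study", "group"])["participant"].nunique()

    raw: dict = {}
    for g in groups[1:]:
        for a_idx in range(len(studies)):
            for b_idx in range(a_idx + 1, len(studies)):
                sa, sb = studies[a_idx], studies[b_idx]
                ok = True
                for s in (sa, sb):
                    if cell_n.get((s, g), 0) < min_cell:
                        logger.info(
                            "interaction contrast skipped: cell (%s, %s) has <%d participants",
                            s, g, min_cell,
                        )
                        ok = False
                if not ok:
                    continue
                contrast: dict = {}
                na, nb = f"study[{sa}]:group[{g}]", f"study[{sb}]:group[{g}]"
                if sa != ref_study:
                    contrast[na] = 1.0
                if sb != ref_study:
                    contrast[nb] = contrast.get(nb, 0.0) - 1.0
                if not contrast or any(n not in names for n in contrast):
                    continue
                _, _, _, p = fit.wald_contrast(contrast)
                raw[(sa, sb, g)] = p
    k = len(raw)
    return {key: min(1.0, p * k) for key, p in raw.items()}


def extract_hyperparameters(
    result: NestedLMMResult, treated_fraction_sd: float = 0.0
) -> TrialHyperparameters:
    """Map a fitted longitudinal model to trial-simulation hyperparameters.

    Intercept becomes the baseline mean, the ``time`` coefficient the
    placebo slope; variance components are copied.  ``treated_fraction_sd``
    (tau) is the between-center SD of the treatment-effect fraction and is
    supplied by the caller, not estimated.
    """
    if not result.converged:
        raise ValueError("refusing to extract hyperparameters from a non-converged fit")
    if "time" not in result.params.index:
        raise ValueError("fit has no time term; cannot define a placebo slope")
    return TrialHyperparameters(
        baseline_mean=float(result.params["intercept"]),
        placebo_slope=float(result.params["time"]),
        sigma2_center=float(result.sigma2_center),
        sigma2_subject=float(result.sigma2_subject),
        sigma2_resid=float(result.sigma2_resid),
        tau_treatment=float(treated_fraction_sd),
    )
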
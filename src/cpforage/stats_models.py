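"""Inference on foraging-site fidelity (NND) records.

Three entry points mirror the analysis questions:

* :func:`fit_year_model` — linear model of log(NND) on year (categorical),
  first season as reference; inter-annual differences in site fidelity.
* :func:`fit_year_timing_model` — log(NND) ~ year x days-since-peak-hatch,
  with estimated marginal means per year at the grand-mean timing and all
  pairwise year contrasts under a Tukey adjustment.
* :func:`fit_smooth_ice_model` — penalized cubic-spline smooth of log(NND)
  on an ice covariate (mean concentration over the trip pair, or the
  between-trip concentration difference) with a bird random intercept; the
  smoothing parameter and the intercept variance are chosen by REML. The
  smooth is a P-spline in its mixed-model parametrization (penalty null
  space as fixed effects, penalized range space as an iid random block).

All models operate on log(NND); back-transformed predictions are exp of the
link-scale fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.stats import studentized_range

logger = logging.getLogger(__name__)


@dataclass
class NndModelResult:
    table: pd.DataFrame  # term, estimate, se, t, p
    reference: str
    transform: str = "log"
    emmeans: pd.DataFrame | None = None
    contrasts: pd.DataFrame | None = None


@dataclass
class SmoothFitResult:
    grid: np.ndarray  # covariate values
    fitted: np.ndarray  # fitted log-NND at grid
    band_low: np.ndarray
    band_high: np.ndarray
    edf: float
    random_intercept_var: float
    sigma2: float
    covariate: str
    linear_fallback: bool = False

    @property
    def fitted_response(self) -> np.ndarray:
        """Back-transformed (km-scale) fitted curve."""
        return np.exp(self.fitted)


def _prepare(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    if np.any(df["nnd"] <= 0):
        n = int((df["nnd"] <= 0).sum())
        logger.warning("%d record(s) with non-positive NND dropped before log transform", n)
        df = df[df["nnd"] > 0]
    df["log_nnd"] = np.log(df["nnd"])
    return df


def _coef_table(fit) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.values,
            "se": fit.bse.values,
            "t": fit.tvalues.values,
            "p": np.round(fit.pvalues.values, 3),
        }
    )


def fit_year_model(records: pd.DataFrame) -> NndModelResult:
    """Linear model of log(NND) on year; first season is the reference level."""
    df = _prepare(records)
    seasons = sorted(df["season"].unique())
    if len(seasons) < 2:
        raise ValueError("year model requires at least two seasons")
    fit = smf.ols("log_nnd ~ C(season)", data=df).fit()
    return NndModelResult(table=_coef_table(fit), reference=seasons[0])


def _tukey_contrasts(emm: np.ndarray, cov: np.ndarray, labels: list[str], df_resid: float) -> pd.DataFrame:
    k = len(emm)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = emm[i] - emm[j]
            se = float(np.sqrt(cov[i, i] + cov[j, j] - 2.0 * cov[i, j]))
            t = diff / se
            p = float(1.0 - studentized_range.cdf(abs(t) * np.sqrt(2.0), k, df_resid))
            rows.append(
                {
                    "contrast": f"{labels[i]} - {labels[j]}",
                    "estimate": float(diff),
                    "se": se,
                    "t": float(t),
                    "p_tukey": round(p, 3),
                }
            )
    return pd.DataFrame(rows)


def fit_year_timing_model(records: pd.DataFrame, min_per_season: int = 3) -> NndModelResult:
    """log(NND) ~ year x timing with Tukey-adjusted pairwise year contrasts.

    Marginal means are evaluated at the grand mean of days-since-peak-hatch;
    seasons with fewer than ``min_per_season`` records are dropped from the
    contrast family (logged).
    """
    df = _prepare(records)
    sizes = df.groupby("season").size()
    small = sizes[sizes < min_per_season].index.tolist()
    if small:
        logger.warning("seasons dropped from contrasts (<%d records): %s", min_per_season, small)
        df = df[~df["season"].isin(small)]
    seasons = sorted(df["season"].unique())
    if len(seasons) < 2:
        raise ValueError("need >= 2 seasons with enough records")
    fit = smf.ols("log_nnd ~ C(season) * days_since_peak_hatch", data=df).fit()

    t0 = float(df["days_since_peak_hatch"].mean())
    # design rows for each season's marginal mean at the grand-mean timing
    L = np.zeros((len(seasons), len(fit.params)))
    names = list(fit.params.index)
    for s_idx, s in enumerate(seasons):
        for c_idx, name in enumerate(names):
            if name == "Intercept":
                L[s_idx, c_idx] = 1.0
            elif name == "days_since_peak_hatch":
                L[s_idx, c_idx] = t0
            elif name == f"C(season)[T.{s}]":
                L[s_idx, c_idx] = 1.0
            elif name == f"C(season)[T.{s}]:days_since_peak_hatch":
                L[s_idx, c_idx] = t0
    emm = L @ fit.params.values
    cov = L @ fit.cov_params().values @ L.T
    emmeans = pd.DataFrame(
        {"season": seasons, "emmean": emm, "se": np.sqrt(np.diag(cov)), "at_timing": t0}
    )
    contrasts = _tukey_contrasts(emm, cov, seasons, fit.df_resid)
    return NndModelResult(
        table=_coef_table(fit), reference=seasons[0], emmeans=emmeans, contrasts=contrasts
    )


# ---------------------------------------------------------------------------
# penalized-spline mixed model (smooth + bird random intercept)
# ---------------------------------------------------------------------------


def _bspline_basis(z: np.ndarray, zmin: float, zmax: float, nbasis: int) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline design over [zmin, zmax] with nbasis functions."""
    degree = 3
    n_interior = nbasis - degree - 1
    if n_interior < 0:
        raise ValueError("nbasis too small for a cubic basis")
    interior = np.linspace(zmin, zmax, n_interior + 2)[1:-1]
    knots = np.concatenate([[zmin] * (degree + 1), interior, [zmax] * (degree + 1)])
    zc = np.clip(z, zmin, zmax)
    B = BSpline.design_matrix(zc, knots, degree).toarray()
    return B, knots


class _PsplineMixed:
    """REML fit of y = f(z) + bird intercept + noise, f a P-spline smooth."""

    def __init__(self, nbasis: int = 10):
        self.nbasis = nbasis

    def fit(self, z, y, group_codes):
        z = np.asarray(z, float)
        y = np.asarray(y, float)
        n = len(y)
        self.zmin_, self.zmax_ = float(z.min()), float(z.max())
        B, self.knots_ = _bspline_basis(z, self.zmin_, self.zmax_, self.nbasis)
        # second-difference penalty; eigen-split into null (fixed) and range (random)
        D = np.diff(np.eye(B.shape[1]), n=2, axis=0)
        S = D.T @ D
        w, U = np.linalg.eigh(S)
        null = w < 1e-8 * w.max()
        self.U_null_, self.U_pen_ = U[:, null], U[:, ~null]
        self.w_pen_ = w[~null]
        X = B @ self.U_null_  # spans {1, z}: the unpenalized part of the smooth
        Zs = B @ self.U_pen_ / np.sqrt(self.w_pen_)
        ng = int(group_codes.max() + 1)
        Zu = np.zeros((n, ng))
        Zu[np.arange(n), group_codes] = 1.0
        p = X.shape[1]

        if np.linalg.matrix_rank(np.column_stack([X, Zs])) < X.shape[1] + Zs.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient smooth basis")

        XtX = X.T @ X

        def crit(logl):
            ls, lu = np.exp(logl)
            V0 = np.eye(n) + ls * (Zs @ Zs.T) + lu * (Zu @ Zu.T)
            try:
                L = np.linalg.cholesky(V0)
            except np.linalg.LinAlgError:
                return np.inf
            Li_y = np.linalg.solve(L, y)
            Li_X = np.linalg.solve(L, X)
            A = Li_X.T @ Li_X
            b = Li_X.T @ Li_y
            try:
                beta = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                return np.inf
            rss = max(Li_y @ Li_y - beta @ b, 1e-300)
            logdetV = 2.0 * np.sum(np.log(np.diag(L)))
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            df = n - p
            return df * np.log(rss / df) + logdetV + logdetA

        res = optimize.minimize(
            crit, x0=np.log([1.0, 1.0]), method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
        )
        self.lambda_s_, self.lambda_u_ = np.exp(res.x)

        # joint penalized LS at the optimum for coefficients, BLUPs and edf
        C = np.column_stack([X, Zs, Zu])
        pen = np.concatenate(
            [np.zeros(p), np.full(Zs.shape[1], 1.0 / self.lambda_s_), np.full(ng, 1.0 / self.lambda_u_)]
        )
        M = C.T @ C + np.diag(pen)
        Minv = np.linalg.inv(M)
        theta = Minv @ (C.T @ y)
        fitted = C @ theta
        df_smooth = np.trace((Minv @ (C.T @ C)))
        rss = float(np.sum((y - fitted) ** 2) + np.sum(pen * theta**2))
        self.sigma2_ = rss / (n - p)
        self.random_intercept_var_ = self.sigma2_ * self.lambda_u_
        # edf of the smooth term: its unpenalized columns + shrunk wiggly columns
        F = Minv @ (C.T @ C)
        idx_smooth = np.arange(p + Zs.shape[1])
        self.edf_ = float(np.trace(F[np.ix_(idx_smooth, idx_smooth)])) - 1.0  # exclude intercept
        self.theta_ = theta
        self.Minv_ = Minv
        self.p_ = p
        self.nZs_ = Zs.shape[1]
        return self

    def predict_grid(self, grid: np.ndarray):
        B, _ = _bspline_basis(grid, self.zmin_, self.zmax_, self.nbasis)
        G = np.column_stack([B @ self.U_null_, B @ self.U_pen_ / np.sqrt(self.w_pen_)])
        coef = self.theta_[: self.p_ + self.nZs_]
        fit = G @ coef
        cov = self.Minv_[: G.shape[1], : G.shape[1]] * self.sigma2_
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", G, cov, G), 0.0))
        return fit, se


def fit_smooth_ice_model(
    records: pd.DataFrame,
    covariate: str = "mean_sic_pair",
    nbasis: int = 10,
    grid_size: int = 100,
    min_records: int = 30,
) -> SmoothFitResult:
    """Penalized-spline GAMM of log(NND) on an ice covariate.

    Requires >= ``min_records`` records and covariate spread > 5 percentage
    points. If the spline basis is rank-deficient at small n the model falls
    back to a straight line (flagged).
    """
    df = _prepare(records)
    z = df[covariate].to_numpy(dtype=float)
    if len(df) < min_records:
        raise ValueError(f"need >= {min_records} records for a smooth fit")
    if np.ptp(z) <= 5.0:
        raise ValueError("covariate spread <= 5 percentage points")
    y = df["log_nnd"].to_numpy()
    codes = pd.Categorical(df["bird_id"]).codes.astype(int)

    linear_fallback = False
    try:
        model = _PsplineMixed(nbasis=nbasis).fit(z, y, codes)
        grid = np.linspace(z.min(), z.max(), grid_size)
        fit, se = model.predict_grid(grid)
        edf = model.edf_
        s2u, s2 = model.random_intercept_var_, model.sigma2_
    except np.linalg.LinAlgError:
        logger.warning("smooth basis rank-deficient; falling back to a linear term")
        linear_fallback = True
        from .repeatability import _fit_random_intercept

        X = np.column_stack([np.ones_like(z), z])
        beta, s2a, s2, _, _ = _fit_random_intercept(X, y, codes, reml=True)
        grid = np.linspace(z.min(), z.max(), grid_size)
        G = np.column_stack([np.ones_like(grid), grid])
        fit = G @ beta
        se = np.full_like(grid, np.sqrt(s2 / len(y)))
        edf, s2u = 1.0, s2a

    return SmoothFitResult(
        grid=grid,
        fitted=fit,
        band_low=fit - 1.96 * se,
        band_high=fit + 1.96 * se,
        edf=float(edf),
        random_intercept_var=float(s2u),
        sigma2=float(s2),
        covariate=covariate,
        linear_fallback=linear_fallback,
    )
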
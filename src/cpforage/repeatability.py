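"""Variance-component repeatability of foraging traits.

For each trait (log total duration, log total distance, log maximal
distance, folded bearing, mean central-phase sea-ice concentration) a
Gaussian random-intercept mixed model is fitted with bird identity as the
grouping factor:

    y_ij = x_ij' beta + a_i + e_ij,   a_i ~ N(0, sigma2_A),  e_ij ~ N(0, sigma2)

and the population-level repeatability is the intraclass correlation

    R = sigma2_A / (sigma2_A + sigma2).

Fixed effects (year, days since peak hatch, their interaction) are selected
backwards from the full interaction model by AIC on maximum-likelihood
fits, preferring the smaller model unless the larger wins by more than 2
AIC units; variance components of the selected structure are re-estimated
by REML. "Adjusted" repeatability conditions on the selected fixed effects;
"non-adjusted" uses the intercept-only model. Uncertainty comes from a
parametric bootstrap (simulate from the fitted model, refit, recompute R).

The single-random-intercept model admits a profiled likelihood in the
variance ratio lambda = sigma2_A/sigma2: given lambda, GLS is closed-form
via per-group sufficient statistics, leaving a 1-D optimization. This makes
the thousands of bootstrap refits cheap; agreement with statsmodels MixedLM
is covered by the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

#: response -> log-transform flag (bearing stays linear; SIC is a bounded %)
DEFAULT_RESPONSES = {
    "total_duration": True,
    "total_distance": True,
    "max_distance": True,
    "bearing_folded": False,
    "central_phase_sic": False,
}


@dataclass(frozen=True)
class LmmSpec:
    """Model specification: response, transform and fixed-effect structure."""

    response: str
    log_transform: bool = False
    year: bool = False
    timing: bool = False
    interaction: bool = False
    group_col: str = "bird_id"
    year_col: str = "season"
    timing_col: str = "days_since_peak_hatch"

    def __post_init__(self):
        if self.interaction and not (self.year and self.timing):
            raise ValueError("interaction requires both main effects")

    @property
    def terms(self) -> tuple[str, ...]:
        out = []
        if self.year:
            out.append("year")
        if self.timing:
            out.append("timing")
        if self.interaction:
            out.append("year:timing")
        return tuple(out)


@dataclass
class LmmFit:
    """Fitted Gaussian random-intercept mixed model."""

    spec: LmmSpec
    beta: np.ndarray
    beta_names: list[str]
    sigma2_A: float
    sigma2: float
    loglik: float
    aic: float  # from the ML fit of the same structure
    reml: bool
    converged: bool
    n_obs: int
    n_groups: int
    X: np.ndarray = field(repr=False, default=None)
    group_codes: np.ndarray = field(repr=False, default=None)


@dataclass
class RepeatabilityResult:
    R: float
    adjusted: bool
    category: str
    sigma2_A: float
    sigma2: float
    se: float | None = None
    ci: tuple[float, float] | None = None
    fixed_terms: tuple[str, ...] = ()


def _design(spec: LmmSpec, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(data))]
    names = ["Intercept"]
    if spec.year:
        years = pd.Categorical(data[spec.year_col])
        for lev in years.categories[1:]:
            cols.append((years == lev).astype(float))
            names.append(f"year[{lev}]")
    if spec.timing:
        cols.append(data[spec.timing_col].to_numpy(dtype=float))
        names.append("timing")
    if spec.interaction:
        years = pd.Categorical(data[spec.year_col])
        tim = data[spec.timing_col].to_numpy(dtype=float)
        for lev in years.categories[1:]:
            cols.append((years == lev).astype(float) * tim)
            names.append(f"year[{lev}]:timing")
    return np.column_stack(cols), names


def _response(spec: LmmSpec, data: pd.DataFrame) -> np.ndarray:
    y = data[spec.response].to_numpy(dtype=float)
    if spec.log_transform:
        if np.any(y <= 0):
            raise ValueError(f"log transform of non-positive {spec.response}")
        y = np.log(y)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite response values in {spec.response}")
    return y


def _profiled_crit(lam, XtX, Xty, yty, Sx, Sy, ni, n, p, reml):
    """-2 log-likelihood (up to an additive constant) profiled in beta, sigma2."""
    w = lam / (1.0 + lam * ni)
    A = XtX - np.einsum("g,gi,gj->ij", w, Sx, Sx)
    b = Xty - (w * Sy) @ Sx
    q = yty - np.sum(w * Sy**2)
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    beta = np.linalg.solve(L.T, np.linalg.solve(L, b))
    rss = max(q - beta @ b, 1e-300)
    logdetV = float(np.sum(np.log1p(lam * ni)))
    if reml:
        logdetA = 2.0 * float(np.sum(np.log(np.diag(L))))
        df = n - p
        crit = df * np.log(2.0 * np.pi * rss / df) + logdetV + logdetA + df
        sigma2 = rss / df
    else:
        crit = n * np.log(2.0 * np.pi * rss / n) + logdetV + n
        sigma2 = rss / n
    return crit, beta, sigma2


def _fit_random_intercept(X, y, codes, reml=True):
    """Profiled fit; returns (beta, sigma2_A, sigma2, loglik, converged)."""
    n, p = X.shape
    ng = codes.max() + 1
    XtX, Xty, yty = X.T @ X, X.T @ y, y @ y
    Sx = np.zeros((ng, p))
    np.add.at(Sx, codes, X)
    Sy = np.bincount(codes, weights=y, minlength=ng)
    ni = np.bincount(codes, minlength=ng).astype(float)

    def crit_at(loglam):
        return _profiled_crit(np.exp(loglam), XtX, Xty, yty, Sx, Sy, ni, n, p, reml)[0]

    res = minimize_scalar(crit_at, bounds=(-14.0, 14.0), method="bounded",
                          options={"xatol": 1e-8})
    # compare the interior optimum against the sigma2_A -> 0 boundary
    c0, beta0, s20 = _profiled_crit(0.0, XtX, Xty, yty, Sx, Sy, ni, n, p, reml)
    copt, betao, s2o = _profiled_crit(np.exp(res.x), XtX, Xty, yty, Sx, Sy, ni, n, p, reml)
    if c0 <= copt:
        lam, crit, beta, sigma2 = 0.0, c0, beta0, s20
    else:
        lam, crit, beta, sigma2 = float(np.exp(res.x)), copt, betao, s2o
    loglik = -0.5 * crit
    return beta, lam * sigma2, sigma2, loglik, bool(np.isfinite(crit))


def fit_lmm(spec: LmmSpec, data: pd.DataFrame, reml: bool = True) -> LmmFit:
    """Fit the random-intercept LMM for a spec.

    Requires at least 2 individuals with at least 2 trips each; AIC is always
    computed from the ML fit of the same structure so fixed-effect structures
    are comparable.
    """
    counts = data[spec.group_col].value_counts()
    if len(counts) < 2 or (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 individuals with >= 2 trips for variance components")
    X, names = _design(spec, data)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient fixed-effect design")
    y = _response(spec, data)
    codes = pd.Categorical(data[spec.group_col]).codes.astype(int)

    beta, s2a, s2e, loglik, conv = _fit_random_intercept(X, y, codes, reml=reml)
    if reml:
        _, _, _, ll_ml, _ = _fit_random_intercept(X, y, codes, reml=False)
    else:
        ll_ml = loglik
    k = X.shape[1] + 2  # fixed coefficients + two variance components
    aic = -2.0 * ll_ml + 2.0 * k
    if not conv:
        logger.warning("LMM fit for %s did not converge", spec.response)
    return LmmFit(
        spec=spec, beta=beta, beta_names=names, sigma2_A=s2a, sigma2=s2e,
        loglik=loglik, aic=aic, reml=reml, converged=conv,
        n_obs=len(y), n_groups=int(codes.max() + 1), X=X, group_codes=codes,
    )


def select_fixed_effects(start: LmmSpec, data: pd.DataFrame) -> LmmFit:
    """Backward AIC elimination over the fixed-effect hierarchy.

    From the full interaction model, repeatedly drop the term (interaction
    before main effects) whose removal gives the best AIC; the reduction is
    accepted unless the larger model is better by more than 2 AIC units
    (parsimony rule). The winning structure is refitted by REML.
    """
    current = start
    cur_fit = fit_lmm(current, data, reml=False)
    while True:
        candidates: list[LmmSpec] = []
        if current.interaction:
            candidates.append(replace(current, interaction=False))
        else:
            if current.year:
                candidates.append(replace(current, year=False))
            if current.timing:
                candidates.append(replace(current, timing=False))
        if not candidates:
            break
        fits = []
        for cand in candidates:
            try:
                fits.append(fit_lmm(cand, data, reml=False))
            except ValueError:
                continue
        fits = [f for f in fits if f.converged]
        if not fits:
            break
        best = min(fits, key=lambda f: f.aic)
        if cur_fit.aic < best.aic - 2.0:
            break  # larger model clearly better
        current, cur_fit = best.spec, best
    return fit_lmm(current, data, reml=True)


def repeatability(fit: LmmFit, adjusted: bool | None = None) -> RepeatabilityResult:
    """Point repeatability R = sigma2_A / (sigma2_A + sigma2) with category.

    Categories: low (R < 0.25), moderate (0.25 <= R <= 0.5), high (R > 0.5).
    """
    tot = fit.sigma2_A + fit.sigma2
    if tot <= 0:
        raise ValueError("degenerate model: both variance components are zero")
    R = fit.sigma2_A / tot
    category = "low" if R < 0.25 else ("moderate" if R <= 0.5 else "high")
    if adjusted is None:
        adjusted = len(fit.spec.terms) > 0
    return RepeatabilityResult(
        R=float(R), adjusted=adjusted, category=category,
        sigma2_A=fit.sigma2_A, sigma2=fit.sigma2, fixed_terms=fit.spec.terms,
    )


def bootstrap_R(
    fit: LmmFit, data: pd.DataFrame, n_boot: int = 1000, seed: int | None = None
) -> RepeatabilityResult:
    """Parametric-bootstrap uncertainty for R.

    Responses are simulated from the fitted model (fixed part + new random
    intercepts and residuals), refitted with the same structure, and R is
    recomputed; se is the bootstrap SD, ci the 2.5/97.5 percentiles.
    """
    base = repeatability(fit)
    if n_boot <= 0:
        return base
    if n_boot < 100:
        logger.warning("n_boot=%d is small; intervals will be unstable", n_boot)
    rng = np.random.default_rng(seed)
    X, codes = fit.X, fit.group_codes
    mu = X @ fit.beta
    ng = codes.max() + 1
    Rs = np.empty(n_boot)
    n_fail = 0
    for b in range(n_boot):
        a = rng.normal(0.0, np.sqrt(fit.sigma2_A), size=ng)
        ystar = mu + a[codes] + rng.normal(0.0, np.sqrt(fit.sigma2), size=len(mu))
        _, s2a, s2e, _, conv = _fit_random_intercept(X, ystar, codes, reml=True)
        if not conv or (s2a + s2e) <= 0:
            n_fail += 1
            Rs[b] = np.nan
            continue
        Rs[b] = s2a / (s2a + s2e)
    if n_fail > 0.1 * n_boot:
        logger.warning("bootstrap non-convergence rate %.1f%%", 100.0 * n_fail / n_boot)
    Rs = Rs[np.isfinite(Rs)]
    base.se = float(np.std(Rs, ddof=1))
    base.ci = (float(np.percentile(Rs, 2.5)), float(np.percentile(Rs, 97.5)))
    return base


def adjusted_vs_nonadjusted(
    start: LmmSpec, data: pd.DataFrame, n_boot: int = 0, seed: int | None = None
) -> dict[str, RepeatabilityResult]:
    """Paired adjusted (AIC-selected fixed effects) and non-adjusted
    (intercept-only) repeatability for one response."""
    sel = select_fixed_effects(start, data)
    null_spec = replace(start, year=False, timing=False, interaction=False)
    null = fit_lmm(null_spec, data, reml=True)
    out = {}
    for key, f, adj in (("adjusted", sel, True), ("non_adjusted", null, False)):
        if n_boot > 0:
            r = bootstrap_R(f, data, n_boot=n_boot, seed=seed)
        else:
            r = repeatability(f)
        r.adjusted = adj
        out[key] = r
    return out


def repeatability_table(
    data: pd.DataFrame,
    responses: dict[str, bool] | None = None,
    n_boot: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Adjusted and non-adjusted R for every trait — the machine-readable
    twin of the repeatability figure."""
    responses = responses or {
        k: v for k, v in DEFAULT_RESPONSES.items() if k in data.columns
    }
    rows = []
    for resp, logt in responses.items():
        sub = data.dropna(subset=[resp])
        if len(sub) < len(data):
            logger.info("%s: %d row(s) without a value dropped", resp, len(data) - len(sub))
        start = LmmSpec(response=resp, log_transform=logt, year=True, timing=True, interaction=True)
        try:
            pair = adjusted_vs_nonadjusted(start, sub, n_boot=n_boot, seed=seed)
        except ValueError as exc:
            logger.warning("repeatability for %s skipped: %s", resp, exc)
            continue
        for key, r in pair.items():
            rows.append(
                {
                    "response": resp,
                    "adjusted": r.adjusted,
                    "R": r.R,
                    "se": r.se,
                    "ci_low": r.ci[0] if r.ci else None,
                    "ci_high": r.ci[1] if r.ci else None,
                    "sigma2_A": r.sigma2_A,
                    "sigma2": r.sigma2,
                    "category": r.category,
                    "fixed_terms": "+".join(r.fixed_terms) if r.fixed_terms else "1",
                }
            )
    return pd.DataFrame(rows)
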
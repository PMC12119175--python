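"""Count regressions with log link, trap-effort offset and a year random intercept.

Maximum-likelihood fitting of Poisson and negative-binomial (NB2) models.
The single random intercept is integrated out of the marginal likelihood by
adaptive Gauss-Hermite quadrature centred at the per-group conditional mode
(1 node = the Laplace approximation).  Optimisation is quasi-Newton on
``(beta, log sigma, log theta)`` with fixed deterministic starting values,
so fits are reproducible given the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess1

from habseg.errors import DataError, FitError

_ETA_CLIP = 30.0
_LOG_SIGMA_BOUNDS = (np.log(1e-8), np.log(50.0))
_LOG_THETA_BOUNDS = (np.log(1e-4), np.log(1e4))

INTERCEPT = "(Intercept)"


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response species, predictor terms, family, structure.

    ``predictors`` name z-scored columns of the data frame; an interaction
    term ``"a:b"`` is the elementwise product of columns ``a`` and ``b``.
    The offset is ``log(effort)``; the intercept is always included.
    """

    species: str
    predictors: tuple = ()
    family: str = "poisson"           # 'poisson' | 'negbin'
    random_intercept: str = "year"    # 'year' | 'none'
    offset_col: str = "effort"
    n_quad: int = 15

    def __post_init__(self):
        if self.family not in ("poisson", "negbin"):
            raise DataError(f"unknown family '{self.family}'")
        if self.random_intercept not in ("year", "none"):
            raise DataError(f"unknown random_intercept '{self.random_intercept}'")
        if len(set(self.predictors)) != len(self.predictors):
            raise DataError("predictors must be unique")
        mains = {p for p in self.predictors if ":" not in p}
        for p in self.predictors:
            if ":" in p:
                a, b = p.split(":", 1)
                if a not in mains or b not in mains:
                    raise DataError(
                        f"interaction '{p}' requires both main effects in the model")

    def with_predictors(self, predictors) -> "ModelSpec":
        return replace(self, predictors=tuple(predictors))


@dataclass
class FitResult:
    """A fitted count model: estimates, likelihood, criteria, diagnostics."""

    spec: ModelSpec
    coefficients: dict
    se: dict
    loglik: float
    aic: float
    aicc: float
    n_obs: int
    k: int
    sigma_year: Optional[float]
    theta: Optional[float]
    ranef: dict
    converged: bool
    message: str = ""
    # fitting frames retained for refits and diagnostics
    y: np.ndarray = field(default=None, repr=False)
    X: np.ndarray = field(default=None, repr=False)
    offset: np.ndarray = field(default=None, repr=False)
    group_codes: Optional[np.ndarray] = field(default=None, repr=False)
    group_levels: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def terms(self):
        return list(self.coefficients)

    def fitted_means(self, conditional: bool = True) -> np.ndarray:
        """Fitted means; conditional fits add the predicted year effects."""
        beta = np.array([self.coefficients[t] for t in self.terms])
        eta = self.X @ beta + self.offset
        if conditional and self.group_codes is not None and self.ranef:
            u = np.array([self.ranef[g] for g in self.group_levels])
            eta = eta + u[self.group_codes]
        return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))

    def to_frame(self) -> pd.DataFrame:
        """One row per term: estimate, SE, z, p (Wald)."""
        rows = []
        for t in self.terms:
            b, s = self.coefficients[t], self.se.get(t, np.nan)
            z = b / s if s and np.isfinite(s) and s > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append({"term": t, "estimate": b, "se": s, "z": z, "p": p})
        return pd.DataFrame(rows)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise DataError(f"AICc undefined: n={n} must exceed k+1={k + 1}")
    aic = -2.0 * loglik + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# log-densities and their eta-derivatives

def _poisson_logpmf(y, mu):
    return special.xlogy(y, mu) - mu - special.gammaln(y + 1)


def _nb_logpmf(y, mu, theta):
    return (special.gammaln(y + theta) - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + special.xlogy(y, mu / (theta + mu)))


def _dlogf_deta(y, mu, theta):
    if theta is None:
        return y - mu
    return (y - mu) * theta / (theta + mu)


def _d2logf_deta2(y, mu, theta):
    if theta is None:
        return -mu
    return -(y + theta) * theta * mu / (theta + mu) ** 2


def _logf(y, mu, theta):
    return _poisson_logpmf(y, mu) if theta is None else _nb_logpmf(y, mu, theta)


# ---------------------------------------------------------------------------
# marginal likelihood

def _group_modes(y, eta0, codes, n_groups, sigma2, theta, tol=1e-10, maxiter=100):
    """Conditional modes of the group random effects, vectorised Newton."""
    u = np.zeros(n_groups)
    for _ in range(maxiter):
        eta = np.clip(eta0 + u[codes], -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        g1 = np.bincount(codes, weights=_dlogf_deta(y, mu, theta),
                         minlength=n_groups) - u / sigma2
        g2 = np.bincount(codes, weights=_d2logf_deta2(y, mu, theta),
                         minlength=n_groups) - 1.0 / sigma2
        step = g1 / g2
        step = np.clip(step, -3.0, 3.0)
        u = u - step
        if np.max(np.abs(g1 * step)) < tol:
            break
    eta = np.clip(eta0 + u[codes], -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    h2 = np.bincount(codes, weights=_d2logf_deta2(y, mu, theta),
                     minlength=n_groups) - 1.0 / sigma2
    return u, h2


def marginal_loglik(y, X, offset, beta, sigma=None, theta=None,
                    group_codes=None, n_quad: int = 15) -> float:
    """Marginal log-likelihood, integrating the random intercept by AGHQ.

    With ``group_codes is None`` (or sigma None) this is the plain GLM
    log-likelihood.  ``n_quad=1`` gives the Laplace approximation.
    """
    y = np.asarray(y, dtype=float)
    eta0 = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
    if group_codes is None or sigma is None:
        return float(np.sum(_logf(y, np.exp(eta0), theta)))
    sigma = max(float(sigma), 1e-10)
    sigma2 = sigma**2
    n_groups = int(group_codes.max()) + 1
    u_hat, h2 = _group_modes(y, eta0, group_codes, n_groups, sigma2, theta)
    tau = 1.0 / np.sqrt(-h2)                      # h2 < 0 always
    x, w = hermgauss(max(int(n_quad), 1))
    # nodes: G x Q
    nodes = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * x[None, :]
    log_terms = np.empty((n_groups, len(x)))
    for j in range(len(x)):
        eta = np.clip(eta0 + nodes[group_codes, j], -_ETA_CLIP, _ETA_CLIP)
        ll_obs = _logf(y, np.exp(eta), theta)
        h = (np.bincount(group_codes, weights=ll_obs, minlength=n_groups)
             - nodes[:, j] ** 2 / (2.0 * sigma2))
        log_terms[:, j] = np.log(w[j]) + x[j] ** 2 + h
    log_Lg = (np.log(np.sqrt(2.0) * tau)
              - 0.5 * np.log(2.0 * np.pi * sigma2)
              + special.logsumexp(log_terms, axis=1))
    return float(np.sum(log_Lg))


# ---------------------------------------------------------------------------
# design construction

def build_design(spec: ModelSpec, df: pd.DataFrame):
    """Design matrix (intercept first), response, offset and group codes."""
    if spec.species not in df.columns:
        raise DataError(f"response column '{spec.species}' not found")
    n = len(df)
    cols = [np.ones(n)]
    names = [INTERCEPT]
    for term in spec.predictors:
        if ":" in term:
            a, b = term.split(":", 1)
            cols.append(df[a].to_numpy(dtype=float) * df[b].to_numpy(dtype=float))
        else:
            if term not in df.columns:
                raise DataError(f"predictor column '{term}' not found")
            cols.append(df[term].to_numpy(dtype=float))
        names.append(term)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the aliased terms via QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in range(len(names))
               if diag[j] < 1e-10 * max(diag.max(), 1.0)]
        raise FitError(f"rank-deficient design; aliased term(s): {bad or names}")
    y = df[spec.species].to_numpy(dtype=float)
    if np.any(y < 0):
        raise DataError("counts must be nonnegative")
    offset = np.log(df[spec.offset_col].to_numpy(dtype=float))
    if not np.all(np.isfinite(offset)):
        raise DataError("offset must be finite (effort >= 1)")
    if spec.random_intercept == "year":
        levels, codes = np.unique(df["year"].to_numpy(), return_inverse=True)
    else:
        levels, codes = None, None
    return y, X, names, offset, codes, levels


def _irls_poisson(y, X, offset, maxiter=100, tol=1e-10):
    """Poisson-GLM IRLS used for deterministic starting values."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-3)) - offset.mean()
    for _ in range(maxiter):
        eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        z = eta - offset + (y - mu) / mu
        W = mu
        XtW = X.T * W
        try:
            new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def fit_count_model(spec: ModelSpec, df: pd.DataFrame) -> FitResult:
    """Fit ``spec`` to ``df`` by maximum likelihood.

    Deterministic given the data: starting values are the Poisson-IRLS
    coefficients, sigma = 0.5, theta = 1.  Non-convergence is flagged on
    the result, never silent.
    """
    y, X, names, offset, codes, levels = build_design(spec, df)
    n, p = X.shape
    has_re = codes is not None
    has_theta = spec.family == "negbin"

    beta0 = _irls_poisson(y, X, offset)
    x0 = list(beta0)
    bounds = [(None, None)] * p
    if has_re:
        x0.append(np.log(0.5))
        bounds.append(_LOG_SIGMA_BOUNDS)
    if has_theta:
        x0.append(0.0)
        bounds.append(_LOG_THETA_BOUNDS)
    x0 = np.array(x0)

    def unpack(params):
        beta = params[:p]
        i = p
        sigma = None
        theta = None
        if has_re:
            sigma = np.exp(params[i]); i += 1
        if has_theta:
            theta = np.exp(params[i]); i += 1
        return beta, sigma, theta

    def negll(params):
        beta, sigma, theta = unpack(params)
        ll = marginal_loglik(y, X, offset, beta, sigma, theta,
                             group_codes=codes, n_quad=spec.n_quad)
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"ftol": 1e-12, "gtol": 1e-8,
                                     "maxiter": 500})
    beta, sigma, theta = unpack(res.x)
    loglik = -res.fun

    # Wald SEs from the numerical Hessian of the negative log-likelihood
    se = np.full(len(res.x), np.nan)
    converged = bool(res.success)
    message = str(res.message)
    try:
        H = approx_hess1(res.x, negll)
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
    except np.linalg.LinAlgError:
        message += "; Hessian not invertible (SEs unavailable)"

    k = p + (1 if has_re else 0) + (1 if has_theta else 0)
    coefficients = dict(zip(names, beta))
    se_map = dict(zip(names, se[:p]))
    ranef = {}
    if has_re:
        u_hat, _ = _group_modes(y, np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP),
                                codes, len(levels), max(sigma, 1e-10) ** 2, theta)
        ranef = {int(g): float(u) for g, u in zip(levels, u_hat)}

    try:
        crit_aicc = aicc(loglik, k, n)
    except DataError:
        crit_aicc = np.inf
    return FitResult(
        spec=spec, coefficients=coefficients, se=se_map, loglik=float(loglik),
        aic=-2.0 * loglik + 2.0 * k, aicc=crit_aicc, n_obs=n, k=k,
        sigma_year=float(sigma) if has_re else None,
        theta=float(theta) if has_theta else None,
        ranef=ranef, converged=converged, message=message,
        y=y, X=X, offset=offset, group_codes=codes, group_levels=levels,
    )


# ---------------------------------------------------------------------------
# tests and diagnostics

def lr_test(full: FitResult, reduced: FitResult):
    """Likelihood-ratio test of nested fits: (statistic, df, p)."""
    if full.spec.family != reduced.spec.family:
        raise DataError("LR test requires the same family")
    if full.spec.species != reduced.spec.species or full.n_obs != reduced.n_obs:
        raise DataError("LR test requires the same response and data")
    if not set(reduced.spec.predictors) <= set(full.spec.predictors):
        raise DataError("models are not nested")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = full.k - reduced.k
    if df <= 0:
        return stat, 0, 1.0
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def boundary_lr_test_sigma(fit_re: FitResult, fit_glm: FitResult):
    """LR test of sigma_year = 0 on the boundary: 0.5*chi2_0 + 0.5*chi2_1 mix."""
    stat = max(0.0, 2.0 * (fit_re.loglik - fit_glm.loglik))
    p = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, 1))
    return stat, p


@dataclass
class DiagnosticsReport:
    """Overdispersion and zero-inflation diagnostics of a count fit."""

    dispersion_ratio: float = np.nan
    dispersion_p: float = np.nan
    overdispersed: bool = False
    observed_zeros: int = 0
    expected_zeros: float = np.nan
    zero_ratio: float = np.nan
    zero_inflated: bool = False


def check_overdispersion(fit: FitResult, alpha: float = 0.05) -> DiagnosticsReport:
    """Pearson chi-square / df dispersion test of a (quasi-)Poisson fit."""
    mu = fit.fitted_means(conditional=True)
    if fit.n_obs <= fit.k:
        raise DataError("dispersion test needs n > k")
    v = mu if fit.theta is None else mu + mu**2 / fit.theta
    pearson = float(np.sum((fit.y - mu) ** 2 / np.maximum(v, 1e-12)))
    dof = fit.n_obs - fit.k
    ratio = pearson / dof
    p = float(stats.chi2.sf(pearson, dof))
    return DiagnosticsReport(
        dispersion_ratio=ratio, dispersion_p=p,
        overdispersed=bool(ratio > 1.0 and p < alpha),
    )


def check_zero_inflation(fit: FitResult, tol: float = 0.05) -> DiagnosticsReport:
    """Observed vs model-expected zero counts."""
    mu = fit.fitted_means(conditional=True)
    if fit.theta is None:
        p0 = np.exp(-mu)
    else:
        p0 = (fit.theta / (fit.theta + mu)) ** fit.theta
    expected = float(np.sum(p0))
    observed = int(np.sum(fit.y == 0))
    ratio = 0.0 if observed == 0 else observed / max(expected, 1e-12)
    return DiagnosticsReport(
        observed_zeros=observed, expected_zeros=expected, zero_ratio=ratio,
        zero_inflated=bool(ratio > 1.0 + tol),
    )


def select_family_and_structure(spec: ModelSpec, df: pd.DataFrame,
                                alpha: float = 0.05):
    """Decision cascade: Poisson -> NB on overdispersion; drop the year
    intercept when its boundary-corrected LR test is non-significant.

    Returns ``(final_spec, trail)`` where ``trail`` records each decision.
    """
    trail = []
    fit = fit_count_model(replace(spec, family="poisson"), df)
    disp = check_overdispersion(fit, alpha=alpha)
    family = "poisson"
    if disp.overdispersed:
        family = "negbin"
        fit = fit_count_model(replace(spec, family="negbin"), df)
    trail.append({"step": "family", "choice": family,
                  "dispersion_ratio": disp.dispersion_ratio,
                  "dispersion_p": disp.dispersion_p})
    random_intercept = spec.random_intercept
    if random_intercept == "year":
        glm_fit = fit_count_model(replace(spec, family=family,
                                          random_intercept="none"), df)
        stat, p = boundary_lr_test_sigma(fit, glm_fit)
        if p >= alpha:
            random_intercept = "none"
        trail.append({"step": "random_intercept", "choice": random_intercept,
                      "lr_stat": stat, "p": p})
    zi = check_zero_inflation(fit)
    trail.append({"step": "zero_inflation", "ratio": zi.zero_ratio,
                  "flag": zi.zero_inflated})
    return replace(spec, family=family, random_intercept=random_intercept), trail


def predict_response(fit: FitResult, variable: str, grid, effort: float = 100.0,
                     year=None) -> pd.DataFrame:
    """Predicted counts along one predictor, the others at z = 0.

    ``prediction = effort * exp(b0 + beta_v * z + u_year)``.
    """
    if variable not in fit.coefficients:
        raise DataError(f"variable '{variable}' is not in the fitted model")
    grid = np.asarray(grid, dtype=float)
    b0 = fit.coefficients[INTERCEPT]
    bv = fit.coefficients[variable]
    u = 0.0
    if year is not None:
        if int(year) not in fit.ranef:
            raise DataError(f"year {year} has no predicted random effect")
        u = fit.ranef[int(year)]
    pred = effort * np.exp(b0 + bv * grid + u)
    return pd.DataFrame({"z": grid, "predicted": pred})


def simulate_from_fit(fit: FitResult, rng: np.random.Generator,
                      new_ranef: bool = True) -> np.ndarray:
    """Parametric-bootstrap draw of the response from a fitted model."""
    beta = np.array([fit.coefficients[t] for t in fit.terms])
    eta = fit.X @ beta + fit.offset
    if fit.group_codes is not None and fit.sigma_year is not None:
        if new_ranef:
            u = rng.normal(0.0, fit.sigma_year, size=len(fit.group_levels))
        else:
            u = np.array([fit.ranef[int(g)] for g in fit.group_levels])
        eta = eta + u[fit.group_codes]
    mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    if fit.theta is None:
        return rng.poisson(mu)
    return rng.poisson(rng.gamma(fit.theta, mu / fit.theta))
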
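"""Variance explained and its partition into contrasting vs. shared effects.

The model r2 is a marginal (fixed-effects) latent-scale r2 for log-link
count models: ``var(X beta) / (var(X beta) + sigma_year^2 + residual)``,
where the observation-level residual variance uses the lognormal
approximation ``ln(1 + 1/lambda)`` (Poisson) or ``ln(1 + 1/lambda + 1/theta)``
(NB2), with ``lambda = exp(mean linear predictor + mean offset)``; a delta-
method variant is available.  Partial r2 of a variable group is the drop in
r2 when the group is removed and the reduced model refitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from habseg.errors import DataError
from habseg.glmm import (FitResult, fit_count_model, lr_test, simulate_from_fit)


def _fixed_effects_variance(fit: FitResult) -> float:
    beta = np.array([fit.coefficients[t] for t in fit.terms])
    eta_fixed = fit.X[:, 1:] @ beta[1:]       # exclude intercept and offset
    return float(np.var(eta_fixed, ddof=1)) if fit.X.shape[1] > 1 else 0.0


def residual_variance(fit: FitResult, method: str = "lognormal") -> float:
    """Observation-level latent-scale variance of a log-link count model."""
    beta = np.array([fit.coefficients[t] for t in fit.terms])
    lam = float(np.exp(np.mean(fit.X @ beta + fit.offset)))
    inv = 1.0 / lam + (1.0 / fit.theta if fit.theta is not None else 0.0)
    if method == "lognormal":
        return float(np.log1p(inv))
    if method == "delta":
        return float(inv)
    raise DataError(f"unknown residual-variance method '{method}'")


def model_r2(fit: FitResult, method: str = "lognormal") -> float:
    """Marginal r2 of the fixed effects on the latent (log) scale."""
    var_f = _fixed_effects_variance(fit)
    sigma2 = (fit.sigma_year or 0.0) ** 2
    return var_f / (var_f + sigma2 + residual_variance(fit, method))


def partial_r2(full_fit: FitResult, subset, df: pd.DataFrame,
               method: str = "lognormal") -> float:
    """r2(full) - r2(full minus subset), refitting the reduced model.

    Floored at 0: finite-sample refits can invert the nesting inequality
    slightly.
    """
    subset = set(subset)
    if not subset:
        return 0.0
    if not subset <= set(full_fit.spec.predictors):
        raise DataError(f"subset {sorted(subset)} not contained in the model")
    reduced_spec = full_fit.spec.with_predictors(
        tuple(v for v in full_fit.spec.predictors if v not in subset))
    reduced = fit_count_model(reduced_spec, df)
    return max(0.0, model_r2(full_fit, method) - model_r2(reduced, method))


def per_variable_partial_r2(fit: FitResult, df: pd.DataFrame,
                            method: str = "lognormal") -> dict:
    """Partial r2 of each predictor of ``fit``, one at a time."""
    return {v: partial_r2(fit, {v}, df, method) for v in fit.spec.predictors}


def contrast_share(contrasting_r2: float, total_r2: float) -> float:
    """Share (percent) of explained variation due to the contrasting group.

    Inputs may be proportions or percents, as long as they share a scale.
    """
    if total_r2 <= 0:
        raise DataError("total explained variation must be positive")
    return 100.0 * contrasting_r2 / total_r2


@dataclass
class ContrastPartition:
    """Per-species contrasting/shared classification and variance shares."""

    contrasting: list
    shared: list
    significance: dict        # species -> {variable: p}
    model_r2: dict            # species -> r2
    contrasting_r2: dict      # species -> group partial r2
    shared_r2: dict
    share_pct: dict           # species -> 100 * contrasting_r2 / model_r2


def _term_pvalues(fit: FitResult, df: pd.DataFrame) -> dict:
    out = {}
    for v in fit.spec.predictors:
        reduced = fit_count_model(
            fit.spec.with_predictors(
                tuple(t for t in fit.spec.predictors if t != v)), df)
        _, _, p = lr_test(fit, reduced)
        out[v] = p
    return out


def contrast_partition(fit_a: FitResult, fit_c: FitResult, df: pd.DataFrame,
                       alpha: float = 0.05,
                       method: str = "lognormal") -> ContrastPartition:
    """Partition explained variance into contrasting vs. shared variables.

    A variable is *contrasting* when it is significant in exactly one
    species, or in both with opposite coefficient signs; *shared* when
    significant in both with the same sign.  Classification is symmetric
    in species order.
    """
    sp_a, sp_c = fit_a.spec.species, fit_c.spec.species
    p_a = _term_pvalues(fit_a, df)
    p_c = _term_pvalues(fit_c, df)
    sig_a = {v for v, p in p_a.items() if p < alpha}
    sig_c = {v for v, p in p_c.items() if p < alpha}
    contrasting, shared = [], []
    for v in sorted(sig_a | sig_c):
        if v in sig_a and v in sig_c:
            same = fit_a.coefficients[v] * fit_c.coefficients[v] > 0
            (shared if same else contrasting).append(v)
        else:
            contrasting.append(v)
    out = ContrastPartition(
        contrasting=contrasting, shared=shared,
        significance={sp_a: p_a, sp_c: p_c},
        model_r2={}, contrasting_r2={}, shared_r2={}, share_pct={})
    for fit, sp in ((fit_a, sp_a), (fit_c, sp_c)):
        r2 = model_r2(fit, method)
        cvars = [v for v in contrasting if v in fit.spec.predictors]
        svars = [v for v in shared if v in fit.spec.predictors]
        cr2 = partial_r2(fit, cvars, df, method) if cvars else 0.0
        sr2 = partial_r2(fit, svars, df, method) if svars else 0.0
        out.model_r2[sp] = r2
        out.contrasting_r2[sp] = cr2
        out.shared_r2[sp] = sr2
        out.share_pct[sp] = contrast_share(cr2, r2) if r2 > 0 else 0.0
    return out


def r2_ci(fit: FitResult, n_boot: int = 1000, seed: int = 0,
          method: str = "lognormal", level: float = 0.95):
    """Parametric-bootstrap percentile CI for the model r2.

    Simulates responses from the fitted model, refits, recomputes r2.
    Refit failures are dropped (counted); more than 20% failures is an
    error.  Seed-deterministic.
    """
    if n_boot < 100:
        raise DataError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    draws = []
    failures = 0
    for _ in range(n_boot):
        y_sim = simulate_from_fit(fit, rng)
        df_sim = pd.DataFrame(fit.X[:, 1:], columns=list(fit.terms)[1:])
        df_sim[fit.spec.species] = y_sim
        df_sim[fit.spec.offset_col] = np.exp(fit.offset)
        if fit.group_levels is not None:
            df_sim["year"] = fit.group_levels[fit.group_codes]
        try:
            refit = fit_count_model(fit.spec, df_sim)
            draws.append(model_r2(refit, method))
        except Exception:
            failures += 1
    if failures > 0.2 * n_boot:
        raise DataError(f"{failures}/{n_boot} bootstrap refits failed")
    lo, hi = np.percentile(draws, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi), failures
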
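"""Interspecific-competition tests: competitor-augmented habitat models.

The focal species' best habitat model is refitted with the competitor's
standardised trapping rate as an extra predictor (LR-tested against the
habitat-only model), then with one habitat-by-competitor interaction at a
time (Holm-adjusted).  Running both directions yields an asymmetry label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from habseg import dataprep
from habseg.errors import DataError
from habseg.glmm import FitResult, fit_count_model, lr_test
from habseg.partition import model_r2, partial_r2


@dataclass
class CompetitionResult:
    """Effect of the competitor's abundance on the focal species."""

    focal: str
    competitor: str
    b: float
    se: float
    chi2: float
    df: int
    p: float
    share: float                    # competitor partial r2 / model r2
    direction: str                  # 'suppression' | 'facilitation' | 'none'
    interactions: pd.DataFrame = field(default=None, repr=False)
    habitat_fit: FitResult = field(default=None, repr=False)
    augmented_fit: FitResult = field(default=None, repr=False)


def competitor_column(df: pd.DataFrame, competitor_species: str,
                      standardise: bool = True) -> np.ndarray:
    """Competitor abundance predictor: z-scored trapping rate per 100 tn."""
    col = (competitor_species if competitor_species.startswith("count_")
           else f"count_{competitor_species}")
    rate = dataprep.trapping_rate(df[col].to_numpy(), df["effort"].to_numpy())
    if not standardise:
        return rate
    if np.std(rate, ddof=1) == 0:
        raise DataError("competitor trapping rate is constant")
    z, _, _ = dataprep.zscore(rate)
    return z


def fit_competition_model(habitat_fit: FitResult, competitor_species: str,
                          df: pd.DataFrame, alpha: float = 0.05,
                          standardise: bool = True) -> CompetitionResult:
    """Augment the focal best habitat model with the competitor term."""
    comp_name = (f"comp_{competitor_species}")
    work = df.copy()
    work[comp_name] = competitor_column(df, competitor_species, standardise)

    base_spec = habitat_fit.spec
    base = fit_count_model(base_spec, work)
    aug_spec = base_spec.with_predictors(base_spec.predictors + (comp_name,))
    aug = fit_count_model(aug_spec, work)
    chi2, dof, p = lr_test(aug, base)
    b = aug.coefficients[comp_name]
    se = aug.se.get(comp_name, float("nan"))
    r2 = model_r2(aug)
    share = partial_r2(aug, {comp_name}, work) / r2 if r2 > 0 else 0.0
    if p < alpha:
        direction = "suppression" if b < 0 else "facilitation"
    else:
        direction = "none"

    rows = []
    habitat_terms = [v for v in base_spec.predictors if ":" not in v]
    for h in habitat_terms:
        inter_spec = aug_spec.with_predictors(
            aug_spec.predictors + (f"{comp_name}:{h}",))
        try:
            inter = fit_count_model(inter_spec, work)
            s, d, pv = lr_test(inter, aug)
        except Exception as exc:    # rank deficiency etc.: logged, not fatal
            s, d, pv = float("nan"), 1, float("nan")
        rows.append({"interaction": f"{comp_name}:{h}", "chi2": s,
                     "df": d, "p": pv})
    inter_df = pd.DataFrame(rows)
    if len(inter_df):
        # Holm step-down adjustment across the one-at-a-time tests
        order = np.argsort(inter_df["p"].to_numpy())
        m = len(inter_df)
        adj = np.full(m, np.nan)
        running = 0.0
        for rank, idx in enumerate(order):
            pv = inter_df["p"].iloc[idx]
            if np.isnan(pv):
                continue
            running = max(running, min(1.0, (m - rank) * pv))
            adj[idx] = running
        inter_df["p_holm"] = adj
        inter_df["significant"] = inter_df["p_holm"] < alpha
    return CompetitionResult(
        focal=base_spec.species, competitor=competitor_species,
        b=float(b), se=float(se), chi2=float(chi2), df=dof, p=float(p),
        share=float(min(max(share, 0.0), 1.0)), direction=direction,
        interactions=inter_df, habitat_fit=base, augmented_fit=aug)


def asymmetry_report(result_a_on_c: CompetitionResult,
                     result_c_on_a: CompetitionResult,
                     alpha: float = 0.05) -> dict:
    """Cross the two directional tests into a symmetry label.

    ``result_a_on_c`` is the effect of species A's abundance on species C
    (C is the focal response), and vice versa.
    """
    sig_on_c = result_a_on_c.p < alpha
    sig_on_a = result_c_on_a.p < alpha
    if sig_on_c and sig_on_a:
        label = "symmetric"
        suppressed = None
    elif sig_on_c or sig_on_a:
        label = "asymmetric"
        suppressed = (result_a_on_c.focal if sig_on_c else result_c_on_a.focal)
    else:
        label = "none"
        suppressed = None
    return {
        "label": label,
        "suppressed_species": suppressed,
        "effect_on": {
            result_a_on_c.focal: {"b": result_a_on_c.b, "se": result_a_on_c.se,
                                  "chi2": result_a_on_c.chi2, "p": result_a_on_c.p,
                                  "share": result_a_on_c.share,
                                  "direction": result_a_on_c.direction},
            result_c_on_a.focal: {"b": result_c_on_a.b, "se": result_c_on_a.se,
                                  "chi2": result_c_on_a.chi2, "p": result_c_on_a.p,
                                  "share": result_c_on_a.share,
                                  "direction": result_c_on_a.direction},
        },
    }
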
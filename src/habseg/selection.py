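"""AICc multimodel inference over habitat-predictor subsets.

Enumerates all main-effect subsets of the candidate variables (intercept
always included), ranks them by AICc, forms the ``delta AICc < 2`` competing
set with renormalised Akaike weights, averages coefficients across the set
(full or conditional mode) and reduces the ranking to the best model
containing only significant predictors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import pandas as pd

from habseg.errors import DataError
from habseg.glmm import FitResult, ModelSpec, fit_count_model, lr_test

MAX_CANDIDATES = 15


@dataclass
class ModelTable:
    """All fitted subsets, ranked by AICc ascending."""

    base_spec: ModelSpec
    fits: dict = field(default_factory=dict)     # frozenset(predictors) -> FitResult
    ranked: list = field(default_factory=list)   # FitResults, best first

    def fit_subset(self, df: pd.DataFrame, subset) -> FitResult:
        key = frozenset(subset)
        if key not in self.fits:
            spec = self.base_spec.with_predictors(sorted(subset))
            self.fits[key] = fit_count_model(spec, df)
        return self.fits[key]

    def to_frame(self) -> pd.DataFrame:
        best = self.ranked[0].aicc if self.ranked else math.nan
        rows = []
        for f in self.ranked:
            rows.append({
                "model": "+".join(f.spec.predictors) or "1",
                "k": f.k, "logLik": f.loglik, "AICc": f.aicc,
                "delta_AICc": f.aicc - best,
            })
        return pd.DataFrame(rows)


def enumerate_and_rank(candidate_variables, df: pd.DataFrame,
                       base_spec: ModelSpec) -> ModelTable:
    """Fit all 2^p main-effect subsets and rank them by AICc.

    Ties are broken by fewer parameters, then by the lexicographic
    predictor string, so the ranking does not depend on fit order.
    """
    candidates = list(candidate_variables)
    if len(candidates) > MAX_CANDIDATES:
        raise DataError(
            f"{len(candidates)} candidate variables exceed the 2^p guard "
            f"({MAX_CANDIDATES}); restrict the candidate list")
    table = ModelTable(base_spec=base_spec)
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            table.fit_subset(df, subset)
    table.ranked = sorted(
        table.fits.values(),
        key=lambda f: (f.aicc, f.k, "+".join(sorted(f.spec.predictors))))
    return table


@dataclass
class CompetingSet:
    """Models within ``delta AICc < threshold`` of the best, with weights."""

    fits: list                 # FitResults, best first
    deltas: list
    weights: list              # renormalised within the set
    reference_aicc: float

    def __len__(self):
        return len(self.fits)


def competing_set(table: ModelTable, threshold: float = 2.0) -> CompetingSet:
    """Retain models with AICc - min(AICc) strictly below ``threshold``."""
    if not table.ranked:
        raise DataError("empty model table")
    best = table.ranked[0].aicc
    kept = [f for f in table.ranked if f.aicc - best < threshold]
    deltas = [f.aicc - best for f in kept]
    raw = [math.exp(-d / 2.0) for d in deltas]
    total = sum(raw)
    return CompetingSet(kept, deltas, [r / total for r in raw], best)


@dataclass
class AveragedCoefficients:
    """Model-averaged coefficients over a competing set.

    Variables absent from every competing model get exactly 0 (matching
    the convention of printing zeros for never-selected variables).
    """

    coefficients: dict         # variable -> averaged beta
    se: dict                   # variable -> unconditional SE
    mode: str


def average_coefficients(cs: CompetingSet, mode: str = "full",
                         variables=None) -> AveragedCoefficients:
    """Akaike-weighted coefficient averaging.

    ``full`` substitutes 0 for a variable absent from a model; conditional
    averages only over the models containing it.  The unconditional SE is
    ``sum_i w_i * sqrt(se_i^2 + (b_i - bbar)^2)`` (with zeros in full mode).
    """
    if mode not in ("full", "conditional"):
        raise DataError(f"unknown averaging mode '{mode}'")
    if variables is None:
        variables = sorted({v for f in cs.fits for v in f.spec.predictors})
    out_b, out_se = {}, {}
    for v in variables:
        entries = []  # (weight, beta, se)
        for w, f in zip(cs.weights, cs.fits):
            if v in f.spec.predictors:
                entries.append((w, f.coefficients[v], f.se.get(v, 0.0)))
            elif mode == "full":
                entries.append((w, 0.0, 0.0))
        if not entries:
            out_b[v], out_se[v] = 0.0, 0.0
            continue
        wtot = sum(w for w, _, _ in entries)
        bbar = sum(w * b for w, b, _ in entries) / wtot
        sebar = sum(w * math.sqrt((s or 0.0) ** 2 + (b - bbar) ** 2)
                    for w, b, s in entries) / wtot
        out_b[v], out_se[v] = bbar, sebar
    return AveragedCoefficients(out_b, out_se, mode)


def predictor_lr_pvalues(fit: FitResult, table: ModelTable,
                         df: pd.DataFrame) -> dict:
    """Per-predictor LR-test p-values, dropping each term in turn.

    Reduced fits are reused from the enumeration cache when available.
    """
    out = {}
    for v in fit.spec.predictors:
        reduced = table.fit_subset(df, set(fit.spec.predictors) - {v})
        _, _, p = lr_test(fit, reduced)
        out[v] = p
    return out


def best_significant_model(table: ModelTable, df: pd.DataFrame,
                           alpha: float = 0.05, threshold: float = 2.0):
    """The best-ranked model whose predictors are all LR-significant.

    Walks the competing set from the top; if no member qualifies, applies
    backward elimination from the top model (iteratively dropping the
    largest-p predictor).  Returns ``(FitResult, path)`` where ``path``
    logs every step taken.
    """
    cs = competing_set(table, threshold=threshold)
    path = []
    for f in cs.fits:
        ps = predictor_lr_pvalues(f, table, df)
        ok = all(p < alpha for p in ps.values())
        path.append({"step": "scan", "model": "+".join(f.spec.predictors) or "1",
                     "p_values": ps, "all_significant": ok})
        if ok:
            return f, path
    current = cs.fits[0]
    while current.spec.predictors:
        ps = predictor_lr_pvalues(current, table, df)
        worst = max(ps, key=ps.get)
        if ps[worst] < alpha:
            path.append({"step": "backward_stop",
                         "model": "+".join(current.spec.predictors)})
            return current, path
        path.append({"step": "backward_drop", "dropped": worst, "p": ps[worst]})
        current = table.fit_subset(df, set(current.spec.predictors) - {worst})
    path.append({"step": "terminus", "model": "1"})
    return current, path
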
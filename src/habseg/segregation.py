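"""Weighted Euclidean habitat-segregation distance and its jackknife inference.

The two species' habitat responses are summarised as averaged coefficients
over the AICc competing set, weighted by per-variable partial r2.  The
stated weighting is under-determined, so several conventions are
implemented and reported side by side; the default weights the squared
coefficient differences by the species-mean partial r2 (proportion scale).
Inference uses a paired jackknife over all LOW x HIGH transect deletions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from habseg import dataprep
from habseg.errors import DataError
from habseg.glmm import ModelSpec
from habseg.partition import partial_r2
from habseg.selection import (average_coefficients, competing_set,
                              enumerate_and_rank)

#: Implemented weighting conventions for the distance.
CONVENTIONS = ("mean-weight", "coord-weight", "coord-sqrt-weight",
               "normalised")

#: Censored "< 1" partial-r2 entries in printed tables map to this percent.
CENSORED_PARTIAL_R2_PCT = 0.5


@dataclass
class ResponseVector:
    """One species' position in habitat-response space within a stratum."""

    species: str
    stratum: str
    names: tuple
    beta: np.ndarray           # averaged coefficients
    weight: np.ndarray         # partial r2, proportion scale, >= 0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if np.any(self.weight < 0):
            raise DataError("negative partial-r2 weight")
        if len(self.names) != len(self.beta) or len(self.beta) != len(self.weight):
            raise DataError("names, beta and weight must be aligned")


def _align(a: ResponseVector, c: ResponseVector):
    """Align two vectors on the union of their variables, 0-filled."""
    if not (set(a.names) & set(c.names)):
        raise DataError("response vectors share no variables")
    names = sorted(set(a.names) | set(c.names))
    def expand(v):
        idx = {n: i for i, n in enumerate(v.names)}
        b = np.array([v.beta[idx[n]] if n in idx else 0.0 for n in names])
        w = np.array([v.weight[idx[n]] if n in idx else 0.0 for n in names])
        return b, w
    ba, wa = expand(a)
    bc, wc = expand(c)
    return names, ba, wa, bc, wc


def weighted_distance(a: ResponseVector, c: ResponseVector,
                      convention: str = "mean-weight") -> float:
    """Partial-r2-weighted Euclidean distance between two response vectors.

    Conventions:

    - ``mean-weight`` (default): ``sqrt(sum_v wbar_v (bA - bC)^2)`` with
      ``wbar = (wA + wC)/2`` on the proportion scale;
    - ``coord-weight``: per-species weighted coordinates ``b*w`` before an
      unweighted Euclidean distance;
    - ``coord-sqrt-weight``: coordinates ``b*sqrt(w)``;
    - ``normalised``: as ``mean-weight`` with weights rescaled to sum 1.
    """
    _, ba, wa, bc, wc = _align(a, c)
    if convention == "mean-weight":
        w = (wa + wc) / 2.0
        return float(np.sqrt(np.sum(w * (ba - bc) ** 2)))
    if convention == "coord-weight":
        return float(np.sqrt(np.sum((ba * wa - bc * wc) ** 2)))
    if convention == "coord-sqrt-weight":
        return float(np.sqrt(np.sum((ba * np.sqrt(wa) - bc * np.sqrt(wc)) ** 2)))
    if convention == "normalised":
        w = (wa + wc) / 2.0
        tot = w.sum()
        if tot <= 0:
            raise DataError("all weights are zero")
        return float(np.sqrt(np.sum(w / tot * (ba - bc) ** 2)))
    raise DataError(f"unknown weighting convention '{convention}'")


def distance_table(a: ResponseVector, c: ResponseVector) -> dict:
    """The distance under every implemented convention."""
    return {conv: weighted_distance(a, c, conv) for conv in CONVENTIONS}


def species_response(df_stratum: pd.DataFrame, species: str, candidates,
                     stratum: str = "", family: str = "poisson",
                     random_intercept: str = "year",
                     threshold: float = 2.0) -> ResponseVector:
    """Per-stratum pipeline: selection -> averaging -> partial-r2 weights.

    Predictors are z-scored within the stratum.  Averaged coefficients come
    from the competing set (full averaging); the weight of each selected
    variable is its partial r2 in the refitted union model (variables never
    selected keep coefficient and weight 0).
    """
    zdf = dataprep.standardize_frame(df_stratum, candidates)
    base = ModelSpec(species=f"count_{species}" if not species.startswith("count_")
                     else species,
                     family=family, random_intercept=random_intercept)
    table = enumerate_and_rank(candidates, zdf, base)
    cs = competing_set(table, threshold=threshold)
    avg = average_coefficients(cs, mode="full", variables=list(candidates))
    union_vars = sorted({v for f in cs.fits for v in f.spec.predictors})
    weights = {v: 0.0 for v in candidates}
    if union_vars:
        union_fit = table.fit_subset(zdf, union_vars)
        for v in union_vars:
            weights[v] = partial_r2(union_fit, {v}, zdf)
    names = tuple(candidates)
    return ResponseVector(
        species=species, stratum=stratum, names=names,
        beta=np.array([avg.coefficients[v] for v in names]),
        weight=np.array([weights[v] for v in names]))


@dataclass
class DistanceReport:
    """Point distances, the paired jackknife sample and its inference."""

    d_low: float
    d_high: float
    pairs: np.ndarray = field(repr=False)   # n_pairs x 2: (d_low, d_high)
    n_low: int = 0
    n_high: int = 0
    failed_pairs: int = 0
    mean_low: float = math.nan
    mean_high: float = math.nan
    ci_low: tuple = (math.nan, math.nan)
    ci_high: tuple = (math.nan, math.nan)
    t: float = math.nan
    df: int = 0
    p: float = math.nan
    mean_diff: float = math.nan
    ci_diff: tuple = (math.nan, math.nan)
    constant_differences: bool = False


def jackknife_distances(low_df: pd.DataFrame, high_df: pd.DataFrame,
                        distance_fn) -> DistanceReport:
    """Paired jackknife over all LOW x HIGH single-transect deletions.

    ``distance_fn(stratum_df) -> float`` reruns the per-stratum pipeline.
    The LOW deletion distance does not depend on the HIGH deletion (and
    vice versa), so each stratum is recomputed once per deleted transect
    and the |LOW| x |HIGH| pairs are formed from the two vectors.  A failed
    refit excludes every pair involving that deletion; more than 5%
    excluded pairs is an error.
    """
    n_low, n_high = len(low_df), len(high_df)
    if n_low < 3 or n_high < 3:
        raise DataError("each stratum needs >= 3 transects for the jackknife")
    d_low0 = distance_fn(low_df)
    d_high0 = distance_fn(high_df)

    def loo(df):
        vals, ok = [], []
        for i in range(len(df)):
            try:
                vals.append(distance_fn(df.drop(df.index[i])))
                ok.append(True)
            except Exception:
                vals.append(math.nan)
                ok.append(False)
        return np.array(vals), np.array(ok)

    dl, ok_l = loo(low_df)
    dh, ok_h = loo(high_df)
    pairs = np.array([(dl[i], dh[k])
                      for i, k in itertools.product(range(n_low), range(n_high))
                      if ok_l[i] and ok_h[k]])
    failed = n_low * n_high - len(pairs)
    if failed > 0.05 * n_low * n_high:
        raise DataError(f"{failed} of {n_low * n_high} jackknife pairs failed")
    report = DistanceReport(d_low=d_low0, d_high=d_high0, pairs=pairs,
                            n_low=n_low, n_high=n_high, failed_pairs=failed)
    return jackknife_ci_and_test(report)


def jackknife_ci_and_test(report: DistanceReport,
                          level: float = 0.95) -> DistanceReport:
    """Percentile CIs of the jackknife distances and a paired one-sample t.

    The paired deletions are treated as independent samples (df = n_pairs
    - 1), matching the convention of reporting df = |LOW| x |HIGH| - 1;
    jackknife replicates are not truly independent, so the t is anti-
    conservative.  ``p`` is one-sided for "difference larger than 0".
    """
    pairs = report.pairs
    if len(pairs) < 3:
        raise DataError("need >= 3 jackknife pairs")
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    report.mean_low = float(pairs[:, 0].mean())
    report.mean_high = float(pairs[:, 1].mean())
    report.ci_low = tuple(np.percentile(pairs[:, 0], [lo_q, hi_q]))
    report.ci_high = tuple(np.percentile(pairs[:, 1], [lo_q, hi_q]))
    diff = pairs[:, 0] - pairs[:, 1]
    report.mean_diff = float(diff.mean())
    report.ci_diff = tuple(np.percentile(diff, [lo_q, hi_q]))
    report.df = len(diff) - 1
    sd = diff.std(ddof=1)
    if sd == 0:
        report.constant_differences = True
        report.t = math.inf if diff.mean() > 0 else (-math.inf if diff.mean() < 0 else 0.0)
        report.p = 0.0 if diff.mean() > 0 else 1.0
    else:
        report.t = float(diff.mean() / (sd / math.sqrt(len(diff))))
        report.p = float(stats.t.sf(report.t, report.df))
    return report


def jackknife_pair_count(n_low: int, n_high: int) -> int:
    """Number of paired single-deletion combinations: |LOW| x |HIGH|."""
    return sum(1 for _ in itertools.product(range(n_low), range(n_high)))


def wilcoxon_rank_sum(group1, group2, alternative: str = "two-sided"):
    """Wilcoxon rank-sum / Mann-Whitney test with midranks for ties.

    Returns ``(W, p)`` where W is the Mann-Whitney U of ``group1`` (the
    rank sum of group1 minus its minimum).  The p-value is exact (full
    enumeration) when n1 + n2 <= 12 and there are no ties, and uses the
    normal approximation with tie correction otherwise.  The exact
    two-sided p counts labelings at least as far from the null mean.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("both groups must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)          # midranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    has_ties = len(np.unique(pooled)) < len(pooled)

    if n1 + n2 <= 12 and not has_ties:
        n = n1 + n2
        dist = [sum(c) - n1 * (n1 + 1) / 2.0
                for c in itertools.combinations(range(1, n + 1), n1)]
        dist = np.array(dist)
        total = len(dist)
        if alternative == "two-sided":
            p = np.sum(np.abs(dist - mu) >= abs(u1 - mu) - 1e-12) / total
        elif alternative == "greater":
            p = np.sum(dist >= u1 - 1e-12) / total
        elif alternative == "less":
            p = np.sum(dist <= u1 + 1e-12) / total
        else:
            raise DataError(f"unknown alternative '{alternative}'")
        return float(u1), float(min(p, 1.0))

    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(u1), 1.0
    sd = math.sqrt(var)
    if alternative == "two-sided":
        z = (abs(u1 - mu) - 0.5) / sd       # continuity correction
        p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    elif alternative == "greater":
        z = (u1 - mu - 0.5) / sd
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        z = (u1 - mu + 0.5) / sd
        p = float(stats.norm.cdf(z))
    else:
        raise DataError(f"unknown alternative '{alternative}'")
    return float(u1), float(p)


def read_coefficient_table(path, censored_pct: float = CENSORED_PARTIAL_R2_PCT):
    """Ingest a printed coefficient/weight table (long CSV).

    Expected columns: ``variable, stratum, species, beta, partial_r2_pct``.
    ``partial_r2_pct`` entries of ``<1`` (censored prints) map to
    ``censored_pct``; weights are converted to the proportion scale.
    Returns ``{stratum: {species: ResponseVector}}``.
    """
    df = pd.read_csv(path, dtype={"partial_r2_pct": str})
    out: dict = {}
    for (stratum, species), grp in df.groupby(["stratum", "species"]):
        names = tuple(grp["variable"])
        beta = grp["beta"].to_numpy(dtype=float)
        w = np.array([
            censored_pct if str(v).strip().startswith("<") else float(v)
            for v in grp["partial_r2_pct"]]) / 100.0
        out.setdefault(stratum, {})[species] = ResponseVector(
            species=species, stratum=stratum, names=names, beta=beta, weight=w)
    return out
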
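"""Reading, validating and preparing transect trapping tables.

A transect record is one transect-year observation: identifiers, survey
year, trapping effort (trap-nights), per-species capture counts (recaptures
excluded) and habitat covariates.  This module owns the CSV schema, z-score
standardisation, trapping-rate computation, collinearity screening
(Spearman + VIF) and the elevation / year-parity dataset splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from habseg.errors import DataError

#: Fixed CSV column order (header mandatory, comma-separated, UTF-8).
COLUMNS = [
    "transect_id", "site_id", "year", "effort", "elevation", "dwat",
    "hheight", "hcov", "scov", "tcov", "con", "moist", "rocks", "logs",
    "count_af", "count_cg",
]

#: Habitat predictors in canonical order.
PREDICTORS = [
    "elevation", "dwat", "hheight", "hcov", "scov", "tcov", "con",
    "moist", "rocks", "logs",
]

#: Count columns, one per species (af = mouse, cg = vole).
SPECIES_COLUMNS = ["count_af", "count_cg"]

_INT_COLUMNS = ["year", "effort", "moist", "rocks", "logs", "count_af", "count_cg"]

#: (low, high) inclusive bounds for range-checked fields.
_RANGES = {
    "effort": (1, None),
    "hcov": (0, 100),
    "scov": (0, 100),
    "tcov": (0, 100),
    "con": (0, 100),
    "moist": (1, 4),
    "rocks": (0, 4),
    "logs": (0, 4),
    "count_af": (0, None),
    "count_cg": (0, None),
}

#: Default elevation cut (m) separating the LOW and HIGH strata.
ELEVATION_CUT = 1300.0


def trapping_rate(count, effort):
    """Capture rate per 100 trap-nights: ``100 * count / effort``.

    Accepts scalars or arrays; ``effort`` must be >= 1 everywhere.
    """
    count = np.asarray(count, dtype=float)
    effort = np.asarray(effort, dtype=float)
    if np.any(effort < 1):
        raise DataError("effort must be >= 1 trap-night")
    out = 100.0 * count / effort
    return float(out) if out.ndim == 0 else out


def capture_share(species_counts, total_count):
    """Percent of all captured individuals belonging to the given species.

    ``species_counts`` is an iterable of per-species totals; the result is
    ``100 * sum(species_counts) / total_count``.
    """
    total_count = float(total_count)
    if total_count <= 0:
        raise DataError("total_count must be positive")
    return 100.0 * float(np.sum(species_counts)) / total_count


def zscore(values):
    """Standardise to mean 0, sample SD 1 (n-1 denominator).

    Returns ``(z, mean, sd)``.  A constant vector has no z-score
    representation and raises :class:`DataError`.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DataError("zscore requires a 1-d vector of length >= 2")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DataError("degenerate predictor: zero variance")
    return (x - mean) / sd, float(mean), float(sd)


@dataclass
class StandardizedMatrix:
    """Z-scored predictor matrix plus the per-column means and SDs used."""

    values: np.ndarray          # transects x predictors
    names: list[str]
    means: np.ndarray
    sds: np.ndarray

    def inverse(self) -> np.ndarray:
        """Map z-scores back to the original scale."""
        return self.values * self.sds + self.means


def standardize(df: pd.DataFrame, columns=None) -> StandardizedMatrix:
    """Z-score the given columns of ``df`` (sample SD, n-1)."""
    columns = list(columns) if columns is not None else list(PREDICTORS)
    zs, means, sds = [], [], []
    for c in columns:
        z, m, s = zscore(df[c].to_numpy())
        zs.append(z)
        means.append(m)
        sds.append(s)
    return StandardizedMatrix(np.column_stack(zs), columns,
                              np.array(means), np.array(sds))


def standardize_frame(df: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Return a copy of ``df`` with the given columns replaced by z-scores."""
    sm = standardize(df, columns)
    out = df.copy()
    for j, c in enumerate(sm.names):
        out[c] = sm.values[:, j]
    return out


@dataclass
class CollinearityReport:
    """Spearman correlation matrix and VIFs with pass flags."""

    names: list[str]
    rho: np.ndarray
    max_abs_rho: float
    vif: np.ndarray
    rho_threshold: float
    vif_threshold: float
    rho_pass: bool = field(init=False)
    vif_pass: bool = field(init=False)

    def __post_init__(self):
        self.rho_pass = bool(self.max_abs_rho <= self.rho_threshold)
        self.vif_pass = bool(np.all(self.vif < self.vif_threshold))


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1/(1-R^2) regressing it on the others + intercept."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def collinearity_screen(X, names=None, rho_threshold: float = 0.6,
                        vif_threshold: float = 5.0) -> CollinearityReport:
    """Screen predictors for collinearity.

    Spearman rho uses midranks for ties.  VIF_j = 1/(1-R^2_j) from an OLS
    regression of predictor j on the remaining predictors; perfectly
    collinear predictors get an infinite VIF and a fail flag rather than an
    exception.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if names is None else list(names)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])] if names is None else list(names)
    n, p = X.shape
    if p < 2:
        raise DataError("collinearity screen requires >= 2 predictors")
    if n <= p:
        raise DataError("VIF requires more rows than predictors")
    rho = stats.spearmanr(X).statistic
    rho = np.atleast_2d(rho)
    off = rho[~np.eye(p, dtype=bool)]
    vif = np.array([_vif_one(X, j) for j in range(p)])
    return CollinearityReport(names, rho, float(np.max(np.abs(off))),
                              vif, rho_threshold, vif_threshold)


def split_by_elevation(df: pd.DataFrame, cut: float = ELEVATION_CUT):
    """Split into (LOW, HIGH): LOW has elevation <= cut, HIGH is above."""
    low = df[df["elevation"] <= cut]
    high = df[df["elevation"] > cut]
    return low, high


def split_by_year_parity(df: pd.DataFrame):
    """Split into (ODD, EVEN) by survey-year parity."""
    odd = df[df["year"] % 2 == 1]
    even = df[df["year"] % 2 == 0]
    return odd, even


def validate_records(df: pd.DataFrame) -> list[str]:
    """Check the transect-record schema; return a list of error strings.

    Row numbers in messages are 1-based positions in the table (excluding
    the header), independent of the index.
    """
    errors: list[str] = []
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        return [f"missing column(s): {', '.join(missing)}"]
    for c in COLUMNS:
        col = df[c]
        if col.isna().any():
            rows = (np.flatnonzero(col.isna().to_numpy()) + 1).tolist()
            errors.append(f"column {c}: missing value(s) at row(s) {rows}")
    if errors:
        return errors
    for c in _INT_COLUMNS:
        vals = df[c].to_numpy()
        if not np.allclose(vals, np.round(vals)):
            rows = (np.flatnonzero(~np.isclose(vals, np.round(vals))) + 1).tolist()
            errors.append(f"column {c}: non-integer value(s) at row(s) {rows}")
    for c, (lo, hi) in _RANGES.items():
        vals = df[c].to_numpy(dtype=float)
        bad = np.zeros(len(vals), dtype=bool)
        if lo is not None:
            bad |= vals < lo
        if hi is not None:
            bad |= vals > hi
        if bad.any():
            rows = (np.flatnonzero(bad) + 1).tolist()
            errors.append(f"column {c}: value out of range "
                          f"[{lo}, {hi if hi is not None else 'inf'}] at row(s) {rows}")
    return errors


def read_transects(path, validate: bool = True) -> pd.DataFrame:
    """Read a transect CSV; missing values or range violations are rejected."""
    df = pd.read_csv(path)
    if validate:
        errors = validate_records(df)
        if errors:
            raise DataError(f"invalid transect table {path}: " + "; ".join(errors))
    for c in _INT_COLUMNS:
        if c in df.columns:
            df[c] = df[c].astype(int)
    return df


def write_transects(df: pd.DataFrame, path) -> None:
    """Write the fixed-schema CSV (floats to 12 significant digits)."""
    df.to_csv(path, index=False, columns=COLUMNS, float_format="%.12g")
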
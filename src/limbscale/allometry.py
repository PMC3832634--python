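"""Standardized major axis (SMA / RMA, Model II) allometric regression.

Scaling relationships y = a x**b are fitted on log10-transformed data, so
log(y) = b log(x) + log(a). Because both body mass and each limb trait
carry measurement and biological error, the line is fitted by standardized
major axis: the slope is sign(r) * s_y / s_x, which treats neither
variable as the independent one.

Inference follows the SMATR family of methods:

* 95% slope CI from b * (sqrt(B + 1) +/- sqrt(B)) with
  B = F(0.95; 1, n-2) * (1 - r^2) / (n - 2);
* the one-sample test of the slope against a null value b0 uses the
  correlation between residual scores (y - b0 x) and fitted-axis scores
  (y + b0 x): F = r_rf^2 (n-2) / (1 - r_rf^2) on (1, n-2) df;
* a likelihood-ratio test for a common slope across groups, and a Wald
  test for common elevation (intercept) given a common slope.

Both the effect-size route (does the 95% CI exclude the null slope?) and
the significance-test route (F-test at alpha = 0.05) are always reported;
no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RMAFit",
    "SlopeDepartureResult",
    "GroupComparison",
    "rma_fit",
    "test_slope_vs_value",
    "common_slope_test",
    "common_elevation_test",
    "run_scaling_table",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class RMAFit:
    """One log-log SMA regression."""

    n: int
    slope: float
    intercept: float
    r_squared: float
    slope_ci: Tuple[float, float]
    intercept_ci: Tuple[float, float]
    sign: int  # sign of the x-y correlation


@dataclass(frozen=True)
class SlopeDepartureResult:
    """Departure of an SMA slope from a null (geometric-similarity) value."""

    null_slope: float
    f_statistic: float
    p_value: float
    ci_excludes_null: bool
    classification: str  # isometry | positive_allometry | negative_allometry


@dataclass(frozen=True)
class GroupComparison:
    """Common-slope (likelihood ratio) and common-elevation (Wald) tests."""

    groups: Tuple[str, ...]
    common_slope: float
    common_slope_stat: float
    common_slope_p: float
    elevation_stat: Optional[float] = None
    elevation_p: Optional[float] = None
    elevations: Optional[Tuple[float, ...]] = None


def _validate_xy(x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError(f"need n >= 3 points, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    return x, y


def rma_fit(x: Sequence[float], y: Sequence[float]) -> RMAFit:
    """Fit the SMA line to (already log-transformed) data.

    Returns slope sign(r) * s_y/s_x, intercept ybar - b*xbar, r^2, the
    analytic 95% slope CI, and an approximate t-based intercept CI.
    """
    x, y = _validate_xy(np.asarray(x), np.asarray(y))
    n = len(x)
    sx = np.std(x, ddof=1)
    sy = np.std(y, ddof=1)
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1 if r >= 0 else -1
    b = sign * sy / sx
    a = float(np.mean(y) - b * np.mean(x))
    r2 = r * r

    if r2 >= 1.0 - 1e-15:
        slope_ci = (b, b)
        intercept_ci = (a, a)
    else:
        fcrit = stats.f.ppf(1 - ALPHA, 1, n - 2)
        B = fcrit * (1 - r2) / (n - 2)
        lo = b * (math.sqrt(B + 1) - math.sqrt(B))
        hi = b * (math.sqrt(B + 1) + math.sqrt(B))
        slope_ci = (min(lo, hi), max(lo, hi))
        # intercept CI: delta-method variance of ybar - b xbar
        resid = y - b * x
        s2_res = float(np.sum((resid - resid.mean()) ** 2)) / (n - 2)
        var_b = b * b * (1 - r2) / (n - 2)
        se_a = math.sqrt(s2_res / n + np.mean(x) ** 2 * var_b)
        tcrit = stats.t.ppf(1 - ALPHA / 2, n - 2)
        intercept_ci = (a - tcrit * se_a, a + tcrit * se_a)

    return RMAFit(
        n=n, slope=float(b), intercept=a, r_squared=r2,
        slope_ci=slope_ci, intercept_ci=intercept_ci, sign=sign,
    )


def _residual_axis_corr(x: np.ndarray, y: np.ndarray, b: float) -> float:
    """Correlation of residual scores y - b x with axis scores y + b x."""
    resid = y - b * x
    axis = y + b * x
    vr = np.var(resid, ddof=1)
    va = np.var(axis, ddof=1)
    # Guard relative to the axis scale: residual variance at the level of
    # float rounding means the null slope fits the data exactly.
    if va <= 0 or vr <= 1e-24 * va:
        return 0.0
    cov = np.cov(resid, axis, ddof=1)[0, 1]
    return float(cov / math.sqrt(vr * va))


def test_slope_vs_value(
    x: Sequence[float], y: Sequence[float], null_slope: float
) -> SlopeDepartureResult:
    """One-sample SMA slope test against a null value.

    F = r_rf^2 (n-2) / (1 - r_rf^2) on (1, n-2) df, where r_rf is the
    correlation between residual and fitted-axis scores at the null slope.
    The classification (isometry vs positive/negative allometry) is made
    from 95%-CI exclusion, with the direction given by sign(b - b0).
    """
    x, y = _validate_xy(np.asarray(x), np.asarray(y))
    if null_slope == 0:
        raise ValueError("null slope must be nonzero")
    n = len(x)
    fit = rma_fit(x, y)
    if fit.sign * null_slope < 0:
        logger.warning(
            "null slope %s has opposite sign to the correlation", null_slope
        )
    r_rf = _residual_axis_corr(x, y, null_slope)
    denom = 1 - r_rf**2
    if denom <= 1e-15:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = r_rf**2 * (n - 2) / denom
        p = float(stats.f.sf(f_stat, 1, n - 2))
    lo, hi = fit.slope_ci
    excludes = not (lo <= null_slope <= hi)
    # Classify from the F-test; it is algebraically equivalent to CI exclusion
    # but does not misfire on the one-ulp boundary of a zero-width CI.
    if p >= ALPHA:
        cls = "isometry"
    elif abs(fit.slope) > abs(null_slope):
        cls = "positive_allometry"
    else:
        cls = "negative_allometry"
    return SlopeDepartureResult(
        null_slope=null_slope, f_statistic=float(f_stat), p_value=p,
        ci_excludes_null=excludes, classification=cls,
    )


def _group_moments(groups: Dict[str, Tuple[np.ndarray, np.ndarray]]):
    out = []
    for name, (x, y) in groups.items():
        try:
            x, y = _validate_xy(np.asarray(x), np.asarray(y))
        except ValueError as exc:
            raise ValueError(f"group {name!r}: {exc}") from exc
        n = len(x)
        sxx = float(np.var(x, ddof=1))
        syy = float(np.var(y, ddof=1))
        sxy = float(np.cov(x, y, ddof=1)[0, 1])
        out.append((name, n, float(np.mean(x)), float(np.mean(y)), sxx, syy, sxy))
    return out


def _lr_stat(b: float, moments) -> float:
    """-2 log Lambda contribution summed over groups at common slope b."""
    total = 0.0
    for _, n, _, _, sxx, syy, sxy in moments:
        num = (syy - b * b * sxx) ** 2
        den = (syy - 2 * b * sxy + b * b * sxx) * (syy + 2 * b * sxy + b * b * sxx)
        r2 = num / den if den > 0 else 0.0
        r2 = min(r2, 1 - 1e-12)
        total += -(n - 2) * math.log1p(-r2)
    return total


def common_slope_test(
    groups: Dict[str, Tuple[Sequence[float], Sequence[float]]]
) -> GroupComparison:
    """Likelihood-ratio test that all groups share one SMA slope.

    The common slope is the value minimizing the summed likelihood-ratio
    contributions (each group's residual-vs-axis correlation at b); the
    minimized statistic is asymptotically chi-squared with k-1 df.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    moments = _group_moments(
        {k: (np.asarray(v[0]), np.asarray(v[1])) for k, v in groups.items()}
    )
    # search over log|b| with the sign shared by the group correlations
    sign = 1 if sum(1 if m[6] >= 0 else -1 for m in moments) >= 0 else -1
    res = optimize.minimize_scalar(
        lambda t: _lr_stat(sign * math.exp(t), moments),
        bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-10},
    )
    b_common = sign * math.exp(res.x)
    stat = float(res.fun)
    df = len(moments) - 1
    p = float(stats.chi2.sf(stat, df))
    return GroupComparison(
        groups=tuple(g[0] for g in moments),
        common_slope=float(b_common),
        common_slope_stat=stat,
        common_slope_p=p,
    )


def _common_slope_var(b: float, moments) -> float:
    """Variance of the common slope from the curvature of the LR profile."""
    h = max(abs(b), 1e-3) * 1e-4
    d2 = (_lr_stat(b + h, moments) - 2 * _lr_stat(b, moments) + _lr_stat(b - h, moments)) / h**2
    return 2.0 / d2 if d2 > 0 else float("inf")


def common_elevation_test(
    groups: Dict[str, Tuple[Sequence[float], Sequence[float]]],
    common_slope: Optional[float] = None,
) -> GroupComparison:
    """Wald test for equal elevation (intercept) across groups.

    Elevations a_i = ybar_i - b xbar_i at the shared slope b (fitted by
    the common-slope routine unless supplied). Their covariance combines
    per-group residual variance with the shared uncertainty in b, which
    correlates elevations through the group means of x.
    """
    base = common_slope_test(groups)
    b = base.common_slope if common_slope is None else float(common_slope)
    moments = _group_moments(
        {k: (np.asarray(v[0]), np.asarray(v[1])) for k, v in groups.items()}
    )
    k = len(moments)
    a = np.array([ybar - b * xbar for _, n, xbar, ybar, *_ in moments])
    xbars = np.array([m[2] for m in moments])
    var_b = _common_slope_var(b, moments)
    V = np.outer(xbars, xbars) * var_b
    for i, (_, n, xbar, ybar, sxx, syy, sxy) in enumerate(moments):
        s2_res = (syy - 2 * b * sxy + b * b * sxx) * (n - 1) / (n - 2)
        V[i, i] += s2_res / n
    L = np.zeros((k - 1, k))
    L[:, 0] = 1.0
    for i in range(k - 1):
        L[i, i + 1] = -1.0
    diff = L @ a
    scale = float(max(np.max(np.abs(a)), 1.0))
    if np.all(np.isfinite(V)):
        M = L @ V @ L.T
        degenerate = float(np.max(np.abs(np.diag(M)))) < 1e-20 * scale**2
    else:
        M = None
        degenerate = True
    if degenerate:
        # noise-free groups: elevations are known exactly, so equal
        # elevations give stat 0 and any difference is certain
        if np.all(np.abs(diff) <= 1e-9 * scale):
            stat, p = 0.0, 1.0
        else:
            stat, p = float("inf"), 0.0
    else:
        try:
            stat = float(diff @ np.linalg.solve(M, diff))
        except np.linalg.LinAlgError:
            raise ValueError("degenerate covariance in elevation test")
        p = float(stats.chi2.sf(stat, k - 1))
    return GroupComparison(
        groups=base.groups,
        common_slope=b,
        common_slope_stat=base.common_slope_stat,
        common_slope_p=base.common_slope_p,
        elevation_stat=stat,
        elevation_p=p,
        elevations=tuple(float(v) for v in a),
    )


def run_scaling_table(
    data: pd.DataFrame,
    trait: str,
    null_slope: float,
    groups: Optional[Dict[str, Sequence[str]]] = None,
    mass_column: str = "body_mass",
) -> pd.DataFrame:
    """Per-group SMA fits and null-slope departures, one row per group.

    ``data`` holds one row per species with positive ``mass_column`` and
    ``trait`` columns in natural units (log10 is applied here). ``groups``
    maps a group name to the list of species it contains (a ``species``
    column is required then); the whole sample is always the first row.
    Groups with fewer than 3 usable species are skipped with a warning.
    Printed-style 2-decimal columns accompany full-precision ones.
    """
    for col in (mass_column, trait):
        if col not in data.columns:
            raise ValueError(f"column {col!r} not in the species table")
    rows: List[dict] = []

    def _one(name: str, sub: pd.DataFrame) -> None:
        sub = sub[[mass_column, trait]].dropna()
        n_dropped = len(data if name == "all" else sub) - len(sub)
        if n_dropped:
            logger.info("group %s: dropped %d rows with missing %s", name, n_dropped, trait)
        if len(sub) < 3:
            logger.warning("group %s skipped: n=%d < 3", name, len(sub))
            return
        x = np.log10(sub[mass_column].to_numpy(dtype=float))
        y = np.log10(sub[trait].to_numpy(dtype=float))
        fit = rma_fit(x, y)
        dep = test_slope_vs_value(x, y, null_slope)
        rows.append({
            "group": name,
            "n": fit.n,
            "null_slope": float(null_slope),
            "intercept": fit.intercept,
            "slope": fit.slope,
            "slope_ci_low": fit.slope_ci[0],
            "slope_ci_high": fit.slope_ci[1],
            "r_squared": fit.r_squared,
            "departure_F": dep.f_statistic,
            "departure_p": dep.p_value,
            "classification": dep.classification,
            "intercept_2dp": _round2(fit.intercept),
            "slope_2dp": _round2(fit.slope),
        })

    _one("all", data)
    if groups:
        if "species" not in data.columns:
            raise ValueError("group definitions require a 'species' column")
        for name, members in groups.items():
            _one(name, data[data["species"].isin(members)])
    return pd.DataFrame(rows)


def _round2(v: float) -> float:
    """Round-half-even to two decimals, as in printed tables."""
    return float(np.round(v, 2))
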
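"""Developmental trend statistics for network measures across grades.

The trajectory of every network measure over grade checkpoints is treated
with the same toolkit:

* a one-way between-groups ANOVA over grades (with 7 grades x 50
  participants this gives df = (6, 343)); a repeated-measures variant is
  available behind a flag,
* Tukey-HSD-adjusted pairwise comparisons, reported for consecutive grades,
* orthogonal-polynomial trend fits over the numeric grade variable,
  respecting the unequal spacing of the checkpoints (grades 1..6 then 8),
* an OLS log-log fit of the degree distribution P(k) on k — a straight line
  signals a power law, i.e. scale-free structure,
* the power of the two-sided zero-correlation test (Fisher-z
  approximation), used to justify the simulated sample size.

Note the power-law fit is deliberately the descriptive log-log OLS, not
maximum-likelihood tail estimation; see the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AnovaResult",
    "PolyTrend",
    "TrendResult",
    "PowerLawFit",
    "oneway_anova",
    "tukey_pairwise",
    "polynomial_trend_fit",
    "loglog_degree_fit",
    "correlation_power",
    "analyze_measure",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p_value: float


@dataclass(frozen=True)
class PolyTrend:
    """Orthogonal-polynomial trend fit: per-order coefficients with t-values."""

    coefficients: tuple[tuple[int, float, float], ...]  # (order, coef, t)
    intercept: tuple[float, float]  # (coef, t)
    r_squared: float


@dataclass(frozen=True)
class TrendResult:
    """Full trend analysis for one network measure."""

    measure_name: str
    anova: AnovaResult
    pairwise: tuple[tuple[str, str, float], ...]  # (grade_a, grade_b, adj. p)
    trend: PolyTrend | None = field(default=None)


@dataclass(frozen=True)
class PowerLawFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def _validated_groups(values: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(values) < 2:
        raise ValueError("need at least 2 grades")
    groups = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"grade {g!r} has fewer than 2 values")
    return groups


def oneway_anova(
    values: Mapping[str, Sequence[float]],
    *,
    repeated: bool = False,
) -> AnovaResult:
    """One-way ANOVA of a measure over grades.

    The default is the between-groups decomposition F = (SSB/df1)/(SSW/df2)
    with df1 = k - 1 and df2 = N - k.  With ``repeated=True`` a
    within-participant (repeated-measures) ANOVA is computed instead, with
    groups aligned by position and df2 = (k - 1)(n - 1).
    """
    groups = _validated_groups(values)
    arrays = list(groups.values())
    k = len(arrays)
    if repeated:
        sizes = {a.size for a in arrays}
        if len(sizes) != 1:
            raise ValueError("repeated-measures ANOVA needs equal group sizes")
        data = np.column_stack(arrays)  # participants x grades
        n = data.shape[0]
        grand = data.mean()
        ss_grade = n * ((data.mean(axis=0) - grand) ** 2).sum()
        ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
        ss_total = ((data - grand) ** 2).sum()
        ss_err = ss_total - ss_grade - ss_subj
        df1, df2 = k - 1, (k - 1) * (n - 1)
        if ss_err <= 0 and ss_grade <= 0:
            raise ValueError("F undefined: no variance in grades or residuals")
        F = (ss_grade / df1) / (ss_err / df2)
        p = float(stats.f.sf(F, df1, df2))
        return AnovaResult(float(F), df1, df2, p)
    N = sum(a.size for a in arrays)
    df1, df2 = k - 1, N - k
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0 and ssb == 0:
        raise ValueError("F undefined: zero between- and within-group variance")
    F, p = stats.f_oneway(*arrays)
    return AnovaResult(float(F), df1, df2, float(p))


def tukey_pairwise(
    values: Mapping[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], float]:
    """Tukey-HSD-adjusted p-values from the studentized-range distribution.

    The adjustment is computed over *all* grade pairs (standard HSD
    practice); ``pairs`` selects which to report — by default the
    consecutive grades in mapping order.
    """
    groups = _validated_groups(values)
    labels = list(groups)
    result = stats.tukey_hsd(*groups.values())
    if pairs is None:
        pairs = list(zip(labels, labels[1:]))
    index = {g: i for i, g in enumerate(labels)}
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        out[(a, b)] = float(result.pvalue[index[a], index[b]])
    return out


def _orthonormal_poly(x: np.ndarray, max_order: int) -> np.ndarray:
    """Orthonormal polynomial basis on x (QR of the Vandermonde matrix).

    Column j spans polynomials of degree j, is orthogonal to all lower
    orders, and has unit norm.  Signs are fixed so each column correlates
    positively with x**j, making coefficients reproducible.
    """
    V = np.vander(x, max_order + 1, increasing=True).astype(float)
    Q, _ = np.linalg.qr(V)
    for j in range(Q.shape[1]):
        ref = x**j
        if np.dot(Q[:, j], ref) < 0:
            Q[:, j] = -Q[:, j]
    return Q


def polynomial_trend_fit(
    grades: Sequence[float],
    values: Mapping[str, Sequence[float]],
    max_order: int = 4,
) -> PolyTrend:
    """Fit orthogonal polynomial contrasts of the numeric grade variable.

    ``grades`` gives the numeric position of each grade label in mapping
    order (e.g. 1, 2, 3, 4, 5, 6, 8 — the gap at 7 is respected).  Each
    participant value is an observation at its grade's position; the fit is
    OLS of the pooled observations on the orthonormal polynomial basis.
    Returns per-order coefficients and t-values plus the R-squared of the
    full polynomial model.
    """
    import statsmodels.api as sm

    groups = _validated_groups(values)
    if len(grades) != len(groups):
        raise ValueError("grades and values must align")
    distinct = len(set(grades))
    if max_order >= distinct:
        raise ValueError(
            f"max_order {max_order} must be < number of distinct grades {distinct}"
        )
    x_parts, y_parts = [], []
    for g_num, (label, v) in zip(grades, groups.items()):
        x_parts.append(np.full(v.size, float(g_num)))
        y_parts.append(v)
    x = np.concatenate(x_parts)
    y = np.concatenate(y_parts)
    Q = _orthonormal_poly(x, max_order)
    design = np.column_stack([np.ones_like(x), Q[:, 1:]])
    fit = sm.OLS(y, design).fit()
    coeffs = tuple(
        (order, float(fit.params[order]), float(fit.tvalues[order]))
        for order in range(1, max_order + 1)
    )
    return PolyTrend(
        coefficients=coeffs,
        intercept=(float(fit.params[0]), float(fit.tvalues[0])),
        r_squared=float(fit.rsquared),
    )


def loglog_degree_fit(distribution: Mapping[int, float]) -> PowerLawFit:
    """OLS of log10 P(k) on log10 k over observed positive-frequency degrees.

    A slope of -a with high R-squared indicates P(k) ~ k^-a, the scale-free
    signature.  Zero-frequency degrees are excluded; fewer than two
    positive-frequency degrees raise :class:`ValueError`.
    """
    pts = [(k, p) for k, p in distribution.items() if p > 0]
    if len(pts) < 2:
        raise ValueError("need at least 2 positive-frequency degrees")
    k = np.log10([float(p[0]) for p in pts])
    p = np.log10([float(p[1]) for p in pts])
    res = stats.linregress(k, p)
    return PowerLawFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(pts),
    )


def correlation_power(n: int, r: float, alpha: float = 0.05) -> float:
    """Power of the two-sided test of zero correlation at true correlation r.

    Fisher-z approximation: with lambda = |atanh(r)| * sqrt(n - 3) and
    z* the upper alpha/2 normal quantile, power = Phi(lambda - z*) +
    Phi(-lambda - z*).  At r = 0 this equals alpha (the size of the test).
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    lam = abs(math.atanh(r)) * math.sqrt(n - 3)
    z_crit = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.sf(z_crit - lam) + stats.norm.cdf(-z_crit - lam))


def analyze_measure(
    measure_name: str,
    grades: Sequence[float],
    values: Mapping[str, Sequence[float]],
    max_order: int = 4,
) -> TrendResult:
    """Convenience wrapper: ANOVA + consecutive-grade Tukey + polynomial trend."""
    anova = oneway_anova(values)
    pairwise = tukey_pairwise(values)
    max_order = min(max_order, len(set(grades)) - 1)
    try:
        trend = polynomial_trend_fit(grades, values, max_order)
    except ValueError:
        trend = None
    return TrendResult(
        measure_name=measure_name,
        anova=anova,
        pairwise=tuple((a, b, p) for (a, b), p in pairwise.items()),
        trend=trend,
    )
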
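"""Method-agreement statistics: NRMSE, OLS fits, Bland-Altman, CV tables.

Conventions used throughout: sample (n-1) standard deviations, limits of
agreement at bias +/- 1.96 SD of the paired differences, NRMSE normalised
by the *range* of the reference values and reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "LinearFit",
    "BlandAltman",
    "nrmse",
    "linear_fit",
    "pearson",
    "bland_altman",
    "agreement_report",
    "cv_table",
    "correlation_matrix",
]

LOA_MULTIPLIER = 1.96


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    return a, b


def nrmse(reference, predicted) -> float:
    """RMSE of ``predicted`` against ``reference`` as % of the reference range."""
    ref, pred = _pair(reference, predicted)
    if ref.size < 2:
        raise ValueError("need at least 2 points")
    rng = np.ptp(ref)
    if rng == 0:
        raise ValueError("reference range is zero; NRMSE undefined")
    rmse = float(np.sqrt(np.mean((pred - ref) ** 2)))
    return 100.0 * rmse / rng


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    slope_through_origin: float


def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares of y on x, plus the through-origin slope."""
    x, y = _pair(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("x is degenerate (zero variance)")
    res = stats.linregress(x, y)
    slope0 = float(np.dot(x, y) / np.dot(x, x))
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue) ** 2,
                     slope_through_origin=slope0)


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x, y = _pair(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float


def bland_altman(a, b) -> BlandAltman:
    """Bland-Altman agreement of method ``a`` against method ``b``.

    Differences are ``a - b``; limits of agreement are
    bias +/- 1.96 * SD(differences) with the sample (n-1) SD.
    """
    a, b = _pair(a, b)
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, sd_diff=sd,
                       loa_low=bias - LOA_MULTIPLIER * sd,
                       loa_high=bias + LOA_MULTIPLIER * sd)


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement summary of a method against a reference method."""

    n: int
    slope: float
    intercept: float
    slope_through_origin: float
    pearson_r: float
    rmse: float
    nrmse_pct: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float


def agreement_report(reference, predicted) -> AgreementReport:
    """Regression + correlation + NRMSE + Bland-Altman of ``predicted``
    (the candidate method) against ``reference``.

    The regression is of the reference on the method (method on the x axis,
    the usual method-comparison layout), so a method that systematically
    overestimates shows a slope below 1.  Bias is ``mean(method -
    reference)``; NRMSE is normalised by the reference range.
    """
    ref, pred = _pair(reference, predicted)
    fit = linear_fit(pred, ref)
    ba = bland_altman(pred, ref)
    rmse = float(np.sqrt(np.mean((pred - ref) ** 2)))
    return AgreementReport(
        n=ref.size, slope=fit.slope, intercept=fit.intercept,
        slope_through_origin=fit.slope_through_origin,
        pearson_r=pearson(ref, pred), rmse=rmse,
        nrmse_pct=nrmse(ref, pred),
        bias=ba.bias, sd_diff=ba.sd_diff,
        loa_low=ba.loa_low, loa_high=ba.loa_high,
    )


def cv_table(df: pd.DataFrame, group_col: str, value_cols: list[str] | None = None
             ) -> pd.DataFrame:
    """Coefficients of variation (%) per group and dimension.

    One row per group plus a ``Mean`` row (the mean of the group CVs) and a
    pooled row (``C.V. of season``) computed on the concatenated data of all
    groups — deliberately not the mean of the per-group CVs.
    """
    if value_cols is None:
        value_cols = [c for c in df.columns if c != group_col]

    def cv(series: pd.Series) -> float:
        m = series.mean()
        if m == 0:
            raise ValueError("zero mean; CV undefined")
        return 100.0 * series.std(ddof=1) / m

    counts = df.groupby(group_col).size()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 records")
    per_group = df.groupby(group_col)[value_cols].agg(cv)
    mean_row = per_group.mean().to_frame().T
    mean_row.index = ["Mean"]
    pooled = pd.DataFrame([{c: cv(df[c]) for c in value_cols}],
                          index=["C.V. of season"])
    return pd.concat([per_group, mean_row, pooled])


def correlation_matrix(df: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values and star flags.

    Returns ``(r, p, stars)`` frames; stars follow the usual convention
    ``'*'`` for 0.001 < P < 0.05 and ``'**'`` for P < 0.001 (no
    multiple-testing correction).
    """
    cols = list(df.columns)
    if len(df) < 3:
        raise ValueError("need at least 3 records")
    for c in cols:
        if np.var(df[c].to_numpy(dtype=float)) == 0:
            raise ValueError(f"column {c!r} is constant")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            if j >= i:
                continue
            res = stats.pearsonr(df[ci], df[cj])
            r.loc[ci, cj] = r.loc[cj, ci] = float(res.statistic)
            p.loc[ci, cj] = p.loc[cj, ci] = float(res.pvalue)
    stars = p.map(lambda v: "**" if v < 0.001 else ("*" if v < 0.05 else ""))
    np.fill_diagonal(stars.values, "")
    return r, p, stars
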
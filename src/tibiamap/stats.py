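"""Observer reliability and the rotation-experiment statistics.

Implements the reliability workflow for reference-point image numbers:
pairwise observer errors in mm and in percent of each specimen's plateau
length (with the 5%-of-length acceptance rule), the single-measure
two-way absolute-agreement intraclass correlation ICC(2,1) with its
F-based 95% confidence interval, and one-way repeated-measures ANOVA
(with a Friedman fallback) for the rotation conditions.

Image numbers are converted to mm after re-zeroing at RP1, which removes
the blank slices occasionally present at the start of a stack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ObserverErrorResult",
    "ReliabilityResult",
    "RMAnovaResult",
    "observer_errors",
    "icc_absolute_agreement",
    "rm_anova",
]


@dataclass
class ObserverErrorResult:
    """Pairwise rater errors for one reference point."""

    table: pd.DataFrame  # one row per rater pair
    mean_error_mm: float
    sem_error_mm: float
    mean_error_pct: float
    sem_error_pct: float
    accepted: bool  # every pairwise mean percent error < 5%
    threshold_pct: float = 5.0


def observer_errors(
    ratings: pd.DataFrame,
    lengths_mm,
    dz_mm: float,
    threshold_pct: float = 5.0,
) -> ObserverErrorResult:
    """Pairwise |difference| of recorded image numbers, in mm and % length.

    ``ratings``: samples x raters (or trials) of 1-based image numbers;
    ``lengths_mm``: per-sample RP1-RP5 plateau length; ``dz_mm``: slice
    spacing.  Errors are deemed acceptable when every pairwise mean error
    is below ``threshold_pct`` percent of the plateau length.
    """
    ratings = pd.DataFrame(ratings)
    if ratings.isna().any().any():
        missing = [(str(i), str(c)) for i, c in zip(*np.where(ratings.isna()))]
        raise ValueError(f"ratings table has missing cells: {missing}")
    if ratings.shape[1] < 2:
        raise ValueError("need at least two raters/trials")
    lengths = np.asarray(lengths_mm, dtype=float)
    if lengths.shape != (len(ratings),):
        raise ValueError("one plateau length per sample is required")

    rows = []
    all_mm, all_pct = [], []
    for a, b in combinations(ratings.columns, 2):
        diff_mm = np.abs(ratings[a].to_numpy(float) - ratings[b].to_numpy(float)) * dz_mm
        pct = diff_mm / lengths * 100.0
        n = len(diff_mm)
        rows.append(
            {
                "pair": f"{a} vs {b}",
                "mean_mm": diff_mm.mean(),
                "sem_mm": diff_mm.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
                "mean_pct": pct.mean(),
                "sem_pct": pct.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
                "accepted": pct.mean() < threshold_pct,
            }
        )
        all_mm.append(diff_mm)
        all_pct.append(pct)
    table = pd.DataFrame(rows)
    all_mm = np.concatenate(all_mm)
    all_pct = np.concatenate(all_pct)
    return ObserverErrorResult(
        table=table,
        mean_error_mm=float(all_mm.mean()),
        sem_error_mm=float(all_mm.std(ddof=1) / np.sqrt(len(all_mm))) if len(all_mm) > 1 else 0.0,
        mean_error_pct=float(all_pct.mean()),
        sem_error_pct=float(all_pct.std(ddof=1) / np.sqrt(len(all_pct))) if len(all_pct) > 1 else 0.0,
        accepted=bool(table["accepted"].all()),
        threshold_pct=threshold_pct,
    )


@dataclass
class ReliabilityResult:
    """Single-measure two-way absolute-agreement ICC with 95% CI."""

    icc: float
    ci_lower: float
    ci_upper: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    n_raters: int


def icc_absolute_agreement(table, alpha: float = 0.05) -> ReliabilityResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    From the two-way ANOVA mean squares of an n x k table (rows =
    subjects, columns = raters)::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with the McGraw & Wong F-based confidence interval.  A table with no
    variance at all is returned as ICC = 1 with a degenerate CI and a
    warning.
    """
    X = np.asarray(pd.DataFrame(table), dtype=float)
    if np.isnan(X).any():
        raise ValueError("ICC requires a complete matrix (no missing cells)")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least a 2x2 table, got {n}x{k}")
    grand = X.mean()
    row_m = X.mean(axis=1)
    col_m = X.mean(axis=0)
    ssr = k * ((row_m - grand) ** 2).sum()
    ssc = n * ((col_m - grand) ** 2).sum()
    sse = ((X - row_m[:, None] - col_m[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    if np.isclose(((X - grand) ** 2).sum(), 0.0):
        warnings.warn("zero total variance; ICC defined as 1 with degenerate CI")
        return ReliabilityResult(1.0, 1.0, 1.0, msr, msc, mse, n, k)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom

    # McGraw & Wong (1996) interval for ICC(A,1)
    if np.isclose(mse, 0.0) and np.isclose(msc, mse):
        return ReliabilityResult(float(icc), float(icc), float(icc), msr, msc, mse, n, k)
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
    else:
        v = (n - 1) * (k - 1)
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return ReliabilityResult(float(icc), float(lower), float(upper), msr, msc, mse, n, k)


@dataclass
class RMAnovaResult:
    statistic: float
    df_between: float
    df_error: float
    p_value: float
    method: str  # "rm_anova" or "friedman"


def rm_anova(data, nonparametric: str | bool = False) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions table.

    ``F = MS_conditions / MS_error`` with df (k-1, (n-1)(k-1)).  With
    ``nonparametric=True`` (or ``"auto"`` and a failed Shapiro normality
    pre-check of the residuals) the Friedman test is used instead.
    """
    X = np.asarray(pd.DataFrame(data), dtype=float)
    if np.isnan(X).any():
        raise ValueError("RM ANOVA requires a complete matrix")
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least two conditions")
    if n < 2:
        raise ValueError("need at least two subjects")

    row_m = X.mean(axis=1)
    col_m = X.mean(axis=0)
    grand = X.mean()
    resid = X - row_m[:, None] - col_m[None, :] + grand

    use_np = nonparametric is True
    if nonparametric == "auto":
        flat = resid.ravel()
        if np.ptp(flat) > 0 and sps.shapiro(flat).pvalue < 0.05:
            use_np = True
    if use_np:
        stat, p = sps.friedmanchisquare(*[X[:, j] for j in range(k)])
        return RMAnovaResult(float(stat), float(k - 1), float("nan"), float(p), "friedman")

    ss_cond = n * ((col_m - grand) ** 2).sum()
    ss_err = (resid**2).sum()
    df_b = k - 1
    df_e = (n - 1) * (k - 1)
    ms_cond = ss_cond / df_b
    ms_err = ss_err / df_e
    if np.isclose(ss_cond, 0.0):
        return RMAnovaResult(0.0, df_b, df_e, 1.0, "rm_anova")
    if np.isclose(ms_err, 0.0):
        return RMAnovaResult(float("inf"), df_b, df_e, 0.0, "rm_anova")
    F = ms_cond / ms_err
    p = float(sps.f.sf(F, df_b, df_e))
    return RMAnovaResult(float(F), df_b, df_e, p, "rm_anova")
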
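"""Method-agreement statistics for paired effective-dose measurements.

Implements the analysis used to validate an automated dose calculator
against a reference method on the same patients: per-method mean +/- sample
SD, squared Pearson correlation, least-squares regression of the automated
values on the reference values, Bland-Altman mean difference with 1.96-SD
limits of agreement, Student's t-tests (paired and unpaired), signed percent
difference of column means, and a two-way absolute-agreement single-
measurement ICC for repeatability.

The maximum allowed difference drawn on Bland-Altman plots is pluggable; the
default combines both methods' coefficients of variation as
``1.96 * sqrt(cv_a^2 + cv_b^2) * grand_mean``. It is a plausible reading of
"calculated from the coefficients of variation of both methods", not a
validated reproduction of any published value - treat it as a QC guide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, UndefinedStatisticError

#: Bland-Altman limits-of-agreement multiplier (95% of differences)
LOA_MULTIPLIER = 1.96


def _col(x: Sequence[float], min_n: int, name: str = "column") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InsufficientDataError(f"{name} must be 1-D")
    if arr.size < min_n:
        raise InsufficientDataError(f"{name} needs >= {min_n} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise InsufficientDataError(f"{name} contains non-finite values")
    return arr


def mean_sd(x: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1 denominator)."""
    arr = _col(x, 2)
    return float(arr.mean()), float(arr.std(ddof=1))


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation coefficient."""
    ax, ay = _paired(x, y, 3)
    if ax.std() == 0 or ay.std() == 0:
        raise UndefinedStatisticError("correlation undefined for zero-variance input")
    r = sps.pearsonr(ax, ay).statistic
    return float(r * r)


def ols_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Least-squares (slope, intercept) predicting y from x."""
    ax, ay = _paired(x, y, 3)
    if ax.std() == 0:
        raise UndefinedStatisticError("regression undefined for zero-variance x")
    fit = sps.linregress(ax, ay)
    return float(fit.slope), float(fit.intercept)


def _paired(a: Sequence[float], b: Sequence[float], min_n: int) -> tuple[np.ndarray, np.ndarray]:
    aa = _col(a, min_n, "a")
    bb = _col(b, min_n, "b")
    if aa.size != bb.size:
        raise InsufficientDataError(f"paired columns differ in length: {aa.size} vs {bb.size}")
    return aa, bb


def default_max_allowed_difference(a: np.ndarray, b: np.ndarray) -> float:
    """1.96 * sqrt(cv_a^2 + cv_b^2) * grand mean (coefficient-of-variation based)."""
    ma, sa = a.mean(), a.std(ddof=1)
    mb, sb = b.mean(), b.std(ddof=1)
    if ma == 0 or mb == 0:
        raise UndefinedStatisticError("CV undefined for zero-mean column")
    grand = (ma + mb) / 2.0
    return float(LOA_MULTIPLIER * np.hypot(sa / ma, sb / mb) * grand)


@dataclass(frozen=True)
class BlandAltman:
    """Agreement between two paired measurement columns (a - b)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    max_allowed_diff: float


def bland_altman(
    a: Sequence[float],
    b: Sequence[float],
    mad_fn: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> BlandAltman:
    """Bland-Altman mean difference and 1.96-SD limits of agreement for a - b.

    ``mad_fn`` overrides the maximum-allowed-difference formula
    (default: :func:`default_max_allowed_difference`).
    """
    aa, bb = _paired(a, b, 3)
    d = aa - bb
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    mad = (mad_fn or default_max_allowed_difference)(aa, bb)
    return BlandAltman(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - LOA_MULTIPLIER * sd_diff,
        loa_high=mean_diff + LOA_MULTIPLIER * sd_diff,
        max_allowed_diff=float(mad),
    )


def paired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Paired Student's t statistic and two-sided p (n-1 df).

    Identical columns (zero-variance, zero-mean differences) return (0, 1).
    """
    aa, bb = _paired(a, b, 2)
    d = aa - bb
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return float(np.inf * np.sign(d.mean())), 0.0
    res = sps.ttest_rel(aa, bb)
    return float(res.statistic), float(res.pvalue)


def unpaired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample (equal-variance) Student's t statistic and two-sided p."""
    aa, bb = _paired(a, b, 2)
    if aa.std(ddof=1) == 0 and bb.std(ddof=1) == 0:
        if aa.mean() == bb.mean():
            return 0.0, 1.0
        return float(np.inf * np.sign(aa.mean() - bb.mean())), 0.0
    res = sps.ttest_ind(aa, bb)
    return float(res.statistic), float(res.pvalue)


def percent_difference(reference_mean: float, other_mean: float) -> float:
    """Signed percent difference of ``other`` relative to ``reference``."""
    if reference_mean <= 0:
        raise UndefinedStatisticError(
            f"reference mean must be > 0, got {reference_mean}"
        )
    return (other_mean - reference_mean) / reference_mean * 100.0


def icc_repeatability(measurements: Sequence[Sequence[float]] | np.ndarray) -> float:
    """ICC(2,1): two-way absolute-agreement, single-measurement.

    ``measurements`` is an (n subjects x k repeats) table. Computed from the
    two-way ANOVA decomposition

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR/MSC/MSE the subject, repeat and residual mean squares. Exactly
    repeated columns over varying subjects give 1.0. Undefined (flagged)
    when subjects do not vary at all.
    """
    data = np.asarray(measurements, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise InsufficientDataError(
            f"need >= 2 subjects and >= 2 repeats, got shape {data.shape}"
        )
    if not np.all(np.isfinite(data)):
        raise InsufficientDataError("measurements contain non-finite values")
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rep_means = data.mean(axis=0)
    ss_rows = k * ((subj_means - grand) ** 2).sum()
    ss_cols = n * ((rep_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise UndefinedStatisticError(
            "ICC undefined: no between-subject variance (all values identical)"
        )
    return float((msr - mse) / denom)


@dataclass(frozen=True)
class AgreementStats:
    """Agreement of one method column against the reference column."""

    method: str
    mean: float
    sd: float
    reference_mean: float
    reference_sd: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    max_allowed_diff: float
    r2: float
    slope: float
    intercept: float
    t_paired: float
    p_paired: float
    t_unpaired: float
    p_unpaired: float
    percent_diff_vs_reference: float


def agreement(
    method_values: Sequence[float],
    reference_values: Sequence[float],
    method: str = "method",
) -> AgreementStats:
    """Full agreement panel of one method against a reference.

    Differences, regression (method ~ reference) and percent difference are
    oriented method-vs-reference.
    """
    mv, rv = _paired(method_values, reference_values, 3)
    m_mean, m_sd = mean_sd(mv)
    r_mean, r_sd = mean_sd(rv)
    ba = bland_altman(mv, rv)
    slope, intercept = ols_fit(rv, mv)
    t_p, p_p = paired_t(mv, rv)
    t_u, p_u = unpaired_t(mv, rv)
    return AgreementStats(
        method=method,
        mean=m_mean,
        sd=m_sd,
        reference_mean=r_mean,
        reference_sd=r_sd,
        mean_diff=ba.mean_diff,
        sd_diff=ba.sd_diff,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        max_allowed_diff=ba.max_allowed_diff,
        r2=pearson_r2(rv, mv),
        slope=slope,
        intercept=intercept,
        t_paired=t_p,
        p_paired=p_p,
        t_unpaired=t_u,
        p_unpaired=p_u,
        percent_diff_vs_reference=percent_difference(r_mean, m_mean),
    )


def method_comparison_report(
    table: pd.DataFrame,
    reference: str = "automated",
    comparator: str = "physician",
) -> dict:
    """The full validation analysis on a method-comparison table.

    ``table`` follows the shipped schema: ``pet_ed`` plus ``<method>_ct`` /
    ``<method>_total`` columns. Returns, per dose kind (ct/total):

    * mean/SD for every method column (plus the shared PET column),
    * the agreement panel of ``reference`` vs ``comparator`` (the automated
      program against the physician's manual calculation by default),
    * percent differences of every other method's mean vs the reference
      (computed on column means, matching how such comparisons are reported),
      with the unpaired Student's p for the mean comparison.
    """
    methods = sorted(
        {c.rsplit("_", 1)[0] for c in table.columns if c.endswith(("_ct", "_total"))}
    )
    if reference not in methods or comparator not in methods:
        raise InsufficientDataError(
            f"table lacks columns for {reference!r} and {comparator!r}; found {methods}"
        )
    report: dict = {"n": int(len(table)), "methods": methods, "pet_ed": {}}
    report["pet_ed"]["mean"], report["pet_ed"]["sd"] = mean_sd(table["pet_ed"])
    for kind in ("ct", "total"):
        ref_col = table[f"{reference}_{kind}"]
        section: dict = {"columns": {}, "percent_diff_vs_reference": {}}
        for m in methods:
            mu, sd = mean_sd(table[f"{m}_{kind}"])
            section["columns"][m] = {"mean": mu, "sd": sd}
        section["agreement"] = agreement(
            ref_col, table[f"{comparator}_{kind}"], method=reference
        )
        for m in methods:
            if m == reference:
                continue
            other = table[f"{m}_{kind}"]
            section["percent_diff_vs_reference"][m] = {
                "percent": percent_difference(float(ref_col.mean()), float(other.mean())),
                "p_unpaired": unpaired_t(other, ref_col)[1],
            }
        report[kind] = section
    return report
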
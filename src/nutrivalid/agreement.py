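"""Method-comparison statistics.

Bland-Altman agreement with explicit divisor conventions, Pearson
association with a signed coefficient of determination, paired testing with
a Shapiro-Wilk normality gate and Bonferroni adjustment, and the
single-measure absolute-agreement intraclass correlation ICC(2,1) under a
two-way random-effects model.

Divisor conventions
-------------------
Published Bland-Altman tables are not consistent about whether standard
errors use n or n-1 in the denominator; both are supported per call
(``convention='n'`` or ``'n-1'``) and the choice is recorded in the result.
With m the effective divisor,

    se_bias = sd / sqrt(m)
    se_loa  = sd * sqrt(3/m)

and the 95% limits of agreement are always bias +/- 1.96*sd exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementResult",
    "ICCResult",
    "bland_altman",
    "loa_from_summary",
    "pearson_assoc",
    "paired_compare",
    "icc_two_way_random",
]

Z_95 = 1.96


@dataclass
class AgreementResult:
    """Bland-Altman summary for one method pair (a minus b, b = reference)."""

    bias: float
    sd_bias: float
    se_bias: float
    ci_bias: tuple[float, float]
    loa: tuple[float, float]
    se_loa: float
    n: int
    divisor_convention: str
    t_df: int
    unit: str = "kcal/day"


@dataclass
class ICCResult:
    """Intraclass correlation under a two-way random-effects model."""

    icc: float
    ci: tuple[float, float]
    model: str
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    n_raters: int
    n_dropped: int = 0


def _divisor(n: int, convention: str) -> int:
    if convention == "n":
        return n
    if convention in ("n-1", "n_minus_1"):
        return n - 1
    raise ValueError(f"unknown divisor convention {convention!r}")


def bland_altman(
    values_a: np.ndarray,
    values_b: np.ndarray,
    convention: str = "n",
    unit: str = "kcal/day",
) -> AgreementResult:
    """Bland-Altman agreement between method a and reference method b.

    bias is the mean of a-b; sd is the sample SD (ddof=1) of the
    differences; the 95% CI of the bias uses Student t with n-1 df.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    n = a.size
    if n < 2:
        raise ValueError(f"Bland-Altman needs at least 2 pairs, got {n}")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    m = _divisor(n, convention)
    se_bias = sd / np.sqrt(m)
    se_loa = sd * np.sqrt(3.0 / m)
    df = n - 1
    tcrit = stats.t.ppf(0.975, df)
    return AgreementResult(
        bias=bias,
        sd_bias=sd,
        se_bias=se_bias,
        ci_bias=(bias - tcrit * se_bias, bias + tcrit * se_bias),
        loa=loa_from_summary(bias, sd),
        se_loa=se_loa,
        n=n,
        divisor_convention=convention,
        t_df=df,
        unit=unit,
    )


def loa_from_summary(bias: float, sd: float) -> tuple[float, float]:
    """95% limits of agreement, bias +/- 1.96*sd, from summary statistics."""
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    return (bias - Z_95 * sd, bias + Z_95 * sd)


def summary_from_convention(
    bias: float, sd: float, n: int, convention: str = "n"
) -> dict[str, float]:
    """Reconstruct SEs, CI and LoA from printed (bias, sd, n) summaries.

    The effective sample size is the divisor m; the bias CI uses Student t
    with m-1 df, i.e. the convention treats m as the pair count throughout.
    """
    m = _divisor(n, convention)
    lo, hi = loa_from_summary(bias, sd)
    se_bias = sd / np.sqrt(m)
    tcrit = stats.t.ppf(0.975, m - 1)
    return {
        "bias": bias,
        "se_bias": se_bias,
        "se_loa": sd * np.sqrt(3.0 / m),
        "loa_lower": lo,
        "loa_upper": hi,
        "ci_lower": bias - tcrit * se_bias,
        "ci_upper": bias + tcrit * se_bias,
    }


def pearson_assoc(
    values_a: np.ndarray, values_b: np.ndarray
) -> dict[str, float]:
    """Pearson correlation with plain and signed r-squared.

    signed_r2 = sign(r) * r**2, so an inverse linear relationship carries a
    negative coefficient of determination in the scorecard.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3:
        raise ValueError(f"correlation needs at least 3 pairs, got {a.size}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:  # exactly constant input
        return {
            "r": float("nan"),
            "r2": float("nan"),
            "signed_r2": float("nan"),
            "p": float("nan"),
        }
    r, p = stats.pearsonr(a, b)
    return {
        "r": float(r),
        "r2": float(r * r),
        "signed_r2": float(np.sign(r) * r * r),
        "p": float(p),
    }


def paired_compare(
    values_a: np.ndarray,
    values_b: np.ndarray,
    alpha: float = 0.05,
    bonferroni_k: int = 3,
) -> dict[str, float | str]:
    """Paired test with a Shapiro-Wilk gate and Bonferroni adjustment.

    Shapiro-Wilk on the differences at ``alpha`` chooses between the paired
    t-test (normal) and the Wilcoxon signed-rank test (non-normal). The
    adjusted p is min(1, k*p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3:
        raise ValueError(f"paired comparison needs at least 3 pairs, got {a.size}")
    diff = a - b
    if np.allclose(diff, diff[0]):
        return {
            "test": "degenerate",
            "statistic": float("nan"),
            "p_raw": float("nan"),
            "p_adj": float("nan"),
            "shapiro_p": float("nan"),
        }
    shapiro_p = float(stats.shapiro(diff).pvalue)
    if shapiro_p >= alpha:
        test = "paired_t"
        res = stats.ttest_rel(a, b)
    else:
        test = "wilcoxon"
        res = stats.wilcoxon(a, b)
    p_raw = float(res.pvalue)
    return {
        "test": test,
        "statistic": float(res.statistic),
        "p_raw": p_raw,
        "p_adj": min(1.0, bonferroni_k * p_raw),
        "shapiro_p": shapiro_p,
    }


def icc_two_way_random(
    matrix: pd.DataFrame | np.ndarray, alpha: float = 0.05
) -> ICCResult:
    """ICC(2,1): single-measure absolute agreement, two-way random effects.

    Parameters
    ----------
    matrix : subjects x raters (e.g. participants x days). Rows containing
        missing values are dropped and counted in ``n_dropped``.

    Notes
    -----
    From the two-way ANOVA mean squares (MSR between subjects, MSC between
    raters, MSE residual):

        ICC = (MSR - MSE) / (MSR + (k-1)*MSE + k*(MSC - MSE)/n)

    with the F-based confidence interval of McGraw & Wong. The estimate can
    be negative when within-subject variance dominates.
    """
    x = pd.DataFrame(matrix)
    n_before = len(x)
    x = x.dropna(axis=0)
    n_dropped = n_before - len(x)
    data = x.to_numpy(dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError(
            f"ICC needs at least 2 subjects and 2 raters, got {n}x{k}"
        )
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong F-based CI with Satterthwaite df
    a_coef = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b_coef = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a_coef):
        v = (a_coef * msc + b_coef * mse) ** 2 / (
            (a_coef * msc) ** 2 / (k - 1)
            + (b_coef * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        denom_const = k * msc + (k * n - k - n) * mse
        lower = n * (msr - f1 * mse) / (f1 * denom_const + n * msr)
        upper = n * (f2 * msr - mse) / (denom_const + n * f2 * msr)
    else:
        lower, upper = 1.0, 1.0
    return ICCResult(
        icc=float(icc),
        ci=(float(lower), float(upper)),
        model="two-way random, single measure, absolute agreement (ICC 2,1)",
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
        n_subjects=n,
        n_raters=k,
        n_dropped=n_dropped,
    )
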
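"""Statistical procedures: Mann-Whitney U, intraclass correlation,
Bland-Altman agreement and descriptive summaries.

Mann-Whitney U compares metric distributions between uptake grades.  The
intraclass correlation quantifies absolute agreement between operators'
repeated quantifications; the variant is ICC(2,1) — two-way random effects,
absolute agreement, single measures — selectable if a different convention
is required.  Bland-Altman summarizes intra-operator reproducibility as the
mean difference (bias) and 95% limits of agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["mann_whitney", "icc", "bland_altman", "describe", "Describe"]

#: Two-sided significance level used in reports.
ALPHA = 0.05


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U statistic (for the first sample) and two-sided p.

    The p-value is exact (full enumeration of rank assignments) when the
    pooled sample size is at most 12 and there are no ties; otherwise the
    normal approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def icc(matrix, variant: str = "icc2_1") -> float:
    """Intraclass correlation of a complete subjects-by-readers matrix.

    ``icc2_1`` (default): two-way random effects, absolute agreement,
    single measures,

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    from the two-way ANOVA mean squares (MSR rows/subjects, MSC columns/
    readers, MSE residual).  ``icc3_1`` (two-way mixed, consistency) is
    available for comparison with software that defaults to it.
    Zero between-subject variance yields 0 with a warning (agreement is
    undefined when subjects do not differ).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete matrix with >= 2 subjects and >= 2 readers")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains missing or non-finite cells")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if np.isclose(ss_rows, 0.0):
        warnings.warn("zero between-subject variance: ICC reported as 0")
        return 0.0
    if variant == "icc2_1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        return float((msr - mse) / denom)
    if variant == "icc3_1":
        return float((msr - mse) / (msr + (k - 1) * mse))
    raise ValueError(f"unknown ICC variant {variant!r}")


def bland_altman(a, b) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement for paired measurements.

    bias = mean(a - b); limits = bias -/+ 1.96 * sample SD of (a - b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


@dataclass
class Describe:
    mean: float
    sd_sample: float
    sd_population: float
    min: float
    max: float
    n: int


def describe(values) -> Describe:
    """Mean, both SD conventions, min, max of a non-empty sample.

    Both the n-1 (sample) and n (population) standard deviations are
    returned because published summary tables do not always state which
    convention they use; reporting layers default to the sample SD.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    sd_s = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return Describe(mean=float(v.mean()), sd_sample=sd_s,
                    sd_population=float(v.std(ddof=0)),
                    min=float(v.min()), max=float(v.max()), n=int(v.size))
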
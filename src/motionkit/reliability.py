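"""Agreement and accuracy statistics for raters and measurement systems.

The inter-rater agreement on ordinal severity scores is quantified by the
single-measure intraclass correlation under a two-way random-effects model
with absolute agreement — ICC(A,1) in the McGraw-Wong taxonomy — computed
from the two-way ANOVA mean squares, with the F-based 95% confidence
interval.  Tracking accuracy between two measurement systems is assessed
by the Pearson correlation of paired parameter sample sequences (per-trial
signals concatenated in acquisition order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import UndefinedStatisticError


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    label: str

    def to_dict(self) -> dict:
        return {
            "icc": self.icc, "ci95": [self.ci_low, self.ci_high], "label": self.label
        }


def _anova_mean_squares(scores: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x raters) ANOVA mean squares: rows, columns, error."""
    n, k = scores.shape
    grand = scores.mean()
    row_means = scores.mean(axis=1)
    col_means = scores.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((scores - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_absolute(matrix: np.ndarray, ci: float = 0.95) -> ICCResult:
    """Single-measure two-way random-effects absolute-agreement ICC.

    ``matrix`` is a complete subjects x raters score grid (>= 5 subjects,
    >= 2 raters).  The confidence interval follows the F-based method with
    a Satterthwaite denominator degrees-of-freedom approximation.  Zero
    between-subject variance yields ICC 0 with a warning.
    """
    scores = np.asarray(matrix, dtype=float)
    if scores.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x raters)")
    n, k = scores.shape
    if n < 5 or k < 2:
        raise ValueError(f"need >= 5 subjects and >= 2 raters, got {n}x{k}")
    if np.any(~np.isfinite(scores)):
        raise ValueError("rater grid has missing cells")

    msr, msc, mse = _anova_mean_squares(scores)
    if msr <= 1e-15:  # all subjects identical on average
        warnings.warn("zero between-subject variance: ICC reported as 0")
        return ICCResult(0.0, 0.0, 0.0, interpret_icc(0.0))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if icc >= 1.0 - 1e-12:  # perfect agreement: degenerate CI
        return ICCResult(1.0, 1.0, 1.0, interpret_icc(1.0))

    # F-based CI (two-way random, absolute agreement, single measure)
    alpha = 1.0 - ci
    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc))
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return ICCResult(float(icc), float(lower), float(upper), interpret_icc(float(icc)))


def interpret_icc(icc: float) -> str:
    """Conventional reliability band: poor / moderate / good / excellent.

    Cut points 0.5, 0.75 and 0.9; boundary values fall in the higher band.
    """
    if not -1.0 <= icc <= 1.0:
        raise ValueError("ICC must lie in [-1, 1]")
    if icc >= 0.9:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


@dataclass
class ParamSampleSeq:
    """Paired sample vectors of one parameter from two measurement systems,
    concatenated across trials in acquisition order."""

    name: str
    system_a: np.ndarray
    system_b: np.ndarray

    def __post_init__(self) -> None:
        self.system_a = np.asarray(self.system_a, dtype=float)
        self.system_b = np.asarray(self.system_b, dtype=float)
        if self.system_a.shape != self.system_b.shape:
            raise ValueError("paired sample vectors must have equal length")
        if self.system_a.size < 10:
            raise ValueError("need >= 10 paired samples")


def pearson_pss(pss: ParamSampleSeq) -> tuple[float, float]:
    """Pearson r (and two-sided p) between the two systems' sample sequences."""
    a, b = pss.system_a, pss.system_b
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedStatisticError(
            f"{pss.name}: zero variance, correlation undefined"
        )
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
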
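"""Method-agreement statistics for paired volume measurements.

Bundles the comparisons used to validate one flow-measurement method
against another: Bland–Altman bias and limits of agreement, the
intraclass correlation coefficient (two-way random effects, absolute
agreement, single measures — the standard form for method comparison),
Pearson correlation, a two-sided paired t-test and least-squares
regression.  ICC values are interpreted on a five-band scale from poor to
excellent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "AgreementResult",
    "bland_altman",
    "icc_agreement",
    "interpret_icc",
    "compare_methods",
    "write_agreement_json",
]

# Band cut-points: the published bands (0.0–0.3, 0.31–0.50, 0.51–0.70,
# 0.71–0.90, 0.91–1.00) leave the gaps (0.30, 0.31) etc. undefined; we close
# them with half-open intervals split at the midpoints.
_ICC_CUTS = (0.305, 0.505, 0.705, 0.905)
_ICC_LABELS = ("poor", "weak", "moderate", "strong", "excellent")


@dataclass
class AgreementResult:
    """Agreement summary between two measurement methods."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    icc: float
    icc_category: str
    pearson_r: float
    pearson_p: float
    paired_t_p: float
    slope: float
    intercept: float
    n: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _paired(a, b, min_n: int):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {a.size}")
    return a, b


def bland_altman(a, b) -> tuple[float, float, float, float]:
    """Bias, SD of the paired differences, and 95% limits of agreement.

    d = a − b; bias = mean(d); sd is the sample SD (n − 1 denominator);
    limits of agreement are bias ± 1.96 sd.
    """
    a, b = _paired(a, b, 2)
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def icc_agreement(a, b) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the ANOVA mean squares of the n×2 table: with MSR the
    between-subject, MSC the between-method and MSE the residual mean
    square,

        ICC = (MSR − MSE) / (MSR + MSE + 2 (MSC − MSE) / n).

    Returns NaN when the total variance is zero (agreement undefined).
    """
    a, b = _paired(a, b, 3)
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total <= 1e-12:
        return float("nan")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) <= 1e-12:
        return float("nan")
    return float((msr - mse) / denom)


def interpret_icc(icc: float) -> str:
    """Five-band interpretation: poor / weak / moderate / strong / excellent.

    Bands are half-open at the documented midpoint cut-points
    (0.305, 0.505, 0.705, 0.905); values below zero map to poor.
    """
    if not np.isfinite(icc):
        return "undefined"
    if not (-1.0 <= icc <= 1.0 + 1e-12):
        raise ValueError("ICC must lie in [-1, 1]")
    for cut, label in zip(_ICC_CUTS, _ICC_LABELS):
        if icc < cut:
            return label
    return _ICC_LABELS[-1]


def compare_methods(a, b) -> AgreementResult:
    """Full agreement bundle between paired measurements of two methods.

    Combines Bland–Altman, ICC with its category, Pearson r with p,
    a two-sided paired t-test and least-squares regression of a on b.
    The conventional 0.05 significance threshold is reported by the caller,
    not enforced here.  A zero-variance difference leaves the paired-t
    p-value NaN (flagged undefined).
    """
    a, b = _paired(a, b, 3)
    bias, sd, lo, hi = bland_altman(a, b)
    icc = icc_agreement(a, b)
    pearson = stats.pearsonr(a, b)
    if sd > 0:
        t_res = stats.ttest_rel(a, b)
        t_p = float(t_res.pvalue)
    else:
        t_p = float("nan")  # zero variance in differences: test undefined
    reg = stats.linregress(b, a)
    return AgreementResult(
        bias=bias,
        sd=sd,
        loa_low=lo,
        loa_high=hi,
        icc=icc,
        icc_category=interpret_icc(icc),
        pearson_r=float(pearson.statistic),
        pearson_p=float(pearson.pvalue),
        paired_t_p=t_p,
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        n=int(a.size),
    )


def write_agreement_json(result: AgreementResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(result.to_json())
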
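"""Segmentation overlap metrics and method-agreement statistics.

Overlap between an automatic mask A and a reference mask M is scored with
the Dice coefficient 2|A∩M|/(|A|+|M|) and the Jaccard index |A∩M|/|A∪M|
(algebraically J = D/(2−D)).  Agreement between two paired measurement
series uses Bland–Altman bias / limits of agreement and the two-way
random-effects, absolute-agreement intraclass correlation (single and
average measures, with F-based 95% confidence intervals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "SegMetrics",
    "AgreementResult",
    "dice",
    "jaccard",
    "seg_metrics",
    "pearson_fit",
    "bland_altman",
    "icc",
    "compare_methods",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """Raised for metrics undefined on the given input (e.g. two empty masks)."""


@dataclass(frozen=True)
class SegMetrics:
    dice: float
    jaccard: float
    v_a: int
    v_m: int
    v_am: int


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    loa_low: float
    loa_high: float
    icc_single: float
    icc_average: float
    icc_single_ci: tuple[float, float]
    icc_average_ci: tuple[float, float]
    pearson_r: float
    slope: float
    intercept: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")


def _as_masks(mask_a, mask_m) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(mask_a, dtype=bool)
    m = np.asarray(mask_m, dtype=bool)
    if a.shape != m.shape:
        raise ValueError("masks must share shape")
    return a, m


def dice(mask_a, mask_m) -> float:
    """Dice coefficient 2|A∩M|/(|A|+|M|); 1 iff the masks coincide as sets."""
    a, m = _as_masks(mask_a, mask_m)
    va, vm = int(a.sum()), int(m.sum())
    if va + vm == 0:
        raise UndefinedMetricError("both masks are empty")
    return 2.0 * int((a & m).sum()) / (va + vm)


def jaccard(mask_a, mask_m) -> float:
    """Jaccard index |A∩M|/|A∪M|."""
    a, m = _as_masks(mask_a, mask_m)
    union = int((a | m).sum())
    if union == 0:
        raise UndefinedMetricError("both masks are empty")
    return int((a & m).sum()) / union


def seg_metrics(mask_a, mask_m) -> SegMetrics:
    a, m = _as_masks(mask_a, mask_m)
    return SegMetrics(
        dice=dice(a, m),
        jaccard=jaccard(a, m),
        v_a=int(a.sum()),
        v_m=int(m.sum()),
        v_am=int((a & m).sum()),
    )


def pearson_fit(x, y) -> tuple[float, float, float]:
    """Pearson r and the OLS line of y on x: returns (r, slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D series of length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: fit is degenerate")
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.intercept)


def bland_altman(a, b) -> dict:
    """Bland–Altman agreement of paired series.

    Returns bias = mean(a−b), limits of agreement bias ± 1.96·sd(a−b)
    (sample sd, n−1 denominator; 0 for n == 1 or constant differences),
    plus the per-pair means and differences for plotting.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D series of length >= 2")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "means": (a + b) / 2.0,
        "diffs": diff,
    }


def icc(a, b, confidence: float = 0.95) -> dict:
    """Two-way random-effects, absolute-agreement intraclass correlation.

    Treats the two series as two raters scoring n subjects and returns the
    single-measure and average-measure (k = 2) coefficients with
    F-distribution confidence intervals.  With zero residual and zero
    rater variance but varying subjects the agreement is perfect (ICC 1);
    when the total variance is zero the coefficient is undefined and is
    returned as 1.0 with ``degenerate=True``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1-D series of length >= 3")
    n, k = len(a), 2
    x = np.column_stack([a, b])
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - gm) ** 2).sum())
    ssc = n * float(((col_means - gm) ** 2).sum())
    sst = float(((x - gm) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom_single = msr + (k - 1) * mse + k * (msc - mse) / n
    denom_avg = msr + (msc - mse) / n
    if denom_single <= 0 or denom_avg <= 0:
        warnings.warn("zero total variance: ICC undefined, reporting 1", stacklevel=2)
        return {
            "icc_single": 1.0,
            "icc_average": 1.0,
            "ci_single": (1.0, 1.0),
            "ci_average": (1.0, 1.0),
            "degenerate": True,
        }
    icc_1 = (msr - mse) / denom_single
    icc_k = (msr - mse) / denom_avg

    alpha = 1.0 - confidence
    if mse == 0.0 and msc == 0.0:
        ci1 = (1.0, 1.0)
    else:
        r = max(min(icc_1, 1 - 1e-12), -1 + 1e-12)
        av = k * r / (n * (1 - r))
        bv = 1 + k * r * (n - 1) / (n * (1 - r))
        num_v = (av * msc + bv * mse) ** 2
        den_v = (av * msc) ** 2 / (k - 1) + (bv * mse) ** 2 / ((n - 1) * (k - 1))
        v = num_v / den_v if den_v > 0 else 1.0
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = (
            n * (msr - f_l * mse)
            / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        upper = (
            n * (f_u * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
        )
        ci1 = (float(lower), float(upper))
    # average-measure bounds via the Spearman–Brown step-up of the single CI
    def _step_up(r1: float) -> float:
        return k * r1 / (1 + (k - 1) * r1) if (1 + (k - 1) * r1) != 0 else 1.0

    cik = (_step_up(ci1[0]), _step_up(ci1[1]))
    return {
        "icc_single": float(icc_1),
        "icc_average": float(icc_k),
        "ci_single": ci1,
        "ci_average": cik,
        "degenerate": False,
    }


def compare_methods(a, b) -> AgreementResult:
    """Full agreement report between two paired measurement series."""
    ba = bland_altman(a, b)
    ic = icc(a, b)
    try:
        r, slope, intercept = pearson_fit(a, b)
    except ValueError:
        r, slope, intercept = float("nan"), float("nan"), float("nan")
    return AgreementResult(
        bias=ba["bias"],
        loa_low=ba["loa_low"],
        loa_high=ba["loa_high"],
        icc_single=ic["icc_single"],
        icc_average=ic["icc_average"],
        icc_single_ci=ic["ci_single"],
        icc_average_ci=ic["ci_average"],
        pearson_r=r,
        slope=slope,
        intercept=intercept,
        degenerate=ic["degenerate"],
    )
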
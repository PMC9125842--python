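"""Method-agreement statistics for paired volume measurements.

Implements the single-rater, two-way random-effects, absolute-agreement
intraclass correlation ICC(A,1) from the two-way ANOVA mean squares, with
the F-distribution 95% confidence interval (McGraw & Wong parameterization),
plus Bland-Altman mean difference and 1.96-SD limits of agreement.  One pair
per subject; no repeated-measures correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AgreementResult", "icc_absolute_agreement", "bland_altman"]

LOA_MULTIPLIER = 1.96


@dataclass
class AgreementResult:
    icc: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    mean_diff: float | None = None
    loa_low: float | None = None
    loa_high: float | None = None
    n: int = 0

    def __post_init__(self) -> None:
        if self.icc is not None and self.ci_low is not None:
            if not (self.ci_low <= self.icc + 1e-12 and self.icc <= self.ci_high + 1e-12):
                raise ValueError("confidence interval must bracket the ICC")
        if self.mean_diff is not None and self.loa_low is not None:
            if not (self.loa_low <= self.mean_diff <= self.loa_high):
                raise ValueError("limits of agreement must bracket the mean difference")


def _paired(value_a, value_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(value_a, dtype=float)
    b = np.asarray(value_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("value_a and value_b must be 1D and paired")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("measurements must be finite")
    return a, b


def icc_absolute_agreement(
    value_a, value_b, confidence: float = 0.95
) -> AgreementResult:
    """ICC(A,1) for two measurement systems on the same subjects.

    Mean squares from the n x 2 two-way layout: MSR (subjects), MSC
    (methods), MSE (residual);
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).
    """
    a, b = _paired(value_a, value_b)
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    sst = ssr + ssc + sse
    if sst <= 1e-12 * max(1.0, grand**2):
        raise ValueError("zero total variance; ICC undefined")
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    # F-based interval for ICC(A,1); Satterthwaite df for the mixed term.
    if abs(1.0 - icc) < 1e-12:
        lo = hi = icc
    else:
        aa = (k * icc) / (n * (1.0 - icc))
        bb = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
        num = (aa * msc + bb * mse) ** 2
        den = (aa * msc) ** 2 / (k - 1) + (bb * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else (n - 1) * (k - 1)
        f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = (n * (msr - f_low * mse)) / (
            f_low * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = (n * (f_up * msr - mse)) / (
            k * msc + (k * n - k - n) * mse + n * f_up * msr
        )
        lo, hi = min(lo, icc), max(hi, icc)
    return AgreementResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi), n=n)


def bland_altman(value_a, value_b) -> tuple[AgreementResult, np.ndarray]:
    """Mean difference and 1.96-SD limits of agreement.

    Also returns the per-subject (mean, difference) coordinates for plotting.
    """
    a, b = _paired(value_a, value_b)
    diff = a - b
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    res = AgreementResult(
        mean_diff=mean_diff,
        loa_low=mean_diff - LOA_MULTIPLIER * sd,
        loa_high=mean_diff + LOA_MULTIPLIER * sd,
        n=a.size,
    )
    coords = np.column_stack([(a + b) / 2.0, diff])
    return res, coords


def bland_altman_plot(value_a, value_b, path) -> AgreementResult:
    """Write a Bland-Altman scatter with mean-difference and LoA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res, coords = bland_altman(value_a, value_b)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(coords[:, 0], coords[:, 1], s=18, color="tab:blue")
    ax.axhline(res.mean_diff, color="k", lw=1)
    for y in (res.loa_low, res.loa_high):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of methods (ml)")
    ax.set_ylabel("difference (ml)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return res
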
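"""Agreement statistics between estimated and reference RR series.

Two complementary views: the intraclass correlation coefficient ICC(A,1)
(two-way model, absolute agreement, single measure — sensitive to systematic
offsets, not just correlation) and Bland-Altman limits of agreement
(bias +/- 1.96 SD of the paired differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = [
    "PairedSeries",
    "IccResult",
    "BlandAltmanResult",
    "icc_a1",
    "bland_altman",
    "agreement_by_group",
]


@dataclass(frozen=True)
class PairedSeries:
    """Paired estimated/reference values (bpm), with optional source labels."""

    est: np.ndarray
    ref: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        est = np.asarray(self.est, dtype=np.float64)
        ref = np.asarray(self.ref, dtype=np.float64)
        if est.shape != ref.shape or est.ndim != 1:
            raise ValueError("est and ref must be equal-length 1-D sequences")
        if est.size < 2:
            raise ValueError(f"need at least 2 pairs, got {est.size}")
        if not (np.all(np.isfinite(est)) and np.all(np.isfinite(ref))):
            raise ValueError("non-finite values in paired series")
        object.__setattr__(self, "est", est)
        object.__setattr__(self, "ref", ref)
        if self.labels is not None:
            lab = np.asarray(self.labels)
            if lab.shape != est.shape:
                raise ValueError("labels must match the series length")
            object.__setattr__(self, "labels", lab)

    @property
    def n(self) -> int:
        return int(self.est.size)


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    alpha: float


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float  # mean(est - ref), bpm
    sd_diff: float  # SD of differences, N-1 denominator
    loa_low: float  # bias - 1.96 sd
    loa_high: float  # bias + 1.96 sd
    pearson_cc: float


def _two_way_mean_squares(pairs: PairedSeries) -> tuple[float, float, float, int, int]:
    """Mean squares of the two-way (subjects x raters) ANOVA decomposition."""
    x = np.column_stack([pairs.est, pairs.ref])  # n subjects, k=2 raters
    n, k = x.shape
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - gm) ** 2) / (n - 1)
    msc = n * np.sum((col_means - gm) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + gm
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse), n, k


def icc_a1(pairs: PairedSeries, alpha: float = 0.05) -> IccResult:
    """ICC(A,1): two-way model, absolute agreement, single measure.

    From the ANOVA mean squares (rows = subjects, columns = the two raters),

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

    with the confidence interval built from the F-distribution using a
    Satterthwaite-approximated denominator degree of freedom, following the
    standard absolute-agreement single-score construction.
    """
    msr, msc, mse, n, k = _two_way_mean_squares(pairs)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        raise ValueError("zero total variance: ICC undefined for constant data")
    icc = (msr - mse) / denom

    if icc >= 1.0 or mse == 0.0:
        # perfect agreement: the interval degenerates
        return IccResult(icc=float(icc), ci_low=float(icc), ci_high=float(icc), alpha=alpha)

    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_low = scipy.stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_up = scipy.stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    ci_low = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ci_high = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return IccResult(icc=float(icc), ci_low=float(ci_low), ci_high=float(ci_high), alpha=alpha)


def bland_altman(pairs: PairedSeries) -> BlandAltmanResult:
    """Bias and 95% limits of agreement of the paired differences.

    ``d = est - ref``; limits are ``bias +/- 1.96 * sd(d)`` with the
    (N-1)-denominator standard deviation and the fixed normal multiplier.
    Pearson correlation of the two series is attached for reference.
    """
    d = pairs.est - pairs.ref
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if np.ptp(pairs.est) == 0 or np.ptp(pairs.ref) == 0:
        cc = float("nan")  # correlation undefined for a constant series
    else:
        cc = float(scipy.stats.pearsonr(pairs.est, pairs.ref).statistic)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        pearson_cc=cc,
    )


def agreement_by_group(
    pairs: PairedSeries, alpha: float = 0.05
) -> dict[str, tuple[IccResult, BlandAltmanResult]]:
    """Stratified + combined agreement, keyed by label (``"combined"`` always present)."""
    out: dict[str, tuple[IccResult, BlandAltmanResult]] = {}
    if pairs.labels is not None:
        for lab in dict.fromkeys(pairs.labels.tolist()):  # preserve first-seen order
            sel = pairs.labels == lab
            sub = PairedSeries(pairs.est[sel], pairs.ref[sel])
            out[str(lab)] = (icc_a1(sub, alpha), bland_altman(sub))
    out["combined"] = (icc_a1(pairs, alpha), bland_altman(pairs))
    return out
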
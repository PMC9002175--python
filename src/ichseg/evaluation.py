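"""Segmentation-overlap metrics and method-agreement statistics.

Overlap between an algorithmic mask AV and a reference mask GT is
summarized by the voxelwise confusion table and the derived
sensitivity Sen = TP/(TP+FN), positive predictive value PPV = TP/(TP+FP),
Dice similarity index DSI = 2TP/(2TP+FP+FN) and Jaccard index
JI = |AV∩GT| / |AV∪GT| = TP/(TP+FP+FN).

Agreement between two volume series (in mL) is assessed with the
intraclass correlation coefficient — by default ICC(2,1): two-way
random effects, absolute agreement, single measures, the standard choice
for method comparison of continuous measurements — and with Bland–Altman
limits of agreement (mean difference ± 1.96 × SD of the differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .region_growing import SegmentationMask


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class SimilarityMetrics:
    """Overlap metrics in [0, 1]; ``None`` marks an undefined metric
    (zero denominator), never silently 0."""

    sen: float | None
    ppv: float | None
    dsi: float | None
    ji: float | None


@dataclass(frozen=True)
class ICCResult:
    value: float
    ci_lower: float
    ci_upper: float
    form: str = "ICC2_1"


@dataclass(frozen=True)
class BlandAltman:
    """Agreement summary for paired differences d = a - b (mL)."""

    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_mean_lower: float
    ci_mean_upper: float
    differences: tuple[float, ...]
    means: tuple[float, ...]


def confusion(av: SegmentationMask | np.ndarray,
              gt: SegmentationMask | np.ndarray) -> ConfusionCounts:
    """Voxelwise 2x2 table of an algorithmic mask against a reference."""
    a = av.astype_bool() if isinstance(av, SegmentationMask) else np.asarray(av, bool)
    g = gt.astype_bool() if isinstance(gt, SegmentationMask) else np.asarray(gt, bool)
    if a.shape != g.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {g.shape}")
    tp = int(np.count_nonzero(a & g))
    fp = int(np.count_nonzero(a & ~g))
    fn = int(np.count_nonzero(~a & g))
    tn = int(np.count_nonzero(~a & ~g))
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def similarity(c: ConfusionCounts) -> SimilarityMetrics:
    def ratio(num, den):
        return num / den if den > 0 else None

    return SimilarityMetrics(
        sen=ratio(c.TP, c.TP + c.FN),
        ppv=ratio(c.TP, c.TP + c.FP),
        dsi=ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN),
        ji=ratio(c.TP, c.TP + c.FP + c.FN),
    )


def _mean_squares(data: np.ndarray):
    """Two-way ANOVA mean squares for an n x k table (cases x methods)."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_total - ss_rows) / (n * (k - 1))
    return msr, msc, mse, msw


def icc(volumes_a, volumes_b, form: str = "ICC2_1",
        alpha: float = 0.05) -> ICCResult:
    """Intraclass correlation between two paired measurement series.

    ``form`` selects the Shrout–Fleiss convention: ICC2_1 (two-way random,
    absolute agreement, default), ICC3_1 (two-way mixed, consistency) or
    ICC1_1 (one-way random).  The 95% CI uses the McGraw–Wong F-based
    formulas; for ICC2_1 the degrees of freedom follow the
    Satterthwaite-style approximation.
    """
    a = np.asarray(volumes_a, dtype=float)
    b = np.asarray(volumes_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("volume series must be 1-D and equal length")
    n = a.size
    if n < 3:
        raise ValidationError(f"need at least 3 paired cases, got {n}")
    data = np.column_stack([a, b])
    k = 2
    msr, msc, mse, msw = _mean_squares(data)

    if form == "ICC2_1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0:
            return ICCResult(1.0, 1.0, 1.0, form)
        value = (msr - mse) / denom
        if mse == 0 and msc == 0:
            return ICCResult(value, value, value, form)
        a_ = k * value / (n * (1 - value)) if value < 1 else np.inf
        b_ = 1 + k * value * (n - 1) / (n * (1 - value)) if value < 1 else np.inf
        if np.isinf(a_):
            lower = upper = 1.0
        else:
            v = (a_ * msc + b_ * mse) ** 2 / (
                (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1)))
            f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lower = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
            upper = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr)
    elif form == "ICC3_1":
        denom = msr + (k - 1) * mse
        if denom == 0:
            return ICCResult(1.0, 1.0, 1.0, form)
        value = (msr - mse) / denom
        if mse == 0:
            return ICCResult(value, value, value, form)
        f_obs = msr / mse
        df2 = (n - 1) * (k - 1)
        f_l = f_obs / stats.f.ppf(1 - alpha / 2, n - 1, df2)
        f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, n - 1)
        lower = (f_l - 1) / (f_l + k - 1)
        upper = (f_u - 1) / (f_u + k - 1)
    elif form == "ICC1_1":
        denom = msr + (k - 1) * msw
        if denom == 0:
            return ICCResult(1.0, 1.0, 1.0, form)
        value = (msr - msw) / denom
        if msw == 0:
            return ICCResult(value, value, value, form)
        f_obs = msr / msw
        df2 = n * (k - 1)
        f_l = f_obs / stats.f.ppf(1 - alpha / 2, n - 1, df2)
        f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, n - 1)
        lower = (f_l - 1) / (f_l + k - 1)
        upper = (f_u - 1) / (f_u + k - 1)
    else:
        raise ValidationError(f"unknown ICC form {form!r}")
    return ICCResult(float(value), float(min(lower, value)),
                     float(max(upper, value)), form)


def bland_altman(volumes_a, volumes_b) -> BlandAltman:
    """Bland–Altman agreement summary for d = a - b.

    Reports both the limits of agreement (mean ± 1.96 SD, SD with n-1
    denominator) and the 95% CI of the mean difference, labeled
    separately — they answer different questions.
    """
    a = np.asarray(volumes_a, dtype=float)
    b = np.asarray(volumes_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("volume series must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise ValidationError(f"need at least 2 paired cases, got {n}")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    t = float(stats.t.ppf(0.975, n - 1))
    half = t * sd / np.sqrt(n)
    return BlandAltman(
        mean_diff=mean, sd_diff=sd,
        loa_lower=mean - 1.96 * sd, loa_upper=mean + 1.96 * sd,
        ci_mean_lower=mean - half, ci_mean_upper=mean + half,
        differences=tuple(float(x) for x in d),
        means=tuple(float(x) for x in (a + b) / 2.0),
    )


def plot_bland_altman(ba: BlandAltman, path, title: str = "Bland-Altman") -> None:
    """Render the classic Bland–Altman scatter with mean and limits."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ba.means, ba.differences, s=18, alpha=0.8)
    for y, style in [(ba.mean_diff, "-"), (ba.loa_lower, "--"),
                     (ba.loa_upper, "--")]:
        ax.axhline(y, color="crimson", linestyle=style, linewidth=1)
    ax.set_xlabel("Mean of methods (mL)")
    ax.set_ylabel("Difference (mL)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
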
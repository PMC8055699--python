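"""Method-agreement and repeatability statistics.

Implements Bland-Altman limits of agreement, the two-way random-effects
intraclass correlation coefficient ICC(2,1) (absolute agreement, single
measure) with its F-based 95% confidence interval, and per-subject absolute
inter-eye difference summaries.  Group comparisons are delegated to stock
rank-sum routines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

ICC_FORM = "ICC(2,1) two-way random, absolute agreement, single measure"


@dataclass
class PairedSeries:
    """Two aligned measurement series (e.g. manual vs automated SI)."""

    ids: Sequence[str]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (len(self.ids) == len(self.a) == len(self.b)):
            raise ValueError("ids, a and b must have equal length")
        if len(self.a) < 2:
            raise ValueError("need at least 2 pairs")
        if not (np.isfinite(self.a).all() and np.isfinite(self.b).all()):
            raise ValueError("missing or non-finite values in paired series")

    def __len__(self) -> int:
        return len(self.a)


@dataclass
class AgreementReport:
    mean_diff: float
    loa_lower: float
    loa_upper: float
    n: int
    icc: Optional[float] = None
    icc_ci: Optional[Tuple[float, float]] = None
    icc_form: str = ICC_FORM

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "n": self.n,
            "icc": self.icc,
            "icc_ci": list(self.icc_ci) if self.icc_ci is not None else None,
            "icc_form": self.icc_form,
        }


def bland_altman(pairs: PairedSeries, plot_path: Optional[str] = None) -> AgreementReport:
    """Mean difference and 1.96-SD limits of agreement for a-b.

    The SD uses the n-1 denominator.  When ``plot_path`` is given, the
    standard difference-vs-mean plot with three horizontal lines is written
    there.
    """
    diffs = pairs.a - pairs.b
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lower, upper = mean_diff - 1.96 * sd, mean_diff + 1.96 * sd
    if plot_path is not None:
        _bland_altman_plot(pairs, mean_diff, lower, upper, plot_path)
    return AgreementReport(mean_diff=mean_diff, loa_lower=lower, loa_upper=upper, n=len(pairs))


def _bland_altman_plot(pairs, mean_diff, lower, upper, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = (pairs.a + pairs.b) / 2.0
    diffs = pairs.a - pairs.b
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=18, color="tab:blue")
    for y, style in ((mean_diff, "-"), (lower, "--"), (upper, "--")):
        ax.axhline(y, linestyle=style, color="tab:red", linewidth=1)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (a - b)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def icc_two_way_random(
    ratings: np.ndarray, alpha: float = 0.05
) -> Tuple[float, Tuple[float, float]]:
    """ICC(2,1) and its confidence interval from the two-way ANOVA terms.

    ``ratings`` is an ``n x k`` matrix (subjects by raters/methods).  Returns
    ``(icc, (ci_lower, ci_upper))``.  Zero between-subject variance yields
    ``icc = 0`` with a warning instead of an error.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an n x k matrix with n >= 2, k >= 2")
    if not np.isfinite(x).all():
        raise ValueError("ratings contain missing values")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if np.isclose(msr, 0.0, atol=1e-30) or np.isclose(denom, 0.0, atol=1e-30):
        warnings.warn("degenerate variance structure: between-subject variance is zero")
        return 0.0, (0.0, 0.0)
    icc = (msr - mse) / denom
    if np.isclose(mse, 0.0, atol=1e-30) and np.isclose(msc, 0.0, atol=1e-30):
        # perfect agreement: the F-based interval degenerates
        return float(icc), (float(icc), float(icc))

    # McGraw & Wong F-based interval for ICC(A,1)
    a_ = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b_ = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a_):
        return float(icc), (float(icc), float(icc))
    v = (a_ * msc + b_ * mse) ** 2 / (
        (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(icc), (float(lower), float(upper))


@dataclass
class InterEyeSummary:
    diffs: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)
    median: float = field(init=False)
    range: Tuple[float, float] = field(init=False)
    n: int = field(init=False)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.diffs, dtype=float)
        self.diffs = d
        self.mean = float(d.mean())
        self.sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
        self.median = float(np.median(d))
        self.range = (float(d.min()), float(d.max()))
        self.n = len(d)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "range": list(self.range),
            "n": self.n,
            "n_skipped": self.n_skipped,
        }


def inter_eye_difference(per_subject: Sequence[Tuple[Optional[float], Optional[float]]]) -> InterEyeSummary:
    """Per-subject absolute |SI_right - SI_left| and its summary statistics.

    Subjects missing a fellow eye are skipped with a warning.  Symmetric in
    eye order.
    """
    diffs: List[float] = []
    skipped = 0
    for i, (right, left) in enumerate(per_subject):
        if right is None or left is None or not np.isfinite([right, left]).all():
            warnings.warn(f"subject index {i}: missing fellow eye, skipped")
            skipped += 1
            continue
        diffs.append(abs(float(right) - float(left)))
    if not diffs:
        raise ValueError("no complete eye pairs")
    return InterEyeSummary(diffs=np.asarray(diffs), n_skipped=skipped)


def compare_groups(diffs_a: Sequence[float], diffs_b: Sequence[float]) -> dict:
    """Rank-sum comparison of two groups of inter-eye differences (plumbing)."""
    stat, p = stats.mannwhitneyu(diffs_a, diffs_b, alternative="two-sided")
    return {"statistic": float(stat), "p_value": float(p), "test": "Mann-Whitney U"}
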
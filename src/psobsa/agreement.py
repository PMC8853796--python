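"""Method-agreement statistics between two per-image BSA ratio series.

The model-estimated psoriasis-to-body ratio is compared against the
reference (dermatologist-style ground truth) reading on the same images
with two standard instruments:

* the intraclass correlation coefficient for absolute agreement on single
  measurements, ICC(A,1) in the McGraw-Wong taxonomy, computed directly
  from the two-way ANOVA mean squares so the confidence-interval
  construction is itself testable; and
* Bland-Altman analysis: bias = mean(model - reference) and limits of
  agreement bias +/- 1.96 * SD of the paired differences, optionally
  restricted to images whose reference ratio is below a cut (the < 50%
  subset isolates agreement away from the severe high-area cases).

With n subjects and k = 2 methods, writing MSR, MSC and MSE for the
between-subject, between-method and residual mean squares:

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

CI endpoints follow the McGraw-Wong F-based construction with the
Satterthwaite degrees of freedom, reported in ascending order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats


@dataclass
class PairedSeries:
    """Two aligned per-image measurement series (a = reference, b = model)."""

    ids: list[str]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (len(self.ids) == self.a.size == self.b.size):
            raise ValueError("ids, a and b must have equal lengths")
        if self.a.size < 2:
            raise ValueError("need at least 2 paired measurements")

    def __len__(self) -> int:
        return self.a.size


@dataclass
class AgreementReport:
    """ICC and Bland-Altman estimates for one paired series."""

    icc: float
    icc_ci_low: float
    icc_ci_high: float
    ba_bias: float
    ba_loa_low: float
    ba_loa_high: float
    n_used: int
    subset_rule: str = "all pairs"

    def summary(self) -> str:
        lines = [
            "Agreement report",
            "================",
            f"n used                 {self.n_used}",
            f"subset rule            {self.subset_rule}",
            f"ICC(A,1)               {self.icc:.4f}",
            f"  95% CI               [{self.icc_ci_low:.4f}, "
            f"{self.icc_ci_high:.4f}]",
            f"Bland-Altman bias      {self.ba_bias:+.5f}",
            f"  limits of agreement  [{self.ba_loa_low:+.5f}, "
            f"{self.ba_loa_high:+.5f}]",
        ]
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "icc": self.icc, "icc_ci_low": self.icc_ci_low,
            "icc_ci_high": self.icc_ci_high, "ba_bias": self.ba_bias,
            "ba_loa_low": self.ba_loa_low, "ba_loa_high": self.ba_loa_high,
            "n_used": self.n_used, "subset_rule": self.subset_rule,
        }


class DegenerateSeriesError(ValueError):
    """Raised when the ICC is undefined (no variance anywhere)."""


def _anova_mean_squares(a: np.ndarray, b: np.ndarray):
    """Two-way (subjects x methods) ANOVA mean squares for k = 2."""
    data = np.stack([a, b], axis=1)  # (n, k)
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return msr, msc, mse, n, k


def icc_absolute_agreement_single(series: PairedSeries, alpha: float = 0.05,
                                  ) -> tuple[float, float, float]:
    """ICC(A,1) with its (1 - alpha) confidence interval.

    Returns ``(icc, ci_low, ci_high)`` with endpoints in ascending order.
    A series with zero variance everywhere has no defined ICC and raises
    :class:`DegenerateSeriesError` instead of silently returning 1.
    """
    msr, msc, mse, n, k = _anova_mean_squares(series.a, series.b)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or np.allclose([msr, msc, mse], 0.0):
        raise DegenerateSeriesError("total variance is zero; ICC undefined")
    icc = (msr - mse) / denom

    if mse == 0.0 and msc == 0.0:
        # exact agreement: the interval collapses at 1
        return 1.0, 1.0, 1.0

    # McGraw-Wong CI for ICC(A,1), Satterthwaite df for the mixture term
    a_coef = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b_coef = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a_coef):
        num = (a_coef * msc + b_coef * mse) ** 2
        den = ((a_coef * msc) ** 2 / (k - 1)
               + (b_coef * mse) ** 2 / ((n - 1) * (k - 1)))
        v = num / den if den > 0 else (n - 1) * (k - 1)
    else:
        v = (n - 1) * (k - 1)
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (n * (msr - f_l * mse)
             / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
    upper = (n * (f_u * msr - mse)
             / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    lo, hi = sorted((float(lower), float(upper)))
    return float(icc), lo, hi


def bland_altman(series: PairedSeries,
                 max_reference_ratio: float | None = None,
                 ) -> tuple[dict, np.ndarray, np.ndarray]:
    """Bland-Altman bias and limits of agreement for b - a differences.

    ``max_reference_ratio`` (e.g. 0.50) keeps only pairs whose reference
    value ``a`` is strictly below the cut before computing the statistics.
    Returns the statistics dict plus the per-pair means and differences
    for plotting.
    """
    keep = np.ones(len(series), dtype=bool)
    rule = "all pairs"
    if max_reference_ratio is not None:
        keep = series.a < max_reference_ratio
        rule = f"reference ratio < {max_reference_ratio}"
    if keep.sum() < 2:
        raise ValueError("fewer than 2 pairs remain after filtering")
    a, b = series.a[keep], series.b[keep]
    diffs = b - a
    means = 0.5 * (a + b)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    stats_d = {
        "ba_bias": bias,
        "ba_loa_low": bias - 1.96 * sd,
        "ba_loa_high": bias + 1.96 * sd,
        "n_used": int(keep.sum()),
        "subset_rule": rule,
    }
    return stats_d, means, diffs


def agreement_report(series: PairedSeries,
                     max_reference_ratio: float | None = None,
                     alpha: float = 0.05) -> AgreementReport:
    """ICC(A,1) + Bland-Altman on one (optionally subset) paired series."""
    ba, _, _ = bland_altman(series, max_reference_ratio)
    if max_reference_ratio is not None:
        keep = series.a < max_reference_ratio
        sub = PairedSeries(ids=[i for i, k in zip(series.ids, keep) if k],
                           a=series.a[keep], b=series.b[keep])
    else:
        sub = series
    icc, lo, hi = icc_absolute_agreement_single(sub, alpha=alpha)
    return AgreementReport(icc=icc, icc_ci_low=lo, icc_ci_high=hi,
                           n_used=ba["n_used"], subset_rule=ba["subset_rule"],
                           ba_bias=ba["ba_bias"],
                           ba_loa_low=ba["ba_loa_low"],
                           ba_loa_high=ba["ba_loa_high"])


def scatter_and_ba_plots(series: PairedSeries, report: AgreementReport,
                         out_dir: Path | str,
                         prefix: str = "agreement") -> tuple[Path, Path]:
    """Write the identity-line scatter and the Bland-Altman figure."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(series.a, series.b, s=18, alpha=0.8, edgecolor="none")
    lim = max(1e-6, float(max(series.a.max(), series.b.max())) * 1.05)
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="identity")
    ax.set_xlabel("reference psoriasis/body ratio")
    ax.set_ylabel("model psoriasis/body ratio")
    ax.set_title(f"ICC(A,1) = {report.icc:.3f}")
    ax.legend()
    scatter_path = out_dir / f"{prefix}_scatter.png"
    fig.savefig(scatter_path, dpi=120, bbox_inches="tight")
    plt.close(fig)

    _, means, diffs = bland_altman(series)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=18, alpha=0.8, edgecolor="none")
    ax.axhline(report.ba_bias, color="C1", lw=1.2, label="bias")
    ax.axhline(report.ba_loa_low, color="C3", ls="--", lw=1)
    ax.axhline(report.ba_loa_high, color="C3", ls="--", lw=1,
               label="limits of agreement")
    ax.set_xlabel("mean of paired ratios")
    ax.set_ylabel("model - reference")
    ax.legend()
    ba_path = out_dir / f"{prefix}_bland_altman.png"
    fig.savefig(ba_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return scatter_path, ba_path
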
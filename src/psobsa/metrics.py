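"""Pixel-level segmentation indices, BSA ratios, and summary tables.

The five classical indices are computed one-vs-rest for a designated
positive class (psoriasis, label 2, for the headline numbers):

    ACC = (correct pixels) / (all pixels)        [3-class overall accuracy]
    JI  = TP / (TP + FP + FN)                    [Jaccard / IoU]
    DSC = 2*TP / (2*TP + FN + FP)                [Dice]
    SE  = TP / (TP + FN)                         [sensitivity]
    SP  = TN / (TN + FP)                         [specificity]

JI, DSC and SE are *undefined* (returned as NaN and excluded from summary
counts) on images whose denominators vanish — e.g. no psoriasis in either
truth or prediction — rather than being coerced to 0 or 1.  The body
surface area ratio is psoriasis pixels over body (skin + psoriasis)
pixels, and the residual of an image is the absolute difference between
the reference and predicted ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import PSORIASIS, SKIN

UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest TP/FP/FN/TN pixel totals for a positive class."""

    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    acc: float
    ji: float
    dsc: float
    se: float
    sp: float
    image_id: str = ""

    def as_dict(self) -> dict:
        return {"image_id": self.image_id, "acc": self.acc, "ji": self.ji,
                "dsc": self.dsc, "se": self.se, "sp": self.sp}


@dataclass
class RatioPair:
    true_ratio: float
    predicted_ratio: float
    image_id: str = ""

    @property
    def residual(self) -> float:
        return residual(self.true_ratio, self.predicted_ratio)


def confusion_counts(pred_mask: np.ndarray, true_mask: np.ndarray,
                     positive_class: int = PSORIASIS) -> ConfusionCounts:
    """Tally one-vs-rest confusion totals over every pixel."""
    pred_mask = np.asarray(pred_mask)
    true_mask = np.asarray(true_mask)
    if pred_mask.shape != true_mask.shape:
        raise ValueError(f"mask shapes differ: {pred_mask.shape} vs "
                         f"{true_mask.shape}")
    p = pred_mask == positive_class
    t = true_mask == positive_class
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn,
                           positive_class=positive_class)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def segmentation_metrics(pred_mask: np.ndarray, true_mask: np.ndarray,
                         positive_class: int = PSORIASIS,
                         image_id: str = "",
                         binary_accuracy: bool = False) -> MetricsReport:
    """All five indices for one image.

    ACC is by default the overall 3-class pixel accuracy across
    background/skin/psoriasis; ``binary_accuracy=True`` switches it to the
    one-vs-rest accuracy (TP+TN)/(TP+TN+FP+FN) of the positive class.
    JI/DSC/SE come back as NaN when their denominators are zero.
    """
    c = confusion_counts(pred_mask, true_mask, positive_class)
    if binary_accuracy:
        acc = _safe_div(c.tp + c.tn, c.total)
    else:
        acc = float(np.count_nonzero(np.asarray(pred_mask) ==
                                     np.asarray(true_mask)) / c.total)
    return MetricsReport(
        acc=acc,
        ji=_safe_div(c.tp, c.tp + c.fp + c.fn),
        dsc=_safe_div(2 * c.tp, 2 * c.tp + c.fn + c.fp),
        se=_safe_div(c.tp, c.tp + c.fn),
        sp=_safe_div(c.tn, c.tn + c.fp),
        image_id=image_id,
    )


def psoriasis_ratio(mask: np.ndarray) -> float:
    """Psoriasis / (skin + psoriasis) pixel fraction; NaN with no body."""
    mask = np.asarray(mask)
    pso = int(np.count_nonzero(mask == PSORIASIS))
    body = pso + int(np.count_nonzero(mask == SKIN))
    return _safe_div(pso, body)


def residual(true_ratio: float, predicted_ratio: float) -> float:
    """Absolute difference of the two area ratios (the residual percentage)."""
    for v in (true_ratio, predicted_ratio):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"ratio {v} outside [0, 1]")
    return abs(predicted_ratio - true_ratio)


def signed_difference(true_ratio: float, predicted_ratio: float) -> float:
    """Predicted minus reference ratio (what Bland-Altman analysis needs)."""
    return predicted_ratio - true_ratio


@dataclass
class SummaryTable:
    """Count/mean/std/min/Q1/Q2/Q3/max row of an evaluation table."""

    count: int
    mean: float
    std: float
    min: float
    q1: float
    q2: float
    q3: float
    max: float

    def as_dict(self) -> dict:
        return {"count": self.count, "mean": self.mean, "std": self.std,
                "min": self.min, "q1": self.q1, "q2": self.q2,
                "q3": self.q3, "max": self.max}


def summarize(values, drop_undefined: bool = True) -> SummaryTable:
    """Summary statistics with undefined (NaN) entries excluded.

    The reported count reflects the exclusion, so a metric undefined on 2
    of 49 images reports count 47.  Quartiles use linear interpolation
    between order statistics; std is the sample standard deviation
    (ddof=1, or 0.0 for a single value).
    """
    arr = np.asarray(list(values), dtype=float)
    if drop_undefined:
        arr = arr[~np.isnan(arr)]
    elif np.isnan(arr).any():
        raise ValueError("undefined values present with drop_undefined=False")
    if arr.size == 0:
        raise ValueError("no defined values to summarise")
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    return SummaryTable(
        count=int(arr.size),
        mean=float(arr.mean()),
        std=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        min=float(arr.min()), q1=float(q1), q2=float(q2), q3=float(q3),
        max=float(arr.max()),
    )


def metrics_frame(reports: list[MetricsReport],
                  ratios: list[RatioPair] | None = None) -> pd.DataFrame:
    """Per-image table: one row per image, metric columns plus ratios."""
    df = pd.DataFrame([r.as_dict() for r in reports])
    if ratios is not None:
        rdf = pd.DataFrame(
            [{"image_id": rp.image_id, "true_ratio": rp.true_ratio,
              "pred_ratio": rp.predicted_ratio, "residual": rp.residual}
             for rp in ratios]
        )
        df = df.merge(rdf, on="image_id", how="left")
    return df


def summary_frame(df: pd.DataFrame, columns: list[str] | None = None,
                  ) -> pd.DataFrame:
    """Stack per-metric SummaryTable rows into a table-style DataFrame."""
    columns = columns or ["acc", "ji", "dsc", "se", "sp"]
    rows = {col: summarize(df[col].to_numpy()).as_dict() for col in columns}
    return pd.DataFrame(rows)
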
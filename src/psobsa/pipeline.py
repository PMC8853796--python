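"""End-to-end orchestration: simulate -> tile -> train -> predict -> evaluate.

The functions here glue the synthetic-data generator, the tiler, the
network and the evaluation/agreement statistics into the full measurement
pipeline, and are what both the command-line interface and the
reproduction script drive.  An *oracle* mode substitutes the ground-truth
masks for the network's predictions, which exercises the measurement half
of the pipeline (ratios, residuals, ICC, Bland-Altman) independently of
any trained model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as em
from .agreement import PairedSeries, agreement_report, scatter_and_ba_plots
from .synthdata import (
    DatasetManifest,
    generate_dataset,
    load_labeled_image,
)
from .tiling import extract_patches, filter_background_patches
from .unet import SegNetConfig, TrainConfig, UNet

logger = logging.getLogger(__name__)


@dataclass
class EvaluationResult:
    """Everything cmd-evaluate produces, as in-memory objects."""

    per_image: pd.DataFrame
    metric_summary: pd.DataFrame
    residual_summary: pd.DataFrame
    agreement_all: dict
    agreement_subset: dict | None = None


def patches_from_manifest(manifest: DatasetManifest, split: str,
                          patch_size: int = 512,
                          min_foreground_fraction: float = 0.0,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Tile every image of a split and drop background-only patches."""
    imgs, masks = [], []
    for entry in manifest.entries:
        if entry.split != split:
            continue
        img = load_labeled_image(entry.image_path, entry.mask_path, entry.id)
        _, patches = extract_patches(img, patch_size=patch_size)
        for p in filter_background_patches(patches, min_foreground_fraction):
            imgs.append(p.pixels)
            masks.append(p.mask)
    if not imgs:
        raise ValueError(f"no foreground patches in split '{split}'")
    return np.stack(imgs), np.stack(masks)


def train_from_manifest(manifest: DatasetManifest, net_config: SegNetConfig,
                        train_config: TrainConfig, patch_size: int = 512,
                        early_stop_val_acc: float | None = None) -> tuple:
    """Build and train a model on the manifest's train/val splits."""
    xtr, ytr = patches_from_manifest(manifest, "train", patch_size)
    try:
        xva, yva = patches_from_manifest(manifest, "val", patch_size)
    except ValueError:
        xva = yva = None
    model = UNet(net_config)
    logger.info("training on %d patches (%d val), %d parameters",
                len(xtr), 0 if xva is None else len(xva),
                model.parameter_count())
    history = model.fit(xtr, ytr, xva, yva, train_config,
                        early_stop_val_acc=early_stop_val_acc)
    return model, history


def evaluate_split(manifest: DatasetManifest, split: str = "test",
                   model: UNet | None = None, oracle: bool = False,
                   subset_threshold: float | None = 0.5,
                   binary_accuracy: bool = False,
                   max_pixels: int | None = None) -> EvaluationResult:
    """Per-image indices, ratio residuals and agreement for one split.

    With ``oracle=True`` the ground-truth mask stands in for the model
    prediction (a pipeline self-consistency mode); otherwise ``model``
    must be given.
    """
    if not oracle and model is None:
        raise ValueError("need a model unless oracle=True")
    reports, ratios = [], []
    for entry in manifest.entries:
        if entry.split != split:
            continue
        img = load_labeled_image(entry.image_path, entry.mask_path, entry.id)
        if oracle:
            pred = img.mask
        else:
            pred, _ = model.predict_image(img.pixels, max_pixels=max_pixels)
        reports.append(em.segmentation_metrics(
            pred, img.mask, image_id=entry.id,
            binary_accuracy=binary_accuracy))
        ratios.append(em.RatioPair(
            true_ratio=em.psoriasis_ratio(img.mask),
            predicted_ratio=em.psoriasis_ratio(pred),
            image_id=entry.id))
    if not reports:
        raise ValueError(f"split '{split}' is empty")
    per_image = em.metrics_frame(reports, ratios)
    metric_summary = em.summary_frame(per_image)
    residual_summary = em.summary_frame(per_image, columns=["residual"])

    series = PairedSeries(ids=per_image["image_id"].tolist(),
                          a=per_image["true_ratio"].to_numpy(),
                          b=per_image["pred_ratio"].to_numpy())
    agg_all = agreement_report(series).as_dict()
    agg_sub = None
    if subset_threshold is not None:
        try:
            agg_sub = agreement_report(
                series, max_reference_ratio=subset_threshold).as_dict()
        except ValueError:
            logger.warning("subset rule leaves <2 pairs; subset skipped")
    return EvaluationResult(per_image=per_image,
                            metric_summary=metric_summary,
                            residual_summary=residual_summary,
                            agreement_all=agg_all,
                            agreement_subset=agg_sub)


def write_evaluation(result: EvaluationResult, out_dir: Path | str,
                     make_figures: bool = True) -> None:
    """Persist an EvaluationResult as CSV/JSON (+ optional figures)."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.per_image.to_csv(out_dir / "per_image_metrics.csv", index=False)
    result.metric_summary.to_csv(out_dir / "metric_summary.csv")
    result.residual_summary.to_csv(out_dir / "residual_summary.csv")
    agg = {"all": result.agreement_all}
    if result.agreement_subset is not None:
        agg["subset"] = result.agreement_subset
    with open(out_dir / "agreement.json", "w") as fh:
        json.dump(agg, fh, indent=2)
    if make_figures:
        from .agreement import AgreementReport

        series = PairedSeries(
            ids=result.per_image["image_id"].tolist(),
            a=result.per_image["true_ratio"].to_numpy(),
            b=result.per_image["pred_ratio"].to_numpy())
        scatter_and_ba_plots(series,
                             AgreementReport(**result.agreement_all),
                             out_dir)
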
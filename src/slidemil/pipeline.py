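"""End-to-end orchestration of the slide-classification pipeline.

Each stage is idempotent and reads/writes plain on-disk artifacts under
the run's output directory (slides, masks, patch tables, feature bags,
checkpoints, predictions, metric reports, heatmaps), mirroring real WSI
workflows where expensive stages are cached once.  The :func:`demo`
function chains every stage on a small synthetic cohort.
"""

from __future__ import annotations

import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .evaluation import (
    CVResult,
    folds_to_frame,
    run_cross_validation,
    run_holdout,
)
from .features import FeatureBag, get_extractor, load_bag, save_bag, extract_features
from .heatmap import heatmap_for_slide
from .model import TrainConfig, load_checkpoint, save_checkpoint
from .segmentation import TissueMask, extract_patch_grid, segment_tissue, PatchSet
from .slide import SlideImage, read_manifest, write_manifest
from .synthetic import SyntheticSlideSpec, generate_cohort

log = logging.getLogger("slidemil")


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.2fs", stage, time.perf_counter() - self.t0)

    return _Timer()


def _slide_spec(cfg: RunConfig) -> SyntheticSlideSpec:
    return SyntheticSlideSpec(
        canvas_size_px=(cfg.canvas_px, cfg.canvas_px),
        mpp=cfg.mpp,
        n_tissue_blobs=cfg.n_tissue_blobs,
    )


def synthesize_cohorts(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write a training cohort (multi-slide cases) and a hold-out cohort
    (one slide per case, as in real hold-out sets) under the run dir."""
    out = Path(cfg.out_dir)
    focus_range = (cfg.focus_diameter_min_um, cfg.focus_diameter_max_um)
    with _timed("synth"):
        train_manifest = generate_cohort(
            cfg.n_benign_train,
            cfg.n_malignant_train,
            cfg.cohort,
            seed=cfg.seed,
            out_dir=out / "slides" / "train",
            slides_per_case=(1, 2),
            slide_spec=_slide_spec(cfg),
            focus_diameter_range_um=focus_range,
        )
        holdout_manifest = generate_cohort(
            cfg.n_benign_holdout,
            cfg.n_malignant_holdout,
            f"{cfg.cohort}-holdout",
            seed=cfg.seed + 1,
            out_dir=out / "slides" / "holdout",
            slides_per_case=(1, 1),
            slide_spec=_slide_spec(cfg),
            focus_diameter_range_um=focus_range,
        )
    write_manifest(train_manifest, out / "manifest_train.csv")
    write_manifest(holdout_manifest, out / "manifest_holdout.csv")
    return train_manifest, holdout_manifest


def load_slide(row: pd.Series) -> SlideImage:
    return SlideImage.from_file(
        row["path"], mpp=float(row["mpp"]), slide_id=row["slide_id"],
        label=row["label"],
    )


def segment_and_patch(
    manifest: pd.DataFrame, cfg: RunConfig, subdir: str
) -> dict[str, PatchSet]:
    """Segment every slide, persist masks, and extract the patch grid."""
    out = Path(cfg.out_dir)
    patchsets: dict[str, PatchSet] = {}
    with _timed(f"segment+patch[{subdir}]"):
        for _, row in manifest.iterrows():
            slide = load_slide(row)
            mask = segment_tissue(
                slide,
                sat_threshold=cfg.sat_threshold,
                min_region_area_px=cfg.min_region_area_px,
                closing_radius_px=cfg.closing_radius_px,
                downsample=cfg.mask_downsample,
            )
            mask.save(out / "masks" / subdir / f"{slide.slide_id}.png")
            ps = extract_patch_grid(
                slide,
                mask,
                patch_size_level0=cfg.patch_size_level0,
                out_size=cfg.out_size,
                min_tissue_frac=cfg.min_tissue_frac,
            )
            ps.save(out / "patches" / subdir / f"{slide.slide_id}.csv")
            patchsets[slide.slide_id] = ps
    return patchsets


def compute_features(
    manifest: pd.DataFrame,
    patchsets: dict[str, PatchSet],
    cfg: RunConfig,
    subdir: str,
) -> dict[str, FeatureBag]:
    """Extract (or reload cached) feature bags for every slide."""
    out = Path(cfg.out_dir) / "features" / subdir
    extractor = get_extractor(cfg.extractor_id)
    bags: dict[str, FeatureBag] = {}
    with _timed(f"features[{subdir}]"):
        for _, row in manifest.iterrows():
            sid = row["slide_id"]
            path = out / f"{sid}.h5"
            if path.exists():
                bags[sid] = load_bag(
                    path, expected_extractor=extractor.extractor_id
                )
                continue
            bag = extract_features(load_slide(row), patchsets[sid], extractor)
            save_bag(bag, path)
            bags[sid] = bag
    return bags


def train_config_from(cfg: RunConfig) -> TrainConfig:
    return TrainConfig(
        learning_rate=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
        dropout=cfg.dropout,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        min_epochs=cfg.min_epochs,
        seed=cfg.seed + 500,
    )


def train_cv(
    manifest: pd.DataFrame, bags: dict[str, FeatureBag], cfg: RunConfig
) -> CVResult:
    """Cross-validate, then persist fold models, predictions and metrics."""
    out = Path(cfg.out_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    (out / "results").mkdir(parents=True, exist_ok=True)
    with _timed("train-cv"):
        result = run_cross_validation(
            manifest,
            bags,
            train_config=train_config_from(cfg),
            k=cfg.k_folds,
            seed=cfg.seed + 2,
            n_bootstrap=cfg.n_bootstrap,
        )
    for i, model in enumerate(result.models):
        save_checkpoint(
            model,
            out / "models" / f"fold{i}.npz",
            extractor_id=cfg.extractor_id,
            train_config=train_config_from(cfg),
        )
    folds_to_frame(result.splits).to_csv(out / "models" / "folds.csv", index=False)
    result.predictions.to_csv(out / "results" / "cv_predictions.csv", index=False)
    result.report.to_json(out / "results" / "cv_metrics.json")
    return result

def holdout_eval(
    cv_result: CVResult,
    holdout_manifest: pd.DataFrame,
    bags: dict[str, FeatureBag],
    cfg: RunConfig,
):
    out = Path(cfg.out_dir)
    (out / "results").mkdir(parents=True, exist_ok=True)
    with _timed("holdout"):
        preds, report = run_holdout(
            cv_result.models,
            holdout_manifest,
            bags,
            cv_result.train_case_ids,
            n_bootstrap=cfg.n_bootstrap,
            seed=cfg.seed + 3,
        )
    preds.to_csv(out / "results" / "holdout_predictions.csv", index=False)
    report.to_json(out / "results" / "holdout_metrics.json")
    return preds, report


def make_heatmaps(
    models,
    manifest: pd.DataFrame,
    cfg: RunConfig,
    subdir: str = "holdout",
    n_slides: int | None = None,
) -> list[Path]:
    """Render attention overlays for the first positive slides of a set."""
    out = Path(cfg.out_dir)
    positives = manifest[manifest["label"] == "metastatic"]
    n = n_slides if n_slides is not None else cfg.n_heatmaps
    paths = []
    with _timed("heatmap"):
        for _, row in positives.head(n).iterrows():
            slide = load_slide(row)
            mask = TissueMask.from_file(
                out / "masks" / subdir / f"{slide.slide_id}.png",
                cfg.mask_downsample,
            )
            overlay = heatmap_for_slide(
                models,
                slide,
                mask,
                patch_size_level0=cfg.patch_size_level0,
                out_size=cfg.out_size,
                min_tissue_frac=cfg.min_tissue_frac,
                extractor=get_extractor(cfg.extractor_id),
                downsample=cfg.mask_downsample,
                alpha=cfg.heatmap_alpha,
                cmap=cfg.heatmap_cmap,
            )
            paths.append(overlay.save(out / "heatmaps" / f"{slide.slide_id}.png"))
    return paths


def demo(cfg: RunConfig) -> dict:
    """Run the full synthetic chain: cohort synthesis -> segmentation ->
    patching -> toy features -> 5-fold CV -> ensembled hold-out ->
    heatmaps.  Returns a summary dict of key artifact paths and metrics."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.save(out / "config.yaml")
    train_manifest, holdout_manifest = synthesize_cohorts(cfg)
    train_ps = segment_and_patch(train_manifest, cfg, "train")
    holdout_ps = segment_and_patch(holdout_manifest, cfg, "holdout")
    train_bags = compute_features(train_manifest, train_ps, cfg, "train")
    holdout_bags = compute_features(holdout_manifest, holdout_ps, cfg, "holdout")
    cv_result = train_cv(train_manifest, train_bags, cfg)
    preds, report = holdout_eval(cv_result, holdout_manifest, holdout_bags, cfg)
    heatmap_paths = make_heatmaps(cv_result.models, holdout_manifest, cfg)
    return {
        "out_dir": str(out),
        "cv_metrics": str(out / "results" / "cv_metrics.json"),
        "holdout_metrics": str(out / "results" / "holdout_metrics.json"),
        "holdout_predictions": str(out / "results" / "holdout_predictions.csv"),
        "heatmaps": [str(p) for p in heatmap_paths],
        "cv_auroc": cv_result.report.auroc.point,
        "holdout_auroc": report.auroc.point,
        "holdout_accuracy": report.accuracy.point,
    }
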
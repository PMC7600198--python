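"""End-to-end orchestration: phantom cohort → features → scan-level CV →
post-processing → severity, with deterministic seeding throughout.

This is the programmatic surface the command-line interface and the
reproduction script drive; each stage below simply composes the module
operations in pipeline order.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import classify, deepfeat, postprocess, severity
from .config import PipelineConfig
from .ct_io import CTVolume
from .features import assemble_feature_table
from .phantom import PhantomCase
from .preprocess import HeadMasks, compute_head_masks
from .superpixel import (
    SuperpixelMap,
    generate_superpixels,
    label_superpixels,
    rescale_brain_window,
)

__all__ = ["ProcessedScan", "CVResult", "process_scan", "run_cross_validation", "segment_scan"]

logger = logging.getLogger(__name__)


@dataclass
class ProcessedScan:
    """A scan after pre-processing, superpixelization and feature extraction."""

    volume: CTVolume
    masks: HeadMasks
    spmap: SuperpixelMap
    table: pd.DataFrame
    ground_truth: np.ndarray | None = None


@dataclass
class CVResult:
    """Per-scan cross-validated segmentations and the summary report."""

    report: pd.DataFrame
    fold_aucs: dict[int, float]
    fold_aucs_balanced: dict[int, float]
    segmentations: dict[str, postprocess.SegmentationResult]
    fold_plan: classify.FoldPlan
    config: PipelineConfig


def process_scan(
    volume: CTVolume,
    ground_truth: np.ndarray | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> ProcessedScan:
    """Pre-process one scan and build its per-superpixel feature table."""
    t0 = time.perf_counter()
    masks = compute_head_masks(volume, config.bone_threshold_hu, config.roi_depth_mm)
    spmap = generate_superpixels(
        volume, masks.roi_band, config.slic_target_size_px, config.slic_compactness
    )
    labels = None
    if ground_truth is not None:
        labels = label_superpixels(spmap, ground_truth, config.positive_fraction)
    table = assemble_feature_table(volume, masks, spmap, labels=labels)
    logger.info(
        "processed %s: %d superpixels in %.1fs",
        volume.scan_id,
        spmap.n_superpixels,
        time.perf_counter() - t0,
    )
    return ProcessedScan(volume, masks, spmap, table, ground_truth)


def _unet_training_slices(scans: dict[str, ProcessedScan], scan_ids: list[str]):
    out = []
    for sid in scan_ids:
        ps = scans[sid]
        for k in np.unique(ps.spmap.slice_index):
            img = rescale_brain_window(ps.volume.voxels[:, :, int(k)])
            img = np.where(ps.masks.intracranial[:, :, int(k)], img, 0.0)
            gt = (
                ps.ground_truth[:, :, int(k)]
                if ps.ground_truth is not None
                else np.zeros(img.shape, dtype=bool)
            )
            out.append((sid, img, gt))
    return out


def run_cross_validation(
    cases: list[PhantomCase],
    config: PipelineConfig = PipelineConfig(),
) -> CVResult:
    """Scan-level cross-validation over a phantom cohort.

    For each fold: optionally train the fold's U-net and attach deep
    features, 1:1-undersample the training superpixels, fit the forest,
    predict held-out probability maps, post-process, and score against the
    ground truth. No scan ever contributes to both sides of a fold.
    """
    from .phantom import cohort_manifest

    manifest = cohort_manifest([c for c in cases])
    plan = classify.make_folds(manifest, config.n_folds, seed=config.seed)
    scans = {
        c.volume.scan_id: process_scan(c.volume, c.ground_truth, config) for c in cases
    }
    gt_by_scan = {c.volume.scan_id: c.ground_truth for c in cases}
    true_vol = {
        c.volume.scan_id: severity.measure_volume(c.ground_truth, c.volume.spacing)
        for c in cases
    }

    feature_columns = list(classify.HANDCRAFTED_COLUMNS)
    if config.use_deep_features:
        feature_columns += deepfeat.DEEP_COLUMNS
        spec = deepfeat.UnetSpec(
            epochs=config.unet_epochs, patch_size=config.unet_patch_size, seed=config.seed
        )
        for fold in range(plan.n_folds):
            train_ids = plan.train_scans(fold)
            test_ids = plan.test_scans(fold)
            slices = _unet_training_slices(scans, train_ids)
            artifact = deepfeat.train_unet(
                slices, fold, spec, held_out_scan_ids=set(test_ids)
            )
            for sid in test_ids:
                ps = scans[sid]
                deep = deepfeat.extract_deep_features(
                    artifact, ps.volume, ps.masks, ps.spmap, scan_fold=fold
                )
                ps.table = pd.concat(
                    [ps.table.reset_index(drop=True), deep.reset_index(drop=True)], axis=1
                )

    rows = []
    segmentations: dict[str, postprocess.SegmentationResult] = {}
    fold_aucs: dict[int, float] = {}
    fold_aucs_bal: dict[int, float] = {}
    for fold in range(plan.n_folds):
        train_ids = plan.train_scans(fold)
        test_ids = plan.test_scans(fold)
        assert not set(train_ids) & set(test_ids)
        train_table = pd.concat([scans[s].table for s in train_ids], ignore_index=True)
        balanced = classify.undersample(train_table, seed=config.seed + fold)
        artifact = classify.train_forest(
            balanced,
            feature_columns=feature_columns,
            n_trees=config.n_trees,
            seed=config.seed + fold,
            fold_id=fold,
        )

        test_table = pd.concat([scans[s].table for s in test_ids], ignore_index=True)
        y = test_table["label"].to_numpy(dtype=bool)
        p = artifact.model.predict_proba(
            test_table[feature_columns].to_numpy(dtype=float)
        )[:, list(artifact.model.classes_).index(True)]
        if y.any() and not y.all():
            fold_aucs[fold] = float(roc_auc_score(y, p))
            bal = classify.undersample(
                test_table.assign(_p=p), seed=config.seed + 1000 + fold
            )
            fold_aucs_bal[fold] = float(
                roc_auc_score(bal["label"].to_numpy(dtype=bool), bal["_p"].to_numpy())
            )

        for sid in test_ids:
            ps = scans[sid]
            prob = classify.predict_probability(artifact, ps.table, ps.spmap)
            seg = postprocess.postprocess_mask(
                prob,
                ps.masks.roi_band,
                ps.masks.skull,
                ps.volume.spacing,
                tau=config.prob_threshold,
                min_area_px=config.min_area_px,
                fill_radius_px=config.fill_radius_px,
                max_hole_px=config.fill_max_hole_px,
                min_slices=config.min_slices,
                continuity_drift_mm=config.continuity_drift_mm,
                sigma_mm=(config.smooth_sigma_mm,) * 3,
                tau_s=config.smooth_threshold,
            )
            seg.provenance["config"] = config.to_dict()
            segmentations[sid] = seg

            gt = gt_by_scan[sid]
            before = severity.overlap_metrics(seg.initial_mask, gt, ps.masks.roi_band)
            after = severity.overlap_metrics(seg.final_mask, gt, ps.masks.roi_band)
            vol_cc = severity.measure_volume(seg.final_mask, ps.volume.spacing)
            rows.append(
                {
                    "scan_id": sid,
                    "fold": fold,
                    "true_volume_cc": true_vol[sid],
                    "computed_volume_cc": vol_cc,
                    "severity": severity.classify_severity(
                        vol_cc, config.severity_threshold_cc
                    ).severity,
                    "dice_before": before.dice,
                    "dice": after.dice,
                    "recall": after.recall,
                    "precision": after.precision,
                    "specificity": after.specificity,
                }
            )

    report = pd.DataFrame(rows).sort_values("scan_id").reset_index(drop=True)
    return CVResult(
        report=report,
        fold_aucs=fold_aucs,
        fold_aucs_balanced=fold_aucs_bal,
        segmentations=segmentations,
        fold_plan=plan,
        config=config,
    )


def segment_scan(
    volume: CTVolume,
    artifact: classify.ForestArtifact,
    config: PipelineConfig = PipelineConfig(),
):
    """Segment a single scan with a trained forest and report severity."""
    ps = process_scan(volume, ground_truth=None, config=config)
    prob = classify.predict_probability(artifact, ps.table, ps.spmap)
    seg = postprocess.postprocess_mask(
        prob,
        ps.masks.roi_band,
        ps.masks.skull,
        volume.spacing,
        tau=config.prob_threshold,
        min_area_px=config.min_area_px,
        fill_radius_px=config.fill_radius_px,
        max_hole_px=config.fill_max_hole_px,
        min_slices=config.min_slices,
        continuity_drift_mm=config.continuity_drift_mm,
        sigma_mm=(config.smooth_sigma_mm,) * 3,
        tau_s=config.smooth_threshold,
    )
    seg.provenance["config"] = config.to_dict()
    vol_cc = severity.measure_volume(seg.final_mask, volume.spacing)
    report = severity.classify_severity(vol_cc, config.severity_threshold_cc)
    return seg, report
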
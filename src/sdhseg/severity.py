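"""Lesion volume, severity dichotomy, and all evaluation statistics.

Severity follows the volumetric dichotomy used for subdural hematoma
triage: below 25 cc is non-hematoma/mild, at or above 25 cc is
moderate/severe. Overlap metrics are the standard Dice / recall /
precision / specificity set, with the specificity complement taken within
a stated universe (the ROI band) rather than the whole volume, since only
voxels the classifier could have labeled are meaningful negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SeverityReport",
    "OverlapMetrics",
    "measure_volume",
    "classify_severity",
    "overlap_metrics",
    "severity_confusion",
    "volume_agreement",
    "interrater_compare",
    "SEVERITY_THRESHOLD_CC",
]

SEVERITY_THRESHOLD_CC = 25.0
MILD = "non-hematoma/mild"
SEVERE = "moderate/severe"


@dataclass(frozen=True)
class SeverityReport:
    volume_cc: float
    severity: str
    threshold_cc: float = SEVERITY_THRESHOLD_CC


@dataclass(frozen=True)
class OverlapMetrics:
    """Dice / recall / precision / specificity; metrics undefined for empty
    reference or empty segmentation are reported as None."""

    dice: Optional[float]
    recall: Optional[float]
    precision: Optional[float]
    specificity: float


def measure_volume(mask: np.ndarray, spacing: Sequence[float]) -> float:
    """True-voxel count × voxel volume, in cc."""
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    return float(np.count_nonzero(mask)) * float(np.prod(spacing)) / 1000.0


def classify_severity(
    volume_cc: float, threshold_cc: float = SEVERITY_THRESHOLD_CC
) -> SeverityReport:
    """< threshold → non-hematoma/mild; >= threshold → moderate/severe."""
    if volume_cc < 0:
        raise ValueError("volume must be non-negative")
    label = SEVERE if volume_cc >= threshold_cc else MILD
    return SeverityReport(volume_cc=volume_cc, severity=label, threshold_cc=threshold_cc)


def overlap_metrics(S: np.ndarray, GT: np.ndarray, universe: np.ndarray) -> OverlapMetrics:
    """Set-overlap metrics of a segmentation S against a reference GT.

    Dice = 2|S∩GT| / (|S|+|GT|); recall = |S∩GT|/|GT|; precision =
    |S∩GT|/|S|; specificity = |S̄∩GT̄|/|GT̄| with complements taken within
    *universe*. Dice and recall are None when GT is empty, precision None
    when S is empty.
    """
    if S.shape != GT.shape or S.shape != universe.shape:
        raise ValueError("masks must share geometry")
    S = S.astype(bool) & universe
    GT = GT.astype(bool) & universe
    inter = int(np.count_nonzero(S & GT))
    n_s = int(np.count_nonzero(S))
    n_gt = int(np.count_nonzero(GT))
    n_u = int(np.count_nonzero(universe))
    tn = int(np.count_nonzero(universe & ~S & ~GT))
    dice = 2 * inter / (n_s + n_gt) if n_gt > 0 else None
    recall = inter / n_gt if n_gt > 0 else None
    precision = inter / n_s if n_s > 0 else None
    neg = n_u - n_gt
    specificity = tn / neg if neg > 0 else 1.0
    return OverlapMetrics(dice=dice, recall=recall, precision=precision, specificity=specificity)


def severity_confusion(
    reference_volumes_cc: Sequence[float],
    computed_volumes_cc: Sequence[float],
    threshold_cc: float = SEVERITY_THRESHOLD_CC,
):
    """2×2 severity confusion matrix and the severe-class statistics.

    Returns ``(counts, stats)``: *counts* is rows=reference, cols=computed
    over {<threshold, >=threshold}; *stats* holds recall, specificity,
    precision, and F1 for the >=threshold class, as percentages.
    """
    ref = np.asarray(reference_volumes_cc, dtype=float)
    com = np.asarray(computed_volumes_cc, dtype=float)
    if ref.shape != com.shape:
        raise ValueError("paired volume lists differ in length")
    ref_sev = ref >= threshold_cc
    com_sev = com >= threshold_cc
    counts = np.array(
        [
            [int(np.sum(~ref_sev & ~com_sev)), int(np.sum(~ref_sev & com_sev))],
            [int(np.sum(ref_sev & ~com_sev)), int(np.sum(ref_sev & com_sev))],
        ]
    )
    return counts, confusion_stats(counts)


def confusion_stats(counts: np.ndarray) -> dict[str, float]:
    """Recall / specificity / precision / F1 (percent) for the severe class
    of a 2×2 matrix with rows=reference, cols=computed, class order
    (<threshold, >=threshold)."""
    counts = np.asarray(counts, dtype=float)
    tn, fp = counts[0]
    fn, tp = counts[1]
    recall = tp / (tp + fn) if tp + fn > 0 else math.nan
    specificity = tn / (tn + fp) if tn + fp > 0 else math.nan
    precision = tp / (tp + fp) if tp + fp > 0 else math.nan
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else math.nan
    )
    return {
        "recall_pct": round(100 * recall, 2),
        "specificity_pct": round(100 * specificity, 2),
        "precision_pct": round(100 * precision, 2),
        "f1_pct": round(100 * f1, 2),
    }


def volume_agreement(
    reference_volumes_cc: Sequence[float],
    computed_volumes_cc: Sequence[float],
) -> dict[str, float]:
    """Least-squares regression of computed on reference volume plus
    Bland-Altman agreement statistics.

    Returns slope/intercept with the slope's standard error, the
    through-origin slope, Bland-Altman bias = mean(computed − reference)
    and 95% limits of agreement bias ± 1.96·sd(differences).
    """
    ref = np.asarray(reference_volumes_cc, dtype=float)
    com = np.asarray(computed_volumes_cc, dtype=float)
    if ref.shape != com.shape:
        raise ValueError("paired volume lists differ in length")
    n = len(ref)
    if n < 3:
        raise ValueError("need at least 3 volume pairs")
    sxx = float(np.sum((ref - ref.mean()) ** 2))
    if sxx == 0:
        raise ValueError("zero variance in reference volumes")
    slope = float(np.sum((ref - ref.mean()) * (com - com.mean())) / sxx)
    intercept = float(com.mean() - slope * ref.mean())
    resid = com - (slope * ref + intercept)
    dof = max(n - 2, 1)
    slope_se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    slope_origin = float(np.sum(ref * com) / np.sum(ref**2))
    diff = com - ref
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if n > 1 else 0.0
    return {
        "slope": slope,
        "slope_se": slope_se,
        "intercept": intercept,
        "slope_through_origin": slope_origin,
        "bias_cc": bias,
        "loa_low_cc": bias - 1.96 * sd,
        "loa_high_cc": bias + 1.96 * sd,
    }


def interrater_compare(
    masks_a: dict[str, np.ndarray],
    masks_b: dict[str, np.ndarray],
    reference_volumes_cc: dict[str, float],
    universes: dict[str, np.ndarray],
    threshold_cc: float = SEVERITY_THRESHOLD_CC,
):
    """Per-case Dice between two annotation sets and stratum means.

    Cases are matched by id across the two sets; strata are keyed by the
    reference volume at *threshold_cc*. Returns (per_case, stratum_means).
    """
    if set(masks_a) != set(masks_b):
        raise ValueError("annotation sets cover different case ids")
    per_case: dict[str, Optional[float]] = {}
    strata: dict[str, list[float]] = {"mild": [], "severe": [], "all": []}
    for cid in sorted(masks_a):
        m = overlap_metrics(masks_a[cid], masks_b[cid], universes[cid])
        per_case[cid] = m.dice
        if m.dice is None:
            continue
        strata["all"].append(m.dice)
        key = "severe" if reference_volumes_cc[cid] >= threshold_cc else "mild"
        strata[key].append(m.dice)
    means = {k: (float(np.mean(v)) if v else math.nan) for k, v in strata.items()}
    return per_case, means
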
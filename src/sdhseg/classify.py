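"""Random-forest superpixel classification under scan-level cross-validation.

Folds split by scan, never by superpixel, and are stratified on lesion type
and volume stratum so each fold sees a roughly balanced distribution of
hematoma classes. Training rebalances the (heavily negative-skewed) sample
by 1:1 undersampling: every positive superpixel is kept and an equal number
of negatives is drawn without replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import HANDCRAFTED_COLUMNS
from .superpixel import SuperpixelMap

__all__ = [
    "FoldPlan",
    "ForestArtifact",
    "make_folds",
    "undersample",
    "train_forest",
    "predict_probability",
    "SEVERITY_STRATA_CC",
]

#: volume strata used as the fold-stratification key (cc cut points)
SEVERITY_STRATA_CC = (25.0, 50.0, 100.0, 200.0)

DEFAULT_N_TREES = 200


@dataclass(frozen=True)
class FoldPlan:
    """scan_id → fold_id assignment, split by scan."""

    assignment: dict[str, int]
    n_folds: int

    def fold_of(self, scan_id: str) -> int:
        return self.assignment[scan_id]

    def test_scans(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)

    def train_scans(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f != fold)


@dataclass
class ForestArtifact:
    """A trained forest plus the schema and provenance needed to apply it."""

    model: RandomForestClassifier
    feature_columns: list[str]
    fold_id: int
    seed: int
    meta: dict = field(default_factory=dict)


def _volume_stratum(volume_cc: float) -> int:
    for i, cut in enumerate(SEVERITY_STRATA_CC):
        if volume_cc < cut:
            return i
    return len(SEVERITY_STRATA_CC)


def make_folds(manifest: pd.DataFrame, n_folds: int, seed: int = 0) -> FoldPlan:
    """Stratified scan-level fold assignment.

    *manifest* needs columns ``scan_id``, ``lesion_type``, ``true_volume_cc``.
    Within each (lesion type, volume stratum) stratum, scans are shuffled
    under *seed* and dealt round-robin to folds, the fold offset rotating
    across strata so no fold systematically collects the first scans.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(manifest) < n_folds:
        raise ValueError(f"only {len(manifest)} scans for {n_folds} folds")
    rng = np.random.default_rng(seed)
    df = manifest.copy()
    df["_stratum"] = [
        (t, _volume_stratum(v)) for t, v in zip(df["lesion_type"], df["true_volume_cc"])
    ]
    assignment: dict[str, int] = {}
    offset = 0
    for _, group in sorted(df.groupby("_stratum"), key=lambda kv: str(kv[0])):
        scan_ids = sorted(group["scan_id"])
        rng.shuffle(scan_ids)
        for j, sid in enumerate(scan_ids):
            assignment[str(sid)] = (offset + j) % n_folds
        offset += len(scan_ids)
    return FoldPlan(assignment=assignment, n_folds=n_folds)


def undersample(rows: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Keep all positives; draw an equal number of negatives without
    replacement. Hard error when the subset holds no positive row."""
    if "label" not in rows.columns:
        raise ValueError("rows must carry a 'label' column")
    pos = rows[rows["label"].astype(bool)]
    neg = rows[~rows["label"].astype(bool)]
    if len(pos) == 0:
        raise ValueError(
            "no positive superpixels in the training subset; skip this fold "
            "or evaluate in hand-crafted-only mode on another split"
        )
    if len(neg) <= len(pos):
        warnings.warn("negatives do not outnumber positives; nothing to drop", stacklevel=2)
        return rows
    rng = np.random.default_rng(seed)
    take = rng.choice(len(neg), size=len(pos), replace=False)
    take.sort()
    return pd.concat([pos, neg.iloc[take]]).sort_index()


def train_forest(
    balanced: pd.DataFrame,
    feature_columns: list[str] | None = None,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    fold_id: int = -1,
) -> ForestArtifact:
    """Fit the random forest (200 trees, sqrt features per split, unlimited
    depth by default) on a balanced training table."""
    if feature_columns is None:
        feature_columns = list(HANDCRAFTED_COLUMNS)
    missing = [c for c in feature_columns if c not in balanced.columns]
    if missing:
        raise ValueError(f"training table is missing feature columns {missing}")
    X = balanced[feature_columns].to_numpy(dtype=float)
    y = balanced["label"].to_numpy(dtype=bool)
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        max_depth=None,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return ForestArtifact(
        model=model,
        feature_columns=list(feature_columns),
        fold_id=fold_id,
        seed=seed,
        meta={"n_train": len(balanced), "n_pos": int(y.sum())},
    )


def predict_probability(
    artifact: ForestArtifact,
    rows: pd.DataFrame,
    spmap: SuperpixelMap,
) -> np.ndarray:
    """Per-voxel hematoma probability: every ROI voxel receives its
    superpixel's forest probability; non-ROI voxels are 0."""
    missing = [c for c in artifact.feature_columns if c not in rows.columns]
    if missing:
        raise ValueError(f"feature table is missing columns {missing}")
    present = set(rows["superpixel_id"].astype(int))
    wanted = set(int(i) for i in spmap.ids())
    if not wanted <= present:
        lacking = sorted(wanted - present)[:5]
        raise ValueError(f"feature rows missing for superpixels {lacking}")
    ordered = rows.set_index("superpixel_id").loc[sorted(wanted)]
    X = ordered[artifact.feature_columns].to_numpy(dtype=float)
    classes = list(artifact.model.classes_)
    proba = artifact.model.predict_proba(X)
    p_pos = proba[:, classes.index(True)] if True in classes else np.zeros(len(X))
    lut = np.zeros(spmap.n_superpixels + 1)
    lut[1:] = p_pos
    return lut[spmap.label_image]
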
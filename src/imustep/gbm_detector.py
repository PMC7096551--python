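"""Supervised per-timepoint step classification with gradient-boosted trees.

Every sample of a recording becomes one row of lag/lead difference
features (see :mod:`imustep.signal_prep`); samples inside an annotated
step are labelled 1, all others 0.  A gradient-boosted tree ensemble
(50 trees, depth 5 by default) predicts the per-sample step probability,
the probability is thresholded into a binary mask, and run-length
post-processing turns the mask into step intervals: only runs of at
least ``min_run`` consecutive step predictions start a step, and steps
separated by at most ``merge_gap`` samples are merged.

The feature channel list is configurable.  The default uses the 16
non-magnetometer channels plus four derived series (acceleration, free
acceleration and angular-velocity magnitudes, and the yaw rate), i.e.
20 parameters x 12 offsets = 240 predictors.  The identity of the last
three derived series is a package choice — only the x12 structure and
the total count are fixed by the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imu_io import AnnotationSet, ImuRecording, StepInterval
from .cpd_sst import mask_to_intervals
from .signal_prep import LagLeadSpec, lag_lead_features

__all__ = [
    "GbmConfig",
    "FeatureMatrix",
    "StepClassifier",
    "DEFAULT_GBM_CHANNELS",
    "label_timepoints",
    "split_profiles",
    "build_feature_matrix",
    "train",
    "predict_mask",
    "mask_to_steps",
    "detect_gbm",
]

#: 20 feature channels: 16 raw non-magnetometer channels + 4 derived.
DEFAULT_GBM_CHANNELS: tuple[str, ...] = (
    "Acc_X", "Acc_Y", "Acc_Z",
    "FreeAcc_X", "FreeAcc_Y", "FreeAcc_Z",
    "Gyr_X", "Gyr_Y", "Gyr_Z",
    "Roll", "Pitch", "Yaw",
    "Quat_W", "Quat_X", "Quat_Y", "Quat_Z",
    "Acc_magnitude", "FreeAcc_magnitude", "Gyr_magnitude", "Yaw_rate",
)


@dataclass(frozen=True)
class GbmConfig:
    """Classifier and post-processing configuration."""

    n_trees: int = 50
    max_depth: int = 5
    max_leaves: int = 32
    learning_rate: float = 0.1
    extra_params: dict = field(default_factory=dict)
    prob_threshold: float = 0.5
    min_run: int = 10
    merge_gap: int = 10
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    channels: tuple[str, ...] = DEFAULT_GBM_CHANNELS
    lag_lead: LagLeadSpec = field(default_factory=LagLeadSpec)

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if not (0 <= self.prob_threshold <= 1):
            raise ValueError("prob_threshold must be in [0, 1]")


@dataclass
class FeatureMatrix:
    """Per-timepoint feature rows with optional labels and profile groups."""

    X: pd.DataFrame
    label: np.ndarray | None = None
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.label is not None and len(self.label) != len(self.X):
            raise ValueError("label length does not match feature rows")
        if self.groups is not None and len(self.groups) != len(self.X):
            raise ValueError("groups length does not match feature rows")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, keys) -> "FeatureMatrix":
        if self.groups is None:
            raise ValueError("feature matrix has no group information")
        mask = np.isin(self.groups, list(keys))
        return FeatureMatrix(
            X=self.X.loc[mask].reset_index(drop=True),
            label=None if self.label is None else self.label[mask],
            groups=self.groups[mask],
        )


def label_timepoints(rec: ImuRecording, annotations: AnnotationSet) -> np.ndarray:
    """1 for samples inside an annotated step (half-open), else 0."""
    labels = np.zeros(rec.n_samples, dtype=np.int8)
    for iv in annotations.intervals:
        if iv.end > rec.n_samples:
            raise ValueError(
                f"interval [{iv.start},{iv.end}) exceeds recording length "
                f"{rec.n_samples}"
            )
        labels[iv.start : iv.end] = 1
    return labels


def split_profiles(profile_ids, fractions, seed: int):
    """Deterministic profile-level train/validation/test split.

    Profiles are shuffled with ``seed`` and partitioned so set sizes are
    proportional to ``fractions`` by profile count (largest-remainder
    rounding); a profile is never split across sets.
    """
    ids = sorted(set(map(str, profile_ids)))
    if len(ids) < 3:
        raise ValueError(f"need at least 3 profiles, got {len(ids)}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(ids))
    n = len(ids)
    raw = [f * n for f in fractions]
    counts = [int(np.floor(v)) for v in raw]
    remainders = [v - c for v, c in zip(raw, counts)]
    while sum(counts) < n:
        i = int(np.argmax(remainders))
        counts[i] += 1
        remainders[i] = -1
    # every set gets at least one profile
    for i in range(3):
        if counts[i] == 0:
            j = int(np.argmax(counts))
            counts[j] -= 1
            counts[i] += 1
    train = set(order[: counts[0]])
    valid = set(order[counts[0] : counts[0] + counts[1]])
    test = set(order[counts[0] + counts[1] :])
    return train, valid, test


def build_feature_matrix(
    items,
    cfg: GbmConfig = GbmConfig(),
) -> FeatureMatrix:
    """Stack lag/lead features over recordings.

    ``items`` is an iterable of ``(recording, annotations-or-None)``
    pairs; labels are attached when annotations are supplied for every
    recording.
    """
    frames, labels, groups = [], [], []
    have_labels = True
    for rec, ann in items:
        X = lag_lead_features(rec, cfg.lag_lead, cfg.channels)
        frames.append(X)
        key = f"{rec.profile_id}_leg{rec.leg_id}"
        groups.append(np.full(len(X), key, dtype=object))
        if ann is None:
            have_labels = False
        else:
            labels.append(label_timepoints(rec, ann))
    X_all = pd.concat(frames, ignore_index=True)
    return FeatureMatrix(
        X=X_all,
        label=np.concatenate(labels) if have_labels and labels else None,
        groups=np.concatenate(groups),
    )


@dataclass
class StepClassifier:
    """Fitted per-timepoint classifier plus the schema it was trained on."""

    model: object
    feature_names: list[str]
    config: GbmConfig
    seed: int
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, features: FeatureMatrix) -> np.ndarray:
        if list(features.X.columns) != self.feature_names:
            raise ValueError(
                "feature schema mismatch: matrix columns differ from the "
                "columns the classifier was trained on"
            )
        return self.model.predict_proba(features.X)[:, 1]


def train(
    features: FeatureMatrix,
    cfg: GbmConfig = GbmConfig(),
    seed: int = 0,
    validation: FeatureMatrix | None = None,
) -> StepClassifier:
    """Fit the gradient-boosted ensemble on labelled feature rows.

    NaN feature values (undefined lag/lead positions at recording edges)
    are handled natively by the trees.  When a validation matrix is
    given, its accuracy and class balance are recorded in the returned
    classifier's metadata.
    """
    import lightgbm as lgb

    if features.label is None:
        raise ValueError("training requires labelled features")
    y = np.asarray(features.label)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    params = dict(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        num_leaves=cfg.max_leaves,
        learning_rate=cfg.learning_rate,
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )
    params.update(cfg.extra_params)
    model = lgb.LGBMClassifier(**params)
    model.fit(features.X, y)

    clf = StepClassifier(
        model=model,
        feature_names=list(features.X.columns),
        config=cfg,
        seed=seed,
    )
    clf.metadata["n_train_rows"] = int(len(y))
    clf.metadata["train_positive_fraction"] = float(y.mean())
    if validation is not None and validation.label is not None:
        p = clf.predict_proba(validation)
        pred = p >= cfg.prob_threshold
        clf.metadata["validation_accuracy"] = float(
            np.mean(pred == validation.label.astype(bool))
        )
        clf.metadata["n_validation_rows"] = int(len(p))
    return clf


def predict_mask(
    clf: StepClassifier,
    features: FeatureMatrix,
    prob_threshold: float | None = None,
) -> np.ndarray:
    """Threshold predicted step probabilities into a binary mask."""
    thr = clf.config.prob_threshold if prob_threshold is None else prob_threshold
    return clf.predict_proba(features) >= thr


def mask_to_steps(mask, min_run: int = 10, merge_gap: int = 10) -> list[StepInterval]:
    """Run-length post-processing of the per-timepoint mask.

    Maximal runs of at least ``min_run`` consecutive step predictions
    become candidate steps; candidates whose end-to-start gap is at most
    ``merge_gap`` samples are merged (repeated until stable).
    """
    candidates = [
        iv for iv in mask_to_intervals(mask) if iv.n_samples >= min_run
    ]
    changed = True
    while changed:
        changed = False
        merged: list[StepInterval] = []
        for iv in candidates:
            if merged and iv.start - merged[-1].end <= merge_gap:
                merged[-1] = StepInterval(merged[-1].start, iv.end)
                changed = True
            else:
                merged.append(iv)
        candidates = merged
    return candidates


def detect_gbm(
    rec: ImuRecording,
    clf: StepClassifier,
    cfg: GbmConfig | None = None,
) -> list[StepInterval]:
    """Full supervised pipeline: features -> probabilities -> intervals."""
    cfg = clf.config if cfg is None else cfg
    features = build_feature_matrix([(rec, None)], cfg)
    mask = predict_mask(clf, features, cfg.prob_threshold)
    return mask_to_steps(mask, cfg.min_run, cfg.merge_gap)


def save_classifier(clf: StepClassifier, path) -> None:
    """Persist a classifier with its feature schema and configuration."""
    import joblib

    joblib.dump(
        {
            "model": clf.model,
            "feature_names": clf.feature_names,
            "config": clf.config,
            "seed": clf.seed,
            "metadata": clf.metadata,
        },
        path,
    )


def load_classifier(path) -> StepClassifier:
    import joblib

    payload = joblib.load(path)
    return StepClassifier(
        model=payload["model"],
        feature_names=payload["feature_names"],
        config=payload["config"],
        seed=payload["seed"],
        metadata=payload.get("metadata", {}),
    )
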
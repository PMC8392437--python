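"""Frequency feature matrices, leave-one-out random-forest scores, and
specificity-anchored operating points.

Per-sample mutation frequencies (percent) over the panel whitelist are the
only features. Each sample receives a cancer-probability score in [0, 1] from
a random forest trained on every other sample (leave-one-out
cross-validation). Score thresholds are then anchored on the control cohort:
among the midpoints between sorted distinct control scores, the cutoff whose
achieved specificity is nearest the target (95% or 99%) is chosen, ties going
to the higher specificity. A sample is called positive when its score is
strictly above the threshold.

Sex-restricted models (prostate: males, breast: females) and the separation
of manual vs automated DNA-extraction batches are enforced at cohort-subset
time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

ORGAN_MODELS = ("bladder", "prostate", "lung", "liver", "pancreas", "colorectal", "breast")
MODELS = ("all",) + ORGAN_MODELS

LABEL_COLUMNS = ["label", "organ", "stage", "sex", "batch"]


class CohortError(ValueError):
    """Inconsistent cohort labels or an empty model subset."""


def validate_labels(labels: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort label frame (index sample_id, columns LABEL_COLUMNS)."""
    missing = [c for c in LABEL_COLUMNS if c not in labels.columns]
    if missing:
        raise CohortError(f"label table missing columns {missing}")
    bad = labels[~labels["label"].isin(["cancer", "control"])]
    if len(bad):
        raise CohortError(f"unknown label values for samples {list(bad.index[:5])}")
    controls = labels[labels["label"] == "control"]
    if not (controls["organ"] == "none").all() or not (controls["stage"] == "not_applicable").all():
        raise CohortError("controls must have organ 'none' and stage 'not_applicable'")
    return labels


@dataclass
class FeatureMatrix:
    """Samples x whitelist-variants grid of frequencies (percent), no holes."""

    values: pd.DataFrame  # index sample_id (sorted), columns variant_id (sorted)
    provenance: dict = field(default_factory=dict)  # sample_id -> extraction batch

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise CohortError("feature matrix contains missing cells")
        if (self.values.to_numpy() < 0).any():
            raise CohortError("frequencies must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.values.columns)


def build_feature_matrix(tables, panel, labels: pd.DataFrame) -> FeatureMatrix:
    """One row per QC-passed sample, one column per whitelist variant.

    A variant absent from a sample's mutation table contributes frequency 0.
    Rows and columns are sorted for run-to-run determinism.
    """
    validate_labels(labels)
    variant_ids = sorted(v.variant_id for v in panel.whitelist)
    by_key = {v.key: v.variant_id for v in panel.whitelist}
    data = {}
    for table in tables:
        if table.sample_id not in labels.index:
            raise CohortError(f"sample {table.sample_id} has no label")
        row = dict.fromkeys(variant_ids, 0.0)
        for rec in table.records:
            variant_id = by_key.get(rec.key)
            if variant_id is not None:
                row[variant_id] = rec.frequency
        data[table.sample_id] = row
    values = pd.DataFrame.from_dict(data, orient="index").reindex(columns=variant_ids)
    values = values.sort_index()
    values.index.name = "sample_id"
    provenance = {sid: labels.loc[sid, "batch"] for sid in values.index}
    return FeatureMatrix(values=values, provenance=provenance)


def matrix_from_frame(frequencies: pd.DataFrame, labels: pd.DataFrame) -> FeatureMatrix:
    """Wrap an existing samples x variants frequency frame (simulator output)."""
    validate_labels(labels)
    values = frequencies.sort_index().reindex(sorted(frequencies.columns), axis=1)
    provenance = {sid: labels.loc[sid, "batch"] for sid in values.index}
    return FeatureMatrix(values=values, provenance=provenance)


def subset_cohort(labels: pd.DataFrame, model: str, batch: str | None = None) -> list[str]:
    """Sample ids entering one model run.

    ``all``: every cancer plus every control. An organ model: that organ's
    cancers plus all controls. Prostate restricts both groups to males,
    breast to females. When ``batch`` is given, only samples from that
    extraction batch are kept (manual and automated runs are never pooled).
    """
    validate_labels(labels)
    if model not in MODELS:
        raise CohortError(f"unknown model {model!r}")
    frame = labels
    if batch is not None:
        frame = frame[frame["batch"] == batch]
    if model == "all":
        mask = frame["label"].isin(["cancer", "control"])
    else:
        mask = (frame["label"] == "control") | (frame["organ"] == model)
    if model == "prostate":
        mask &= frame["sex"] == "male"
    elif model == "breast":
        mask &= frame["sex"] == "female"
    subset = frame[mask]
    n_cancer = int((subset["label"] == "cancer").sum())
    n_control = int((subset["label"] == "control").sum())
    if n_cancer == 0 or n_control == 0:
        raise CohortError(
            f"model {model!r} (batch {batch!r}): empty class "
            f"({n_cancer} cancers, {n_control} controls)"
        )
    return sorted(subset.index)


@dataclass
class ModelConfig:
    """Random-forest and cross-validation hyperparameters."""

    n_estimators: int = 100
    max_features: str = "sqrt"
    class_weight: str = "balanced"
    min_samples_leaf: int = 1
    cv: str = "loocv"  # or "kfold" for large synthetic cohorts
    n_folds: int = 10


@dataclass
class ScoreSet:
    """Per-sample cancer-probability scores in [0, 1]."""

    scores: pd.Series  # index sample_id

    def __post_init__(self) -> None:
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValueError("scores must lie in [0, 1]")

    def __getitem__(self, sample_id: str) -> float:
        return float(self.scores[sample_id])


def loocv_scores(
    matrix: FeatureMatrix,
    labels: pd.DataFrame,
    config: ModelConfig | None = None,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> ScoreSet:
    """Cross-validated cancer-probability scores.

    Under LOOCV each sample is scored by a forest trained on all other
    samples; fold ``i`` (in canonical sorted-sample order) uses random state
    ``seed + i``, making the output reproducible and invariant to the row
    order of the input matrix.
    """
    if config is None:
        config = ModelConfig()
    ids = sorted(sample_ids) if sample_ids is not None else list(matrix.values.index)
    X = matrix.values.loc[ids].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    y = (labels.loc[ids, "label"] == "cancer").to_numpy()
    if y.sum() < 2 or (~y).sum() < 2:
        raise CohortError("need at least 2 samples per class")

    def _forest(fold_seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=config.n_estimators,
            max_features=config.max_features,
            class_weight=config.class_weight,
            min_samples_leaf=config.min_samples_leaf,
            random_state=fold_seed,
            n_jobs=1,
        )

    scores = np.empty(len(ids))
    if config.cv == "loocv":
        for i in range(len(ids)):
            mask = np.ones(len(ids), dtype=bool)
            mask[i] = False
            forest = _forest(seed + i)
            forest.fit(X[mask], y[mask])
            cancer_col = list(forest.classes_).index(True)
            scores[i] = forest.predict_proba(X[i : i + 1])[0, cancer_col]
    elif config.cv == "kfold":
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(ids))
        folds = np.array_split(order, config.n_folds)
        for fold_index, test_idx in enumerate(folds):
            mask = np.ones(len(ids), dtype=bool)
            mask[test_idx] = False
            forest = _forest(seed + fold_index)
            forest.fit(X[mask], y[mask])
            cancer_col = list(forest.classes_).index(True)
            scores[test_idx] = forest.predict_proba(X[test_idx])[:, cancer_col]
    else:
        raise ValueError(f"unknown cv mode {config.cv!r}")
    return ScoreSet(scores=pd.Series(scores, index=ids, name="score"))


@dataclass(frozen=True)
class OperatingPoint:
    """A score cutoff anchored at a target specificity on the control cohort."""

    target_specificity: float
    threshold: float
    achieved_specificity: float
    n_control_positive: int
    n_controls: int

    def is_positive(self, score: float) -> bool:
        return score > self.threshold


def derive_cutoff(control_scores, target_specificity: float) -> OperatingPoint:
    """Choose the cutoff whose achieved specificity is nearest the target.

    Candidate thresholds are the midpoints between sorted distinct control
    scores plus sentinels below and above all scores; a control counts as
    positive when its score is strictly above the threshold. Ties in
    closeness resolve toward the higher specificity.
    """
    scores = np.asarray(control_scores, dtype=float)
    n = scores.size
    if n == 0:
        raise ValueError("no control scores")
    distinct = np.unique(scores)
    candidates = [distinct[0] - 1.0]
    candidates += [(a + b) / 2 for a, b in zip(distinct[:-1], distinct[1:])]
    candidates += [distinct[-1] + 1.0]
    best: tuple[float, float, float, int] | None = None
    for threshold in candidates:
        n_pos = int((scores > threshold).sum())
        achieved = 1.0 - n_pos / n
        distance = abs(achieved - target_specificity)
        key = (distance, -achieved)
        if best is None or key < best[:2]:
            best = (distance, -achieved, threshold, n_pos)
    _, neg_achieved, threshold, n_pos = best
    return OperatingPoint(
        target_specificity=target_specificity,
        threshold=float(threshold),
        achieved_specificity=-neg_achieved,
        n_control_positive=n_pos,
        n_controls=n,
    )


def derive_operating_points(
    scores: ScoreSet, labels: pd.DataFrame, targets=(0.95, 0.99)
) -> dict[float, OperatingPoint]:
    control_ids = [s for s in scores.scores.index if labels.loc[s, "label"] == "control"]
    if len(control_ids) < 20:
        raise CohortError("need >= 20 control scores to anchor operating points")
    control_scores = scores.scores[control_ids].to_numpy()
    points = {}
    for target in targets:
        if len(control_ids) < math.ceil(1.0 / (1.0 - target)):
            import warnings

            warnings.warn(
                f"{len(control_ids)} controls cannot resolve specificity {target}",
                stacklevel=2,
            )
        points[target] = derive_cutoff(control_scores, target)
    return points


def write_scores(scores_by_model: dict[str, ScoreSet], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tmodel\tscore\n")
        for model in sorted(scores_by_model):
            series = scores_by_model[model].scores
            for sample_id, score in series.items():
                fh.write(f"{sample_id}\t{model}\t{score:.6f}\n")


def write_operating_points(points_by_model: dict[str, dict[float, OperatingPoint]], path) -> None:
    with open(path, "w") as fh:
        fh.write("model\ttarget_specificity\tthreshold\tachieved_specificity\tn_control_positive\n")
        for model in sorted(points_by_model):
            for target in sorted(points_by_model[model]):
                op = points_by_model[model][target]
                fh.write(
                    f"{model}\t{target:.2f}\t{op.threshold:.6f}\t"
                    f"{op.achieved_specificity:.6f}\t{op.n_control_positive}\n"
                )
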
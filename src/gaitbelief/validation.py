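"""Leave-one-out cross-validation and post-operative projection.

In LOO, only the classifier control parameters (theta, k per feature) are
refitted on the n-1 remaining subjects; the PCA models and the retained
feature set stay fixed, mirroring a workflow in which only the evidence
calibration adapts per fold.  This is a known source of optimistic bias; set
``config.refit_pca_in_loo`` to refit the PCA models inside every fold for
comparison.

Post-operative visits are scored with the trained PCA models and classified by
the fully trained classifier — follow-up data never leaks into training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .cohort_io import SubjectRecord
from .cardiff_classifier import (
    BeliefTriplet,
    DegenerateFeatureError,
    TrainedClassifier,
    classify,
    fit_transfer_params,
    combine_all,
    confidence_factor,
    to_boe,
)
from .feature_reduction import FeatureId, PCAModel, build_feature_matrix, fit_all_pca


class ValidationError(Exception):
    pass


@dataclass
class LOOReport:
    """Per-subject held-out beliefs and aggregate accuracy."""

    table: pd.DataFrame  # subject_id, cohort, b_oa, b_np, u, predicted, correct
    n_correct: int
    n_total: int
    by_cohort: dict[str, tuple[int, int]]  # cohort -> (correct, total)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total

    def summary(self) -> dict:
        return {
            "n_correct": self.n_correct,
            "n_total": self.n_total,
            "accuracy": self.accuracy,
            "by_cohort": {c: {"correct": v[0], "total": v[1]} for c, v in self.by_cohort.items()},
        }


def _classify_fold(
    train_fm: pd.DataFrame,
    train_labels: np.ndarray,
    held_row: Mapping[FeatureId, float],
    features: Sequence[FeatureId],
    config: PipelineConfig,
) -> BeliefTriplet:
    """Refit transfer params on the training fold and classify the held-out row.

    Features degenerate within the fold are skipped for that fold only.
    """
    is_oa = train_labels == "OA"
    if is_oa.sum() < 1 or (~is_oa).sum() < 1:
        raise ValidationError("cohort collapsed during hold-out")
    boes = []
    for f in features:
        col = train_fm[f].to_numpy(dtype=float)
        try:
            p = fit_transfer_params(col[~is_oa], col[is_oa], config, feature_id=f)
        except DegenerateFeatureError:
            continue
        boes.append(to_boe(p, confidence_factor(p, float(held_row[f]))))
    combined = combine_all(boes)
    return BeliefTriplet(combined.m_oa, combined.m_np, combined.m_u)


def loo_validate(
    subjects: Sequence[SubjectRecord],
    retained_features: Sequence[FeatureId],
    config: PipelineConfig,
    pca_models: Mapping[str, PCAModel] | None = None,
    feature_matrix: pd.DataFrame | None = None,
) -> LOOReport:
    """Leave-one-out validation of the classifier over the baseline cohort.

    A precomputed baseline ``feature_matrix`` (rows aligned with ``subjects``)
    may be supplied to skip the PCA stage; otherwise models are fitted on all
    subjects once (or per fold when ``config.refit_pca_in_loo``).
    """
    labels = np.asarray([s.cohort for s in subjects])
    if (labels == "OA").sum() < 2 or (labels == "NP").sum() < 2:
        raise ValidationError("need >=2 subjects per cohort")
    refit_pca = config.refit_pca_in_loo
    if feature_matrix is None and not refit_pca:
        if pca_models is None:
            pca_models = fit_all_pca(subjects, config)
        feature_matrix = build_feature_matrix(pca_models, subjects, "baseline",
                                              variables=config.variables)
    rows = []
    n = len(subjects)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if refit_pca:
            train_subjects = [s for j, s in enumerate(subjects) if mask[j]]
            fold_models = fit_all_pca(train_subjects, config)
            train_fm = build_feature_matrix(fold_models, train_subjects, "baseline",
                                            variables=config.variables)
            held_fm = build_feature_matrix(fold_models, [subjects[i]], "baseline",
                                           variables=config.variables)
            held_row = held_fm.iloc[0]
        else:
            train_fm = feature_matrix.iloc[mask]
            held_row = feature_matrix.iloc[i]
        triplet = _classify_fold(train_fm, labels[mask], held_row,
                                 retained_features, config)
        predicted = triplet.predicted
        correct = predicted == labels[i]  # ties (None) count as incorrect
        rows.append({
            "subject_id": subjects[i].subject_id,
            "cohort": labels[i],
            "b_oa": triplet.b_oa,
            "b_np": triplet.b_np,
            "u": triplet.u,
            "predicted": predicted,
            "correct": bool(correct),
        })
    table = pd.DataFrame(rows)
    by_cohort = {
        c: (int(table.loc[table.cohort == c, "correct"].sum()), int((table.cohort == c).sum()))
        for c in ("NP", "OA")
    }
    return LOOReport(
        table=table,
        n_correct=int(table["correct"].sum()),
        n_total=len(table),
        by_cohort=by_cohort,
    )


def apply_postop(
    classifier: TrainedClassifier,
    pca_models: Mapping[str, PCAModel],
    subjects: Sequence[SubjectRecord],
    config: PipelineConfig,
) -> list[BeliefTriplet]:
    """Beliefs for the post-operative visit via the trained models (no refit).

    Subjects without a post-operative visit are skipped; subjects outside the
    training cohort are classified anyway.
    """
    postop = [s for s in subjects if "postop" in s.waveforms]
    if not postop:
        return []
    fm = build_feature_matrix(pca_models, postop, "postop", variables=config.variables)
    return [
        classify(classifier, fm.iloc[i], subject_id=s.subject_id, visit="postop")
        for i, s in enumerate(postop)
    ]


def apply_baseline(
    classifier: TrainedClassifier,
    pca_models: Mapping[str, PCAModel],
    subjects: Sequence[SubjectRecord],
    config: PipelineConfig,
) -> list[BeliefTriplet]:
    """Beliefs for the baseline visit via the trained models."""
    fm = build_feature_matrix(pca_models, subjects, "baseline", variables=config.variables)
    return [
        classify(classifier, fm.iloc[i], subject_id=s.subject_id, visit="baseline")
        for i, s in enumerate(subjects)
    ]
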
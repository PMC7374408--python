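"""Per-variable PCA over gait waveforms and projection onto trained components.

One PCA model is fitted per waveform variable on the pooled NP+OA training
curves (mean-centred, not variance-standardised; standardisation happens inside
the classifier's transfer function).  The first ``n_components`` components are
retained (3 by default), giving a subjects x (variables * components) feature
matrix of PC scores.  Post-operative visits are projected onto the *trained*
mean and basis — the models are never refitted on follow-up data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .config import N_CYCLE_SAMPLES, PipelineConfig
from .cohort_io import SubjectRecord

#: A feature identifier: (variable_name, 1-based component index).
FeatureId = tuple[str, int]


class FitError(Exception):
    """PCA fit preconditions violated."""


class FeatureMatrixError(Exception):
    """A subject-visit is missing a registered waveform."""


@dataclass
class PCAModel:
    """Trained principal components of one variable's waveform ensemble."""

    variable_name: str
    mean_curve: np.ndarray  # (101,)
    components: np.ndarray  # (retained, 101), orthonormal rows
    explained_variance: np.ndarray  # (retained,), non-increasing

    def score(self, waveform: np.ndarray) -> np.ndarray:
        """Project one curve: score_k = <waveform - mean_curve, component_k>."""
        waveform = np.asarray(waveform, dtype=float)
        if waveform.shape != (N_CYCLE_SAMPLES,):
            raise FitError(
                f"waveform for {self.variable_name!r} has shape {waveform.shape}, "
                f"expected ({N_CYCLE_SAMPLES},)"
            )
        return (waveform - self.mean_curve) @ self.components.T

    def to_dict(self) -> dict:
        return {
            "variable_name": self.variable_name,
            "mean_curve": self.mean_curve.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "PCAModel":
        return cls(
            variable_name=data["variable_name"],
            mean_curve=np.asarray(data["mean_curve"], dtype=float),
            components=np.asarray(data["components"], dtype=float),
            explained_variance=np.asarray(data["explained_variance"], dtype=float),
        )


def fit_pca(curves: Sequence[np.ndarray] | np.ndarray, retained: int = 3,
            variable_name: str = "") -> PCAModel:
    """Fit a PCA model to one variable's training curves.

    The mean curve is the pointwise mean over the pooled training set;
    components are eigenvectors of the sample covariance in decreasing
    eigenvalue order.  Eigenvector sign ambiguity is removed by forcing each
    component's largest-magnitude loading to be positive.
    """
    data = np.asarray(curves, dtype=float)
    if data.ndim != 2 or data.shape[1] != N_CYCLE_SAMPLES:
        raise FitError(f"training curves must be (n, {N_CYCLE_SAMPLES}), got {data.shape}")
    if data.shape[0] < retained + 1:
        raise FitError(
            f"need at least {retained + 1} training curves for {retained} components, "
            f"got {data.shape[0]}"
        )
    pca = PCA(n_components=retained, svd_solver="full")
    pca.fit(data)
    components = pca.components_.copy()
    for k in range(components.shape[0]):
        j = np.argmax(np.abs(components[k]))
        if components[k, j] < 0:
            components[k] = -components[k]
    return PCAModel(
        variable_name=variable_name,
        mean_curve=pca.mean_.copy(),
        components=components,
        explained_variance=pca.explained_variance_.copy(),
    )


def score(model: PCAModel, waveform: np.ndarray) -> np.ndarray:
    return model.score(waveform)


def fit_all_pca(subjects: Sequence[SubjectRecord], config: PipelineConfig,
                visit: str = "baseline") -> dict[str, PCAModel]:
    """Fit one PCA model per registered variable on the given visit's curves."""
    models = {}
    for var in config.variables:
        curves = []
        for s in subjects:
            if visit not in s.waveforms or var not in s.waveforms[visit]:
                raise FeatureMatrixError(f"subject {s.subject_id} lacks {var!r} at {visit}")
            curves.append(s.waveforms[visit][var].samples)
        models[var] = fit_pca(np.asarray(curves), retained=config.n_components,
                              variable_name=var)
    return models


def build_feature_matrix(
    models: Mapping[str, PCAModel],
    subjects: Sequence[SubjectRecord],
    visit: str,
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Subjects x (variable, component) PC-score matrix for one visit.

    Column order is deterministic: registry order, then component index
    (1-based).  A missing waveform raises naming the subject and variable.
    """
    if variables is None:
        variables = list(models)
    columns = pd.MultiIndex.from_tuples(
        [(var, k + 1) for var in variables for k in range(models[var].components.shape[0])],
        names=["variable", "component"],
    )
    rows = []
    index = []
    for s in subjects:
        if visit not in s.waveforms:
            raise FeatureMatrixError(f"subject {s.subject_id} has no {visit} visit")
        row = []
        for var in variables:
            if var not in s.waveforms[visit]:
                raise FeatureMatrixError(
                    f"subject {s.subject_id} is missing variable {var!r} at {visit}"
                )
            row.extend(models[var].score(s.waveforms[visit][var].samples))
        rows.append(row)
        index.append(s.subject_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="subject_id"), columns=columns)


def save_models(models: Mapping[str, PCAModel], path: str | Path,
                config_hash: str = "") -> None:
    payload = {
        "config_hash": config_hash,
        "models": {var: m.to_dict() for var, m in models.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_models(path: str | Path) -> tuple[dict[str, PCAModel], str]:
    payload = json.loads(Path(path).read_text())
    models = {var: PCAModel.from_dict(d) for var, d in payload["models"].items()}
    return models, payload.get("config_hash", "")
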
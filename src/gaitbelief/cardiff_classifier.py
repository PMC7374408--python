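"""Dempster-Shafer evidence-theory gait classifier ("Cardiff Classifier" style).

Each retained feature value v is mapped to a confidence factor by a sigmoid,

    cf(v) = 1 / (1 + exp(-k (v - theta))),

and the confidence factor to a body of evidence over the frame
Theta = {OA, NP} by the CaRBS-style linear map with clamping:

    m({OA}) = max(0,  B/(1-A) * cf - A B/(1-A))
    m({NP}) = max(0, -B/(1-A) * cf + B)
    m(Theta) = 1 - m({OA}) - m({NP})            (always >= 1 - B)

A is the ignorance margin, B the maximum mass any single feature may commit;
residual mass on Theta encodes per-feature uncertainty.  Per-feature bodies of
evidence are combined with Dempster's rule of combination, and on this
two-hypothesis frame the combined singleton masses are the final beliefs
B(OA), B(NP) and uncertainty U.

Control parameters are set explicitly from the training groups (no iterative
optimisation): theta at the midpoint of the NP and OA means, slope from the
pooled spread with a configurable gain.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .config import PipelineConfig
from .feature_reduction import FeatureId

#: Confidence factors are clamped to [EPS, 1-EPS] before mass assignment.
EPS = 1e-15
SUM_TOL = 1e-12


class ClassifierError(Exception):
    """Base class for classifier failures."""


class DegenerateFeatureError(ClassifierError):
    """A feature with no group separation or zero spread cannot carry evidence."""


class CombinationError(ClassifierError):
    """Total conflict (kappa = 1) between two bodies of evidence."""


@dataclass(frozen=True)
class TransferParams:
    """Explicit sigmoid/mass-assignment parameters for one feature."""

    feature_id: FeatureId
    k: float  # signed sigmoid slope, feature-units^-1
    theta: float  # sigmoid midpoint, feature units
    a: float  # ignorance margin A in [0, 1)
    b: float  # maximum assignable mass B in (0, 1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.a < 1.0:
            raise ClassifierError(f"A must lie in [0, 1), got {self.a}")
        if not 0.0 < self.b < 1.0:
            raise ClassifierError(f"B must lie in (0, 1), got {self.b}")
        if not math.isfinite(self.k) or self.k == 0.0:
            raise DegenerateFeatureError(f"slope k must be finite and nonzero for {self.feature_id}")


@dataclass(frozen=True)
class BodyOfEvidence:
    """Mass triplet over {OA}, {NP} and Theta = {OA, NP}; sums to 1."""

    m_oa: float
    m_np: float
    m_u: float

    def __post_init__(self) -> None:
        if min(self.m_oa, self.m_np, self.m_u) < -SUM_TOL:
            raise ClassifierError(f"negative mass in {self}")
        if abs(self.m_oa + self.m_np + self.m_u - 1.0) > SUM_TOL:
            raise ClassifierError(f"masses do not sum to 1 in {self}")


VACUOUS = BodyOfEvidence(0.0, 0.0, 1.0)


@dataclass(frozen=True)
class BeliefTriplet:
    """Final combined beliefs for one subject-visit."""

    b_oa: float
    b_np: float
    u: float
    subject_id: str = ""
    visit: str = ""

    def __post_init__(self) -> None:
        if abs(self.b_oa + self.b_np + self.u - 1.0) > SUM_TOL:
            raise ClassifierError(f"beliefs do not sum to 1 in {self}")

    @property
    def predicted(self) -> Optional[str]:
        """"OA" or "NP" by the larger belief; None on an exact tie."""
        if self.b_oa > self.b_np:
            return "OA"
        if self.b_np > self.b_oa:
            return "NP"
        return None


def confidence_factor(params: TransferParams, v: float) -> float:
    """Sigmoid confidence factor, clamped away from {0, 1} to guard overflow."""
    z = -params.k * (v - params.theta)
    if z > 700.0:
        cf = 0.0
    elif z < -700.0:
        cf = 1.0
    else:
        cf = 1.0 / (1.0 + math.exp(z))
    return min(max(cf, EPS), 1.0 - EPS)


def to_boe(params: TransferParams, cf: float) -> BodyOfEvidence:
    """Map a confidence factor to a body of evidence (CaRBS-style linear map)."""
    if not 0.0 < cf < 1.0:
        raise ClassifierError(f"confidence factor must lie in (0, 1), got {cf}")
    a, b = params.a, params.b
    m_oa = max(0.0, (b / (1.0 - a)) * cf - a * b / (1.0 - a))
    m_np = max(0.0, -(b / (1.0 - a)) * cf + b)
    return BodyOfEvidence(m_oa, m_np, 1.0 - m_oa - m_np)


def dempster_combine(boe1: BodyOfEvidence, boe2: BodyOfEvidence,
                     feature_ids: tuple = ()) -> BodyOfEvidence:
    """Dempster's rule on the two-hypothesis frame.

    Conflict kappa = m1(OA) m2(NP) + m1(NP) m2(OA) is discounted by
    normalisation; total conflict (kappa = 1) raises CombinationError.
    """
    kappa = boe1.m_oa * boe2.m_np + boe1.m_np * boe2.m_oa
    if kappa >= 1.0 - EPS:
        raise CombinationError(
            f"total conflict between bodies of evidence {feature_ids or (boe1, boe2)}"
        )
    m_oa = boe1.m_oa * boe2.m_oa + boe1.m_oa * boe2.m_u + boe1.m_u * boe2.m_oa
    m_np = boe1.m_np * boe2.m_np + boe1.m_np * boe2.m_u + boe1.m_u * boe2.m_np
    m_u = boe1.m_u * boe2.m_u
    # all three masses are computed explicitly and renormalised by their sum
    # (= 1 - kappa up to rounding) so m(Theta) never cancels to zero when a
    # singleton mass approaches 1
    norm = m_oa + m_np + m_u
    return BodyOfEvidence(m_oa / norm, m_np / norm, m_u / norm)


def combine_all(boes: Iterable[BodyOfEvidence]) -> BodyOfEvidence:
    """Left-fold of Dempster's rule (order-invariant by associativity)."""
    combined = VACUOUS
    for boe in boes:
        combined = dempster_combine(combined, boe)
    return combined


def fit_transfer_params(
    values_np: np.ndarray,
    values_oa: np.ndarray,
    config: PipelineConfig,
    feature_id: FeatureId = ("", 0),
) -> TransferParams:
    """Explicit control-parameter rule for one feature.

    theta = (mean_NP + mean_OA)/2;  k = sign(mean_OA - mean_NP) * 2 g / (sd_NP + sd_OA)
    with gain g, and A, B taken from the config.  Zero separation or zero
    pooled spread is degenerate: the feature carries no orientable evidence
    and is excluded by the caller.
    """
    values_np = np.asarray(values_np, dtype=float)
    values_oa = np.asarray(values_oa, dtype=float)
    if len(values_np) < 1 or len(values_oa) < 1:
        raise ClassifierError(f"need at least one subject per cohort to fit {feature_id}")
    mean_np, mean_oa = values_np.mean(), values_oa.mean()
    # a single-subject group (as in a leave-one-out fold of a minimal cohort)
    # contributes a point estimate with zero spread
    sd_np = values_np.std(ddof=1) if len(values_np) >= 2 else 0.0
    sd_oa = values_oa.std(ddof=1) if len(values_oa) >= 2 else 0.0
    separation = mean_oa - mean_np
    if separation == 0.0:
        raise DegenerateFeatureError(f"feature {feature_id} has zero group separation")
    if sd_np + sd_oa == 0.0:
        raise DegenerateFeatureError(f"feature {feature_id} has zero pooled spread")
    k = math.copysign(1.0, separation) * 2.0 * config.gain / (sd_np + sd_oa)
    theta = 0.5 * (mean_np + mean_oa)
    return TransferParams(feature_id=feature_id, k=k, theta=theta,
                          a=config.ignorance, b=config.max_belief)


@dataclass
class TrainedClassifier:
    """Retained features with their fitted transfer parameters."""

    features: list[FeatureId]
    params: dict[FeatureId, TransferParams]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.features:
            raise ClassifierError("feature list must be non-empty")
        if len(set(self.features)) != len(self.features):
            raise ClassifierError("feature list contains duplicates")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "features": [list(f) for f in self.features],
            "params": [
                {"variable": p.feature_id[0], "component": p.feature_id[1],
                 "k": p.k, "theta": p.theta, "a": p.a, "b": p.b}
                for p in (self.params[f] for f in self.features)
            ],
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedClassifier":
        payload = json.loads(Path(path).read_text())
        features = [tuple(f) for f in payload["features"]]
        params = {
            (p["variable"], p["component"]): TransferParams(
                feature_id=(p["variable"], p["component"]),
                k=p["k"], theta=p["theta"], a=p["a"], b=p["b"],
            )
            for p in payload["params"]
        }
        return cls(features=features, params=params, metadata=payload.get("metadata", {}))


def train_classifier(
    feature_matrix,
    labels,
    config: PipelineConfig,
    features: Sequence[FeatureId] | None = None,
) -> TrainedClassifier:
    """Fit transfer parameters for every retained feature on the full training set.

    Degenerate features are excluded with a warning rather than given an
    infinite slope.
    """
    if features is None:
        features = list(feature_matrix.columns)
    labels = np.asarray(labels)
    is_oa = labels == "OA"
    kept: list[FeatureId] = []
    params: dict[FeatureId, TransferParams] = {}
    for f in features:
        col = feature_matrix[f].to_numpy(dtype=float)
        try:
            params[f] = fit_transfer_params(col[~is_oa], col[is_oa], config, feature_id=f)
        except DegenerateFeatureError as exc:
            warnings.warn(f"excluding degenerate feature {f}: {exc}", stacklevel=2)
            continue
        kept.append(f)
    return TrainedClassifier(
        features=kept,
        params=params,
        metadata={
            "n_np": int((~is_oa).sum()),
            "n_oa": int(is_oa.sum()),
            "config_hash": config.config_hash(),
        },
    )


def classify(classifier: TrainedClassifier, row: Mapping[FeatureId, float],
             subject_id: str = "", visit: str = "") -> BeliefTriplet:
    """Combine per-feature evidence for one subject-visit into a belief triplet."""
    boes = []
    for f in classifier.features:
        if f not in row:
            raise ClassifierError(f"feature {f} missing from the input row")
        p = classifier.params[f]
        boes.append(to_boe(p, confidence_factor(p, float(row[f]))))
    combined = combine_all(boes)
    return BeliefTriplet(combined.m_oa, combined.m_np, combined.m_u,
                         subject_id=subject_id, visit=visit)


def simplex_coordinates(triplet: BeliefTriplet) -> tuple[float, float]:
    """Barycentric coordinates in the unit-side triangle.

    Vertices: B(NP)=1 at (0,0), B(OA)=1 at (1,0), U=1 at (0.5, sqrt(3)/2).
    The decision boundary B(OA)=B(NP) is the vertical line x = 0.5.
    """
    x = triplet.b_oa * 1.0 + triplet.u * 0.5
    y = triplet.u * (math.sqrt(3.0) / 2.0)
    return (x, y)


def belief_change(baseline: BeliefTriplet, postop: BeliefTriplet) -> float:
    """Objective change in gait biomechanics: post-operative minus baseline
    B(OA); negative values indicate improvement."""
    if baseline.subject_id != postop.subject_id:
        raise ClassifierError(
            f"subject mismatch: {baseline.subject_id!r} vs {postop.subject_id!r}"
        )
    if baseline.visit != "baseline" or postop.visit != "postop":
        raise ClassifierError(
            f"visit mismatch: expected (baseline, postop), got "
            f"({baseline.visit!r}, {postop.visit!r})"
        )
    return postop.b_oa - baseline.b_oa


def plot_simplex(
    triplets: Sequence[BeliefTriplet],
    labels: Sequence[str] | None = None,
    path: str | Path | None = None,
    ax=None,
):
    """Simplex (ternary) plot of belief triplets with the decision boundary."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5.5))
    h = math.sqrt(3.0) / 2.0
    ax.plot([0, 1, 0.5, 0], [0, 0, h, 0], color="k", lw=1)
    ax.plot([0.5, 0.5], [0, h], "k--", lw=0.8)  # B(OA) = B(NP)
    # interior loci where B(OA) = 0.5 and B(NP) = 0.5
    ax.plot([0.75, 0.5], [0, h / 2], "k-", lw=0.5)
    ax.plot([0.25, 0.5], [0, h / 2], "k-", lw=0.5)
    xy = np.array([simplex_coordinates(t) for t in triplets])
    if labels is None:
        labels = [""] * len(triplets)
    labels = np.asarray(labels)
    for lab, marker, color in (("NP", "o", "tab:blue"), ("OA", "x", "tab:red")):
        sel = labels == lab
        if sel.any():
            ax.scatter(xy[sel, 0], xy[sel, 1], marker=marker, color=color, label=lab, s=25)
    rest = ~np.isin(labels, ("NP", "OA"))
    if rest.any():
        ax.scatter(xy[rest, 0], xy[rest, 1], marker=".", color="gray")
    ax.annotate("B(NP)=1", (0, 0), xytext=(-0.05, -0.05), ha="right")
    ax.annotate("B(OA)=1", (1, 0), xytext=(1.05, -0.05), ha="left")
    ax.annotate("U=1", (0.5, h), xytext=(0.5, h + 0.04), ha="center")
    ax.set_aspect("equal")
    ax.axis("off")
    if (labels == "NP").any() or (labels == "OA").any():
        ax.legend(loc="upper left")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
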
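"""Pipeline configuration: the gait-variable registry, PROM instrument scales,
classifier constants, and provenance hashing.

A single :class:`PipelineConfig` travels through every stage.  All defaults are
serialisable; the SHA-256 hash of the canonical JSON form is stamped into every
artifact written by the CLI so that trained models and follow-up reports cannot
be mixed across configurations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

JOINTS = ("hip", "knee", "ankle")
PLANES = ("sagittal", "frontal", "transverse")

#: Samples per time-normalised gait cycle (0..100% inclusive).
N_CYCLE_SAMPLES = 101

VISITS = ("baseline", "postop")
COHORTS = ("NP", "OA")
INSTRUMENTS = ("OKS", "KOS", "PACS")


def default_variable_registry() -> list[str]:
    """The default 24-variable registry.

    Three joints x three planes x {angle, moment} (18), the three ground
    reaction force components, and the three pelvis orientation angles.  Any
    other set can be declared in the config; the registry only names the
    waveform channels the pipeline expects per subject-visit.
    """
    names = [f"{j}_{p}_{q}" for j in JOINTS for p in PLANES for q in ("angle", "moment")]
    names += ["grf_vertical", "grf_anteroposterior", "grf_mediolateral"]
    names += [f"pelvis_{p}_angle" for p in PLANES]
    return names


def variable_units(variable_name: str) -> str:
    if variable_name.endswith("_moment"):
        return "N·m/kg"
    if variable_name.startswith("grf_"):
        return "N/kg"
    return "degrees"


@dataclass(frozen=True)
class InstrumentScale:
    """Native range of a PROM instrument: raw ``worst`` maps to 0%, ``best`` to 100%."""

    worst: float
    best: float

    def __post_init__(self) -> None:
        if self.worst == self.best:
            raise ValueError("instrument scale must have distinct endpoints")


def default_instrument_scales(oks_modern: bool = False) -> dict[str, InstrumentScale]:
    """OKS: classic 0-best convention by default (48-best when ``oks_modern``);
    KOS activities-of-daily-living 0-70 with 70 best; PACS 0-110 with 0 best."""
    oks = InstrumentScale(worst=0.0, best=48.0) if oks_modern else InstrumentScale(worst=48.0, best=0.0)
    return {
        "OKS": oks,
        "KOS": InstrumentScale(worst=0.0, best=70.0),
        "PACS": InstrumentScale(worst=110.0, best=0.0),
    }


@dataclass
class PipelineConfig:
    """All tunables of the classification pipeline.

    Parameters
    ----------
    variables
        Waveform variable registry (each subject-visit must provide all of them).
    n_components
        Principal components retained per variable (default 3).
    target_size
        Number of features the split-half ranking aims to retain (default 18).
    gain
        Dimensionless slope gain g of the sigmoid transfer function;
        k = sign(mean_OA - mean_NP) * 2 g / (sd_NP + sd_OA).
    ignorance
        Ignorance margin A in [0, 1): confidence factors below A assign no
        mass to {OA}.
    max_belief
        Maximum single-feature mass B in (0, 1); every feature leaves at
        least 1 - B residual uncertainty.
    split_seed
        Seed of the stratified half-split used for feature ranking.
    normality_alpha
        Shapiro-Wilk level gating Pearson vs. Spearman and t vs. Wilcoxon.
    correlation_method
        "auto" (normality-gated), or force "pearson" / "spearman".
    oks_modern
        Use the 48-best OKS orientation instead of the classic 0-best one.
    refit_pca_in_loo
        Refit the PCA models inside every leave-one-out fold (slow; the
        default refits only the classifier control parameters).
    accuracy_floor
        Minimum LOO accuracy before the train command exits non-zero.
    """

    variables: list[str] = field(default_factory=default_variable_registry)
    n_components: int = 3
    target_size: int = 18
    gain: float = 2.0
    ignorance: float = 0.2
    max_belief: float = 0.9
    split_seed: int = 0
    normality_alpha: float = 0.05
    correlation_method: str = "auto"
    oks_modern: bool = False
    refit_pca_in_loo: bool = False
    accuracy_floor: float = 0.0

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("variable registry must not be empty")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable registry contains duplicates")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not 0.0 <= self.ignorance < 1.0:
            raise ValueError("ignorance margin A must lie in [0, 1)")
        if not 0.0 < self.max_belief < 1.0:
            raise ValueError("max_belief B must lie in (0, 1)")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.correlation_method not in ("auto", "pearson", "spearman"):
            raise ValueError(f"unknown correlation_method {self.correlation_method!r}")

    @property
    def instruments(self) -> dict[str, InstrumentScale]:
        return default_instrument_scales(self.oks_modern)

    def config_hash(self) -> str:
        """Short provenance hash of the canonical JSON form."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data.get("pipeline", data))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"pipeline": asdict(self)}, fh, sort_keys=False)
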
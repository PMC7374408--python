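"""Data model and file I/O for gait cohorts.

Subjects carry time-normalised waveforms (101 samples, 0-100% gait cycle) per
variable and visit; patient-reported outcome measures (PROMs) are stored
alongside with their raw and percent scores.  The on-disk exchange format is
long-form CSV: one row per waveform sample, one row per questionnaire record.

The pipeline starts at time-normalised waveforms; motion-capture processing
(marker trajectories, inverse dynamics) is out of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import (
    COHORTS,
    INSTRUMENTS,
    N_CYCLE_SAMPLES,
    VISITS,
    PipelineConfig,
    variable_units,
)

WAVEFORM_COLUMNS = ("subject_id", "cohort", "visit", "variable_name", "cycle_percent", "value")
PROM_COLUMNS = ("subject_id", "visit", "instrument", "raw_score")


class CohortError(Exception):
    """Base class for cohort I/O failures."""


class ParseError(CohortError):
    """A malformed row in an input file (message names the line)."""


class ValidationError(CohortError):
    """A record violating the data-model invariants."""


@dataclass
class GaitWaveform:
    """One variable's time-normalised curve for one subject-visit.

    Exactly 101 finite samples at 0..100% of the gait cycle.
    """

    subject_id: str
    visit: str
    variable_name: str
    samples: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.visit not in VISITS:
            raise ValidationError(f"unknown visit {self.visit!r} for subject {self.subject_id}")
        if self.samples.shape != (N_CYCLE_SAMPLES,):
            raise ValidationError(
                f"waveform {self.variable_name!r} of subject {self.subject_id} "
                f"({self.visit}) has {self.samples.size} samples, expected {N_CYCLE_SAMPLES}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(
                f"waveform {self.variable_name!r} of subject {self.subject_id} "
                f"({self.visit}) contains non-finite samples"
            )
        if not self.units:
            self.units = variable_units(self.variable_name)


@dataclass
class SubjectRecord:
    """A subject with cohort label, optional demographics, and per-visit waveforms.

    Non-pathological (NP) subjects have a baseline visit only; every visit
    present must carry the identical set of variable names.
    """

    subject_id: str
    cohort: str
    waveforms: dict[str, dict[str, GaitWaveform]] = field(default_factory=dict)
    demographics: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(f"unknown cohort {self.cohort!r} for subject {self.subject_id}")
        if self.cohort == "NP" and "postop" in self.waveforms:
            raise ValidationError(f"NP subject {self.subject_id} has a postop visit")
        varsets = {visit: frozenset(wfs) for visit, wfs in self.waveforms.items()}
        if len(set(varsets.values())) > 1:
            raise ValidationError(
                f"subject {self.subject_id}: visits carry different variable sets"
            )

    @property
    def visits(self) -> tuple[str, ...]:
        return tuple(v for v in VISITS if v in self.waveforms)

    def variable_names(self) -> frozenset[str]:
        for wfs in self.waveforms.values():
            return frozenset(wfs)
        return frozenset()


@dataclass
class PROMRecord:
    """One questionnaire score: raw value on the instrument's native scale plus
    the percent score (100 = healthy).  A missing raw score stays missing."""

    subject_id: str
    visit: str
    instrument: str
    raw_score: Optional[float]
    percent_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.visit not in VISITS:
            raise ValidationError(f"unknown visit {self.visit!r} in PROM for {self.subject_id}")
        if self.instrument not in INSTRUMENTS:
            raise ValidationError(
                f"unknown instrument {self.instrument!r} in PROM for {self.subject_id}"
            )
        if self.raw_score is not None and math.isnan(self.raw_score):
            self.raw_score = None
        if self.percent_score is not None and not 0.0 <= self.percent_score <= 100.0:
            raise ValidationError(
                f"percent score {self.percent_score} outside [0, 100] for {self.subject_id}"
            )

    @property
    def missing(self) -> bool:
        return self.raw_score is None


def percent_score(instrument: str, raw_score: Optional[float], config: PipelineConfig) -> Optional[float]:
    """Linearly map a raw instrument score to percent, 100 = healthy/best.

    Missing raw scores propagate as ``None``.  Raw values outside the
    instrument's native range raise :class:`ValidationError`.
    """
    if raw_score is None or (isinstance(raw_score, float) and math.isnan(raw_score)):
        return None
    try:
        scale = config.instruments[instrument]
    except KeyError:
        raise ValidationError(f"unknown instrument {instrument!r}") from None
    lo, hi = min(scale.worst, scale.best), max(scale.worst, scale.best)
    if not lo <= raw_score <= hi:
        raise ValidationError(
            f"{instrument} raw score {raw_score} outside native range [{lo}, {hi}]"
        )
    return 100.0 * (raw_score - scale.worst) / (scale.best - scale.worst)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CohortError(f"file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required and c != "units"]
    if extra:
        warnings.warn(f"{path}: ignoring unrecognised columns {extra}", stacklevel=3)
    return df


def _parse_float(text) -> float:
    # python float() parsing is correctly rounded, so repr-written values
    # round-trip bit-exactly (pandas' fast parser can be off by one ulp)
    if pd.isna(text) or text == "":
        return float("nan")
    try:
        return float(text)
    except ValueError:
        return float("nan")


def _to_number(df: pd.DataFrame, column: str, path: Path, integer: bool = False) -> pd.Series:
    converted = df[column].map(_parse_float)
    bad = converted.isna() & df[column].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ParseError(f"{path}, line {line}: cannot parse {column}={df[column][bad.idxmax()]!r}")
    if integer:
        frac = converted.dropna() % 1 != 0
        if frac.any():
            line = int(frac.idxmax()) + 2
            raise ParseError(f"{path}, line {line}: {column} must be an integer")
    return converted


def read_cohort(
    waveform_path: str | Path,
    prom_path: str | Path | None,
    config: PipelineConfig,
) -> tuple[list[SubjectRecord], list[PROMRecord]]:
    """Read and validate a cohort from long-form CSVs.

    Waveforms with a wrong sample count, unknown variables, visits or cohorts
    raise :class:`ValidationError`; subjects whose variable set is incomplete
    relative to the configured registry are dropped with a warning naming them.
    """
    waveform_path = Path(waveform_path)
    wdf = _read_csv(waveform_path, WAVEFORM_COLUMNS)
    registry = list(config.variables)
    subjects: list[SubjectRecord] = []
    if len(wdf):
        wdf = wdf.copy()
        wdf["cycle_percent"] = _to_number(wdf, "cycle_percent", waveform_path, integer=True)
        wdf["value"] = _to_number(wdf, "value", waveform_path)
        unknown_vars = set(wdf["variable_name"]) - set(registry)
        if unknown_vars:
            raise ValidationError(f"variables not in the configured registry: {sorted(unknown_vars)}")

        rejected: list[str] = []
        for subject_id, sdf in wdf.groupby("subject_id", sort=True):
            cohorts = sdf["cohort"].unique()
            if len(cohorts) != 1:
                raise ValidationError(f"subject {subject_id} has conflicting cohort labels")
            waveforms: dict[str, dict[str, GaitWaveform]] = {}
            for (visit, var), vdf in sdf.groupby(["visit", "variable_name"], sort=True):
                vdf = vdf.sort_values("cycle_percent")
                pcts = vdf["cycle_percent"].to_numpy()
                if len(vdf) != N_CYCLE_SAMPLES or not np.array_equal(pcts, np.arange(N_CYCLE_SAMPLES)):
                    raise ValidationError(
                        f"subject {subject_id}, variable {var!r} ({visit}): expected "
                        f"{N_CYCLE_SAMPLES} samples at 0..100%, got {len(vdf)}"
                    )
                wf = GaitWaveform(str(subject_id), str(visit), str(var), vdf["value"].to_numpy())
                waveforms.setdefault(str(visit), {})[str(var)] = wf
            complete = all(set(wfs) == set(registry) for wfs in waveforms.values())
            if not complete:
                rejected.append(str(subject_id))
                continue
            subjects.append(SubjectRecord(str(subject_id), str(cohorts[0]), waveforms))
        if rejected:
            warnings.warn(
                f"rejected {len(rejected)} subject(s) with incomplete variable sets: {rejected}",
                stacklevel=2,
            )

    proms: list[PROMRecord] = []
    if prom_path is not None:
        prom_path = Path(prom_path)
        pdf = _read_csv(prom_path, PROM_COLUMNS)
        if len(pdf):
            raw = _to_number(pdf, "raw_score", prom_path)
            for i, row in pdf.iterrows():
                raw_value = None if pd.isna(raw[i]) else float(raw[i])
                proms.append(
                    PROMRecord(
                        subject_id=str(row["subject_id"]),
                        visit=str(row["visit"]),
                        instrument=str(row["instrument"]),
                        raw_score=raw_value,
                        percent_score=percent_score(str(row["instrument"]), raw_value, config),
                    )
                )
    return subjects, proms


def write_cohort(
    subjects: Iterable[SubjectRecord],
    proms: Iterable[PROMRecord],
    waveform_path: str | Path,
    prom_path: str | Path,
) -> None:
    """Write a cohort to long-form CSVs; ``read_cohort`` round-trips the numeric
    fields bit-exactly (floats are serialised with full repr precision)."""
    wrows = []
    for s in subjects:
        for visit in s.visits:
            for var in sorted(s.waveforms[visit]):
                wf = s.waveforms[visit][var]
                for pct, value in enumerate(wf.samples):
                    wrows.append((s.subject_id, s.cohort, visit, var, pct, repr(float(value))))
    wdf = pd.DataFrame(wrows, columns=WAVEFORM_COLUMNS)
    wdf.to_csv(waveform_path, index=False)

    prows = [
        (p.subject_id, p.visit, p.instrument, "" if p.raw_score is None else repr(float(p.raw_score)))
        for p in proms
    ]
    pdf = pd.DataFrame(prows, columns=PROM_COLUMNS)
    pdf.to_csv(prom_path, index=False)
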
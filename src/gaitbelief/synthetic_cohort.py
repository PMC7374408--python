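"""Synthetic NP/OA gait cohorts with the statistical structure the pipeline assumes.

Each variable's waveform is built as

    curve(t) = template(t) + sum_m score_{s,m} * mode_m(t) + noise(t)

with smooth orthonormal mode shapes (an orthonormalised low-order cosine
basis).  Osteoarthritic (OA) subjects are shifted along a configured set of
discriminatory (variable, mode) pairs by ``effect_size_d`` standard deviations
of the mode score.  A post-operative visit for a subset of OA subjects moves
each mode score a latent per-subject fraction rho of the way from baseline
toward the NP mean, and patient-reported outcome (PROM) percent changes are
built from rho via the bivariate-normal construction

    change = mu_c + sigma_c * (r * z_rho + sqrt(1 - r^2) * eps),

so the correlation between PROM change and rho is ``prom_r`` in expectation.

The generator is deterministic under a fixed seed; one master seed spawns
per-component substreams so adding a variable does not perturb earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import N_CYCLE_SAMPLES, PipelineConfig, default_variable_registry, variable_units
from .cohort_io import GaitWaveform, PROMRecord, SubjectRecord, percent_score


@dataclass
class GeneratorSpec:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the training cohort the classifier is designed for:
    31 non-pathological and 41 osteoarthritic subjects, 22 of whom return for
    a post-operative visit; 24 waveform variables with 3 latent variation
    modes each, 6 of which carry the group effect.
    """

    n_np: int = 31
    n_oa: int = 41
    n_postop: int = 22
    n_variables: int = 24
    n_modes_per_variable: int = 3
    discriminatory_modes: Optional[tuple[tuple[str, int], ...]] = None
    effect_size_d: float = 2.0
    score_sd: tuple[float, ...] = (3.0, 2.0, 1.0)
    noise_sd: float = 0.05
    recovery_mean: float = 0.6
    recovery_sd: float = 0.3
    recovery_bounds: tuple[float, float] = (-0.1, 1.1)
    prom_r: float = 0.8
    prom_baseline_mean: float = 45.0
    prom_baseline_sd: float = 10.0
    prom_change_mean: float = 30.0
    prom_change_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_np", "n_oa", "n_variables", "n_modes_per_variable"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.n_postop <= self.n_oa:
            raise ValueError("n_postop must lie in [0, n_oa]")
        if abs(self.prom_r) > 1:
            raise ValueError("|prom_r| must be <= 1")
        if len(self.score_sd) < self.n_modes_per_variable:
            raise ValueError("score_sd must provide one value per mode")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.recovery_bounds[0] >= self.recovery_bounds[1]:
            raise ValueError("recovery_bounds must be increasing")
        if self.discriminatory_modes is None:
            variables = self.variable_names()
            n_disc = min(6, self.n_variables)
            self.discriminatory_modes = tuple((variables[i], 1) for i in range(n_disc))
        for var, mode in self.discriminatory_modes:
            if var not in self.variable_names():
                raise ValueError(f"discriminatory variable {var!r} not in the registry")
            if not 1 <= mode <= self.n_modes_per_variable:
                raise ValueError(f"discriminatory mode {mode} out of range")

    def variable_names(self) -> list[str]:
        registry = default_variable_registry()
        if self.n_variables <= len(registry):
            return registry[: self.n_variables]
        extra = [f"extra_{i:02d}_angle" for i in range(self.n_variables - len(registry))]
        return registry + extra

    def pipeline_config(self, **overrides) -> PipelineConfig:
        """A PipelineConfig whose registry matches this generator."""
        return PipelineConfig(variables=self.variable_names(), **overrides)


@dataclass
class GroundTruth:
    """Latent quantities behind a generated cohort (for parameter-recovery tests)."""

    rho: pd.Series  # per post-operative subject recovery fraction
    mode_scores: pd.DataFrame  # index (subject_id, visit); columns (variable, mode)
    discriminatory_modes: tuple[tuple[str, int], ...]
    prom_change_percent: pd.DataFrame  # intended (pre-quantisation) percent changes


def mode_shapes(n_modes: int) -> np.ndarray:
    """Orthonormal smooth mode shapes over the 101-sample grid.

    Low-order cosines cos(m*pi*t/100), m = 1..n_modes, orthonormalised by QR so
    the basis is exactly orthonormal under the plain dot product; signs fixed so
    each mode starts positive.
    """
    t = np.arange(N_CYCLE_SAMPLES) / (N_CYCLE_SAMPLES - 1)
    raw = np.stack([np.cos(np.pi * (m + 1) * t) for m in range(n_modes)], axis=1)
    q, _ = np.linalg.qr(raw)
    q *= np.where(q[0] >= 0, 1.0, -1.0)
    return q.T  # (n_modes, 101)


def _template(variable_index: int) -> np.ndarray:
    """A deterministic smooth per-variable template curve (arbitrary units)."""
    t = np.arange(N_CYCLE_SAMPLES) / (N_CYCLE_SAMPLES - 1)
    amp = 8.0 + 3.0 * (variable_index % 5)
    phase = 2.0 * np.pi * variable_index / 24.0
    return amp * np.sin(2.0 * np.pi * t + phase) + 0.5 * variable_index


def generate_cohort(
    spec: GeneratorSpec,
) -> tuple[list[SubjectRecord], list[PROMRecord], GroundTruth]:
    """Generate a synthetic cohort, its PROM records and the latent ground truth."""
    variables = spec.variable_names()
    modes = mode_shapes(spec.n_modes_per_variable)
    sds = np.asarray(spec.score_sd[: spec.n_modes_per_variable], dtype=float)

    master = np.random.SeedSequence(spec.seed)
    # fixed child order: recovery, proms, reserved, then one stream per variable
    children = master.spawn(3 + spec.n_variables)
    rng_recovery = np.random.default_rng(children[0])
    rng_prom = np.random.default_rng(children[1])

    np_ids = [f"NP{i + 1:03d}" for i in range(spec.n_np)]
    oa_ids = [f"OA{i + 1:03d}" for i in range(spec.n_oa)]
    postop_ids = oa_ids[: spec.n_postop]

    # latent recovery fractions: truncated normal on recovery_bounds
    lo, hi = spec.recovery_bounds
    if spec.recovery_sd == 0:
        rho = np.full(spec.n_postop, np.clip(spec.recovery_mean, lo, hi))
    else:
        a = (lo - spec.recovery_mean) / spec.recovery_sd
        b = (hi - spec.recovery_mean) / spec.recovery_sd
        rho = stats.truncnorm.rvs(
            a, b, loc=spec.recovery_mean, scale=spec.recovery_sd,
            size=spec.n_postop, random_state=rng_recovery,
        )
    rho_series = pd.Series(rho, index=pd.Index(postop_ids, name="subject_id"), name="rho")

    disc = set(spec.discriminatory_modes)
    curves: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    score_rows: dict[tuple[str, str], dict[tuple[str, int], float]] = {}

    for v, var in enumerate(variables):
        rng_v = np.random.default_rng(children[3 + v])
        template = _template(v)
        shift = np.array(
            [spec.effect_size_d * sds[m] if (var, m + 1) in disc else 0.0
             for m in range(spec.n_modes_per_variable)]
        )
        scores_np = rng_v.normal(0.0, sds, size=(spec.n_np, spec.n_modes_per_variable))
        scores_oa = rng_v.normal(0.0, sds, size=(spec.n_oa, spec.n_modes_per_variable)) + shift
        # post-op: move fraction rho toward the NP population mean (zero for
        # centred modes; the group shift sits on the OA side only)
        scores_post = scores_oa[: spec.n_postop] * (1.0 - rho[:, None])
        noise_np = rng_v.normal(0.0, spec.noise_sd, size=(spec.n_np, N_CYCLE_SAMPLES))
        noise_oa = rng_v.normal(0.0, spec.noise_sd, size=(spec.n_oa, N_CYCLE_SAMPLES))
        noise_post = rng_v.normal(0.0, spec.noise_sd, size=(spec.n_postop, N_CYCLE_SAMPLES))

        for ids, scores, noise, visit in (
            (np_ids, scores_np, noise_np, "baseline"),
            (oa_ids, scores_oa, noise_oa, "baseline"),
            (postop_ids, scores_post, noise_post, "postop"),
        ):
            data = template[None, :] + scores @ modes + noise
            for i, sid in enumerate(ids):
                curves.setdefault((sid, visit), {})[var] = data[i]
                row = score_rows.setdefault((sid, visit), {})
                for m in range(spec.n_modes_per_variable):
                    row[(var, m + 1)] = scores[i, m]

    subjects = []
    for sid in np_ids + oa_ids:
        cohort = "NP" if sid.startswith("NP") else "OA"
        waveforms: dict[str, dict[str, GaitWaveform]] = {}
        for visit in ("baseline", "postop"):
            if (sid, visit) in curves:
                waveforms[visit] = {
                    var: GaitWaveform(sid, visit, var, samples, variable_units(var))
                    for var, samples in curves[(sid, visit)].items()
                }
        subjects.append(SubjectRecord(sid, cohort, waveforms))

    # ---- PROMs: baseline percent for all OA subjects; post-op change driven
    # by rho with analytically calibrated noise so corr(change, rho) ~ prom_r
    config = spec.pipeline_config()
    proms: list[PROMRecord] = []
    if spec.n_postop >= 2 and np.std(rho) > 0:
        z_rho = (rho - rho.mean()) / rho.std()
    else:
        z_rho = np.zeros(spec.n_postop)
    change_rows = {}
    for instrument in ("OKS", "KOS", "PACS"):
        base_pct = np.clip(
            rng_prom.normal(spec.prom_baseline_mean, spec.prom_baseline_sd, size=spec.n_oa),
            0.0, 100.0,
        )
        eps = rng_prom.normal(0.0, 1.0, size=spec.n_postop)
        change = spec.prom_change_mean + spec.prom_change_sd * (
            spec.prom_r * z_rho + np.sqrt(1.0 - spec.prom_r**2) * eps
        )
        post_pct = np.clip(base_pct[: spec.n_postop] + change, 0.0, 100.0)
        change_rows[instrument] = pd.Series(post_pct - base_pct[: spec.n_postop],
                                            index=postop_ids)
        scale = config.instruments[instrument]
        for ids, pcts, visit in ((oa_ids, base_pct, "baseline"), (postop_ids, post_pct, "postop")):
            for sid, pct in zip(ids, pcts):
                raw = round(scale.worst + pct / 100.0 * (scale.best - scale.worst))
                proms.append(
                    PROMRecord(sid, visit, instrument, float(raw),
                               percent_score(instrument, float(raw), config))
                )

    score_index = pd.MultiIndex.from_tuples(sorted(score_rows), names=["subject_id", "visit"])
    columns = pd.MultiIndex.from_tuples(
        [(var, m + 1) for var in variables for m in range(spec.n_modes_per_variable)],
        names=["variable", "mode"],
    )
    mode_scores = pd.DataFrame(
        [[score_rows[key][col] for col in columns] for key in score_index],
        index=score_index, columns=columns,
    )
    truth = GroundTruth(
        rho=rho_series,
        mode_scores=mode_scores,
        discriminatory_modes=tuple(spec.discriminatory_modes),
        prom_change_percent=pd.DataFrame(change_rows),
    )
    return subjects, proms, truth


def ground_truth_recovery(truth: GroundTruth) -> pd.DataFrame:
    """The latent per-subject recovery fractions as a table."""
    return truth.rho.reset_index()
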
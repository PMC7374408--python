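"""Split-half feature ranking and retention.

To limit over-fitting, the training cohort is split into two stratified halves
and every candidate feature is ranked within each half by its single-feature
leave-one-out classification accuracy (transfer parameters refitted on the
remaining subjects of the half for every fold).  Features highly ranked in
*both* halves are retained: the final set is the intersection of the two
top-K lists at the smallest K whose intersection reaches the target size.

Ties in accuracy are broken by the mean belief margin |B(OA) - B(NP)| over the
folds, then by registry order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .cohort_io import SubjectRecord
from .feature_reduction import FeatureId


class RankingError(Exception):
    pass


@dataclass
class RankingResult:
    """Per-half rankings, the retained intersection, and the depth K used."""

    half1: pd.DataFrame
    half2: pd.DataFrame
    retained: list[FeatureId]
    k_used: int

    def report(self) -> pd.DataFrame:
        """Flat report: feature, per-half rank and score, retained flag."""
        r1 = self.half1.set_index("feature")
        r2 = self.half2.set_index("feature")
        rows = []
        for f in r1.index:
            rows.append({
                "variable": f[0], "component": f[1],
                "half1_rank": int(r1.loc[[f], "rank"].iloc[0]),
                "half1_score": float(r1.loc[[f], "accuracy"].iloc[0]),
                "half2_rank": int(r2.loc[[f], "rank"].iloc[0]),
                "half2_score": float(r2.loc[[f], "accuracy"].iloc[0]),
                "retained": f in set(self.retained),
            })
        return pd.DataFrame(rows)


def split_halves(
    subjects: Sequence[SubjectRecord], seed: int
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Stratified half-split: NP/OA proportions preserved within one subject.

    Deterministic given the seed; the split depends on subject positions (not
    identifiers), so relabelling subjects leaves the partition unchanged.
    """
    by_cohort: dict[str, list[SubjectRecord]] = {"NP": [], "OA": []}
    for s in subjects:
        by_cohort[s.cohort].append(s)
    for cohort, members in by_cohort.items():
        if len(members) < 4:
            raise RankingError(f"need >=4 subjects per cohort to split, {cohort} has {len(members)}")
    rng = np.random.default_rng(seed)
    half1: list[SubjectRecord] = []
    half2: list[SubjectRecord] = []
    for cohort in ("NP", "OA"):
        members = by_cohort[cohort]
        order = rng.permutation(len(members))
        cut = (len(members) + 1) // 2
        half1.extend(members[i] for i in sorted(order[:cut]))
        half2.extend(members[i] for i in sorted(order[cut:]))
    return half1, half2


def _single_feature_loo(x: np.ndarray, is_oa: np.ndarray,
                        config: PipelineConfig) -> tuple[float, float]:
    """Accuracy and mean belief margin of one feature under within-half LOO.

    Uses leave-one-out group-moment identities to refit theta and k for every
    fold in closed form; the per-fold mass assignment is identical to
    ``to_boe(confidence_factor(...))`` (cross-checked against that path in the
    test suite).  Degenerate folds (no separation, no spread, or a cohort
    collapsing below two subjects) count as incorrect with zero margin.
    """
    n = len(x)
    idx_oa, idx_np = is_oa, ~is_oa
    n_oa, n_np = int(idx_oa.sum()), int(idx_np.sum())
    s_oa, ss_oa = x[idx_oa].sum(), (x[idx_oa] ** 2).sum()
    s_np, ss_np = x[idx_np].sum(), (x[idx_np] ** 2).sum()

    def loo_stats(sum_, ssq, size, own):
        """Mean/sd per fold for one group; ``own`` marks folds inside the group.

        A group reduced to one subject contributes zero spread, matching
        ``fit_transfer_params`` on a single-subject group.
        """
        m_out = size - 1  # group size when its own member is held out
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = np.where(own, (sum_ - x) / max(m_out, 1), sum_ / size)
            var_full = (ssq - size * (sum_ / size) ** 2) / max(size - 1, 1)
            var_out = (ssq - x**2 - m_out * mu**2) / max(m_out - 1, 1)
            if m_out < 2:
                var_out = np.zeros_like(var_out)
        var = np.where(own, var_out, var_full)
        return mu, np.sqrt(np.clip(var, 0.0, None))

    mu_oa, sd_oa = loo_stats(s_oa, ss_oa, n_oa, idx_oa)
    mu_np, sd_np = loo_stats(s_np, ss_np, n_np, idx_np)

    sep = mu_oa - mu_np
    spread = sd_oa + sd_np
    valid = (sep != 0) & (spread > 0) & np.isfinite(sep) & np.isfinite(spread)
    valid &= np.where(idx_oa, n_oa >= 2, True) & np.where(idx_np, n_np >= 2, True)

    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        k = np.sign(sep) * 2.0 * config.gain / spread
        theta = 0.5 * (mu_oa + mu_np)
        z = np.clip(-k * (x - theta), -700.0, 700.0)
        cf = np.clip(1.0 / (1.0 + np.exp(z)), 1e-15, 1 - 1e-15)
        a, b = config.ignorance, config.max_belief
        m_oa = np.maximum(0.0, (b / (1 - a)) * cf - a * b / (1 - a))
        m_np = np.maximum(0.0, -(b / (1 - a)) * cf + b)

    pred_oa = m_oa > m_np
    pred_np = m_np > m_oa
    correct = np.where(idx_oa, pred_oa, pred_np) & valid
    margin = np.where(valid, np.abs(m_oa - m_np), 0.0)
    return float(correct.mean()), float(margin.mean())


def rank_features(
    feature_matrix: pd.DataFrame,
    labels: Sequence[str],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Rank features of one half by single-feature LOO accuracy, descending.

    Returns a DataFrame with columns feature, accuracy, margin, rank (1 = best).
    """
    labels = np.asarray(labels)
    is_oa = labels == "OA"
    if is_oa.sum() < 2 or (~is_oa).sum() < 2:
        raise RankingError("need >=2 subjects per cohort in the half")
    rows = []
    for pos, f in enumerate(feature_matrix.columns):
        acc, margin = _single_feature_loo(
            feature_matrix[f].to_numpy(dtype=float), is_oa, config
        )
        rows.append({"feature": f, "accuracy": acc, "margin": margin, "_pos": pos})
    df = pd.DataFrame(rows)
    df = df.sort_values(["accuracy", "margin", "_pos"],
                        ascending=[False, False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="_pos").reset_index(drop=True)


def select_retained(
    ranking1: pd.DataFrame, ranking2: pd.DataFrame, target_size: int
) -> RankingResult:
    """Retain features highly ranked in both halves.

    The retained set is the intersection of the two top-K lists at the
    smallest K reaching ``target_size``; if no K suffices the full-universe
    intersection is returned with a warning.
    """
    order1 = list(ranking1["feature"])
    order2 = list(ranking2["feature"])
    universe = set(order1)
    if not universe:
        raise RankingError("empty feature universe")
    if set(order2) != universe:
        raise RankingError("rankings cover different feature universes")
    retained: list[FeatureId] = []
    k_used = len(order1)
    for k in range(max(1, target_size), len(order1) + 1):
        inter = set(order1[:k]) & set(order2[:k])
        if len(inter) >= target_size:
            retained = [f for f in order1 if f in inter]
            k_used = k
            break
    else:
        retained = [f for f in order1 if f in set(order2)]
        warnings.warn(
            f"top-K intersection never reached target size {target_size}; "
            f"returning the full intersection ({len(retained)} features)",
            stacklevel=2,
        )
    return RankingResult(half1=ranking1, half2=ranking2, retained=retained, k_used=k_used)
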
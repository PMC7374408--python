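"""Pre/post summary statistics, effect sizes, objective-subjective correlations,
and the ranked-change (arrow-plot) ordering.

Effect sizes are the mean difference divided by the pooled standard deviation
of the two visits (variance average at equal n, (n-1)-weighted otherwise).
Correlations are Pearson when both margins pass a Shapiro-Wilk normality gate,
Spearman otherwise; the method can be forced in the config.  Missing values
are never imputed — every statistic reports its own pairwise-complete n.
No multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig


class AnalysisError(Exception):
    pass


@dataclass
class ChangeSummary:
    """Baseline vs post-operative summary for one measure."""

    measure: str
    n_baseline: int
    n_postop: int
    n_pairs: int
    baseline_mean: float
    baseline_sd: float
    postop_mean: float
    postop_sd: float
    diff: float  # postop mean - baseline mean
    p_value: float
    effect_size: float
    test: str  # "t" or "wilcoxon"

    @property
    def n(self) -> int:
        return self.n_pairs


@dataclass
class CorrelationResult:
    pair: str
    timepoint: str  # baseline | postop | change
    method: str  # pearson | spearman
    r: float
    p: float
    n: int


def _pooled_sd(sd1: float, sd2: float, n1: int, n2: int) -> float:
    if n1 == n2:
        return float(np.sqrt((sd1**2 + sd2**2) / 2.0))
    return float(np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)))


def change_summary(
    measure: str,
    baseline: Sequence[float],
    postop: Sequence[float],
    config: PipelineConfig | None = None,
) -> ChangeSummary:
    """Summarise a paired measure across the two visits.

    ``baseline`` and ``postop`` are aligned per subject; missing values (NaN)
    are dropped per visit for the means/SDs and pairwise for the paired test.
    The paired test is a t-test when the paired differences pass the normality
    gate, a Wilcoxon signed-rank test otherwise.
    """
    alpha = config.normality_alpha if config is not None else 0.05
    b = np.asarray(baseline, dtype=float)
    p = np.asarray(postop, dtype=float)
    if b.shape != p.shape:
        raise AnalysisError("baseline and postop must be aligned per subject")
    bv, pv = b[~np.isnan(b)], p[~np.isnan(p)]
    pairs = ~np.isnan(b) & ~np.isnan(p)
    if pairs.sum() < 2:
        raise AnalysisError(f"{measure}: need >=2 complete pairs, got {int(pairs.sum())}")
    diffs = p[pairs] - b[pairs]
    if np.allclose(diffs, 0.0):
        p_value, test = 1.0, "t"
    else:
        normal = _is_normal(diffs, alpha)
        if normal:
            p_value = float(stats.ttest_rel(p[pairs], b[pairs]).pvalue)
            test = "t"
        else:
            p_value = float(stats.wilcoxon(p[pairs], b[pairs]).pvalue)
            test = "wilcoxon"
    baseline_mean, baseline_sd = float(bv.mean()), float(bv.std(ddof=1))
    postop_mean, postop_sd = float(pv.mean()), float(pv.std(ddof=1))
    pooled = _pooled_sd(baseline_sd, postop_sd, len(bv), len(pv))
    effect = 0.0 if pooled == 0 else (postop_mean - baseline_mean) / pooled
    return ChangeSummary(
        measure=measure,
        n_baseline=len(bv),
        n_postop=len(pv),
        n_pairs=int(pairs.sum()),
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
        postop_mean=postop_mean,
        postop_sd=postop_sd,
        diff=postop_mean - baseline_mean,
        p_value=p_value,
        effect_size=float(effect),
        test=test,
    )


def _is_normal(values: np.ndarray, alpha: float) -> bool:
    if len(values) < 3 or np.ptp(values) == 0:
        return True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(values).pvalue >= alpha


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    config: PipelineConfig | None = None,
    pair: str = "",
    timepoint: str = "",
) -> CorrelationResult:
    """Correlation on pairwise-complete cases.

    Pearson when both margins pass the Shapiro-Wilk gate at the configured
    alpha, Spearman otherwise; ``config.correlation_method`` forces either.
    """
    alpha = config.normality_alpha if config is not None else 0.05
    forced = config.correlation_method if config is not None else "auto"
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AnalysisError("x and y must be aligned")
    keep = ~np.isnan(x) & ~np.isnan(y)
    xs, ys = x[keep], y[keep]
    if len(xs) < 3:
        raise AnalysisError(f"need >=3 pairwise-complete pairs, got {len(xs)}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise AnalysisError("zero variance in a margin: correlation undefined")
    if forced == "auto":
        method = "pearson" if (_is_normal(xs, alpha) and _is_normal(ys, alpha)) else "spearman"
    else:
        method = forced
    if method == "pearson":
        r, p = stats.pearsonr(xs, ys)
    else:
        r, p = stats.spearmanr(xs, ys)
    return CorrelationResult(pair=pair, timepoint=timepoint, method=method,
                             r=float(r), p=float(p), n=int(len(xs)))


def arrow_ordering(deltas: Mapping[str, float]) -> pd.DataFrame:
    """Order subjects by decreasing functional recovery.

    Most negative change in B(OA) first (rank 1); ties broken by subject id.
    Subjects with a positive change are flagged as worsened and naturally fall
    at the tail of the ordering.
    """
    items = sorted(deltas.items(), key=lambda kv: (kv[1], kv[0]))
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(items) + 1),
            "subject_id": [k for k, _ in items],
            "delta_b_oa": [v for _, v in items],
            "worsened": [v > 0 for _, v in items],
        }
    )


def plot_arrows(
    baseline_b_oa: Mapping[str, float],
    postop_b_oa: Mapping[str, float],
    path=None,
    ax=None,
):
    """Arrow plot: baseline -> post-operative B(OA) per subject, ordered by recovery."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    deltas = {s: postop_b_oa[s] - baseline_b_oa[s] for s in postop_b_oa if s in baseline_b_oa}
    order = arrow_ordering(deltas)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    for i, sid in enumerate(order["subject_id"], start=1):
        y0, y1 = baseline_b_oa[sid], postop_b_oa[sid]
        color = "tab:red" if y1 > y0 else "tab:green"
        ax.annotate("", xy=(i, y1), xytext=(i, y0),
                    arrowprops={"arrowstyle": "->", "color": color})
    ax.set_xlim(0.5, len(order) + 0.5)
    all_vals = list(baseline_b_oa.values()) + list(postop_b_oa.values())
    pad = 0.05 * (max(all_vals) - min(all_vals) + 1e-9)
    ax.set_ylim(min(all_vals) - pad, max(all_vals) + pad)
    ax.set_xlabel("subject (decreasing recovery)")
    ax.set_ylabel("B(OA)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
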
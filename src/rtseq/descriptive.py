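"""Descriptive RT-distribution comparisons: Vincentizing and percentile
rank pooling.

Both methods compare repetition and alternation RT distributions without
committing to a parametric form.  Vincentizing averages per-participant
quantile estimates across participants; percentile rank pooling maps each
trial's RT to its mid-rank within the participant's pooled distribution
across the compared conditions, then pools the ranks across participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import UNDEFINED

#: default quantile probabilities: 5th, 10th, ..., 95th percentile
DEFAULT_PROBS = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


@dataclass
class VincentizedDistribution:
    """Group quantile curves: mean across participants of per-participant
    quantile estimates, per condition."""

    probs: np.ndarray
    mean_rt_per_prob: pd.DataFrame  # index probs, one column per condition
    n_participants: int


@dataclass
class RankHistogram:
    """Relative frequency of pooled percentile ranks per condition."""

    bin_edges: np.ndarray
    relative_frequency: pd.DataFrame  # index bin, one column per condition
    n_trials: dict[str, int]


def percentile_rank(t: float, pooled_rts: np.ndarray) -> float:
    """Mid-rank of ``t`` within ``pooled_rts``: (L + 0.5 E) / N with
    L = #{values < t}, E = #{values == t}, N = pool size."""
    pooled = np.asarray(pooled_rts, dtype=float)
    if pooled.size == 0:
        raise ValueError("empty pool")
    L = int(np.count_nonzero(pooled < t))
    E = int(np.count_nonzero(pooled == t))
    return (L + 0.5 * E) / pooled.size


def percentile_ranks(values: np.ndarray) -> np.ndarray:
    """Vectorized mid-ranks of every element within its own multiset."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="mergesort")
    sv = v[order]
    left = np.searchsorted(sv, v, side="left")
    right = np.searchsorted(sv, v, side="right")
    return (left + 0.5 * (right - left)) / v.size


def compute_ranks(
    table,
    group_by: str = "stimulus_type",
    correct_only: bool = True,
) -> pd.DataFrame:
    """Per-trial percentile ranks, computed within participant and
    ``group_by`` stratum but jointly across the sequence conditions being
    compared.  Returns the trial rows (undefined-sequence trials dropped)
    with a ``rank`` column."""
    df = table.df if hasattr(table, "df") else table
    if "sequence" not in df.columns:
        raise ValueError("sequence labels required; run code_sequence first")
    df = df[df["sequence"] != UNDEFINED]
    if correct_only:
        df = df[df["correct"]]
    out = df.copy()
    out["rank"] = np.nan
    for _, idx in out.groupby(["participant", group_by], sort=False).groups.items():
        out.loc[idx, "rank"] = percentile_ranks(out.loc[idx, "rt_ms"].to_numpy())
    return out


def pool_ranks(
    table,
    group_by: str = "stimulus_type",
    bins: int = 10,
    correct_only: bool = True,
) -> dict[str, RankHistogram]:
    """Pooled rank histograms per ``group_by`` level.

    Ranks are computed per participant across repetition + alternation
    jointly within each stratum, pooled across participants, and binned
    into ``bins`` equal-width bins of [0, 1] per sequence condition.
    """
    ranked = compute_ranks(table, group_by=group_by, correct_only=correct_only)
    edges = np.linspace(0.0, 1.0, bins + 1)
    result: dict[str, RankHistogram] = {}
    for level, sub in ranked.groupby(group_by, sort=True):
        freqs = {}
        counts = {}
        for cond, cond_df in sub.groupby("sequence", sort=True):
            if len(cond_df) == 0:
                warnings.warn(f"condition {cond!r} empty in stratum {level!r}; omitted")
                continue
            h, _ = np.histogram(cond_df["rank"], bins=edges)
            freqs[cond] = h / h.sum()
            counts[cond] = int(len(cond_df))
        result[level] = RankHistogram(
            bin_edges=edges, relative_frequency=pd.DataFrame(freqs), n_trials=counts
        )
    return result


def vincentize(
    table,
    probs=DEFAULT_PROBS,
    group_by: str = "stimulus_type",
    correct_only: bool = True,
) -> dict[str, VincentizedDistribution]:
    """Vincentized group quantiles per ``group_by`` level and sequence
    condition.

    Each participant's quantiles are estimated by linear interpolation of
    order statistics (the 'type 7' convention); the group curve is their
    mean across participants.  Participants with very few trials enter
    with their (degenerate) quantiles and trigger a warning.
    """
    probs = np.asarray(sorted(probs), dtype=float)
    df = table.df if hasattr(table, "df") else table
    if "sequence" not in df.columns:
        raise ValueError("sequence labels required; run code_sequence first")
    df = df[df["sequence"] != UNDEFINED]
    if correct_only:
        df = df[df["correct"]]
    result: dict[str, VincentizedDistribution] = {}
    for level, sub in df.groupby(group_by, sort=True):
        per_cond: dict[str, np.ndarray] = {}
        n_participants = sub["participant"].nunique()
        for cond, cond_df in sub.groupby("sequence", sort=True):
            qs = []
            for _, pdf in cond_df.groupby("participant", sort=True):
                rts = pdf["rt_ms"].to_numpy(float)
                if len(rts) < 2:
                    warnings.warn(
                        f"participant with {len(rts)} trial(s) in {level!r}/{cond!r}: "
                        "degenerate quantiles included"
                    )
                qs.append(np.quantile(rts, probs, method="linear"))
            per_cond[cond] = np.mean(qs, axis=0)
        result[level] = VincentizedDistribution(
            probs=probs,
            mean_rt_per_prob=pd.DataFrame(per_cond, index=probs),
            n_participants=n_participants,
        )
    return result


def plot_vincentized(dists: dict[str, VincentizedDistribution], path=None):
    """Quantile-by-condition panel per stimulus type (one axes each);
    saves to ``path`` if given, returns the figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(dists), figsize=(4 * len(dists), 3.2),
                             squeeze=False, sharey=True)
    for ax, (level, vd) in zip(axes[0], sorted(dists.items())):
        for cond in vd.mean_rt_per_prob:
            ax.plot(vd.probs, vd.mean_rt_per_prob[cond], "o-", ms=3, label=cond)
        ax.set_title(level)
        ax.set_xlabel("quantile")
    axes[0][0].set_ylabel("Vincentized RT (ms)")
    axes[0][0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def plot_rank_histograms(hists: dict[str, RankHistogram], path=None):
    """Pooled percentile-rank frequency bars per stimulus type."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(hists), figsize=(4 * len(hists), 3.2),
                             squeeze=False, sharey=True)
    for ax, (level, h) in zip(axes[0], sorted(hists.items())):
        centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
        width = 0.9 * np.diff(h.bin_edges).mean() / max(len(h.relative_frequency.columns), 1)
        for i, cond in enumerate(h.relative_frequency):
            ax.bar(centers + (i - 0.5) * width, h.relative_frequency[cond],
                   width=width, label=cond)
        ax.set_title(level)
        ax.set_xlabel("percentile rank")
    axes[0][0].set_ylabel("relative frequency")
    axes[0][0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
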
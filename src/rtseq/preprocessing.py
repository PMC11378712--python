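"""Trial-level data model, I/O, RT cutoffs, exclusions, and sequence coding.

The pipeline's universal currency is a tidy trial table: one row per trial
with participant, paradigm, block, within-block trial index, stimulus type,
response, correctness, and RT in milliseconds.  Four binary-choice paradigms
are supported:

``visual_search``
    pop-out search; stimulus types ``color``, ``form`` (target present,
    differing from distractors on that dimension) and ``absent``.
``two_choice``
    color-majority judgment (2CRT); types ``majority_green`` /
    ``majority_red``.
``interference``
    flanker-style congruency task; types ``congruent`` / ``incongruent``.
``task_switching``
    majority-color vs. majority-form task; types ``color_task`` /
    ``form_task``.

Trial history is coded per paradigm into repetition / alternation /
undefined labels, and the standard exclusion cascade (practice block,
warm-up trials, post-error trials, RT range) is applied with an explicit
precedence and an accounting report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

PARADIGMS = ("visual_search", "two_choice", "interference", "task_switching")

#: stimulus_type labels allowed per paradigm
STIMULUS_TYPES: dict[str, tuple[str, ...]] = {
    "visual_search": ("color", "form", "absent"),
    "two_choice": ("majority_green", "majority_red"),
    "interference": ("congruent", "incongruent"),
    "task_switching": ("color_task", "form_task"),
}

#: canonical CSV column order
COLUMNS = (
    "participant",
    "paradigm",
    "block",
    "trial",
    "stimulus_type",
    "stimulus_detail",
    "response",
    "correct",
    "rt_ms",
)

REPETITION = "repetition"
ALTERNATION = "alternation"
UNDEFINED = "undefined"


class FormatError(ValueError):
    """Malformed trial file (missing columns, unparseable values)."""


class ValidationError(ValueError):
    """Well-formed file with rows violating trial invariants."""


@dataclass
class TrialTable:
    """Ordered collection of trials plus design metadata.

    ``df`` holds one row per trial with the canonical columns; rows are
    strictly ordered by (participant, block, trial).  Block 0 is the
    practice block; experimental blocks are numbered from 1 and trial
    indices are 1-based within block.
    """

    df: pd.DataFrame
    n_blocks: int = 10
    trials_per_block: int = 122
    n_warmup_per_block: int = 2

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        if "correct" in self.df.columns:
            self.df["correct"] = self.df["correct"].astype(bool)
        key = self.df[["participant", "block", "trial"]]
        if key.duplicated().any():
            raise ValidationError("duplicate (participant, block, trial) rows")
        order = self.df.sort_values(["participant", "block", "trial"], kind="mergesort")
        if not order.index.equals(self.df.index):
            self.df = order.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def paradigm(self) -> str:
        return str(self.df["paradigm"].iloc[0])

    def copy(self) -> "TrialTable":
        return TrialTable(
            self.df.copy(),
            n_blocks=self.n_blocks,
            trials_per_block=self.trials_per_block,
            n_warmup_per_block=self.n_warmup_per_block,
        )


@dataclass
class FilterConfig:
    """Trial-exclusion settings.

    The default upper cutoff of 3000 ms flags extremely slow responses;
    the lower cutoff is paradigm-specific and is usually determined from
    the data with :func:`determine_lower_bound`.
    """

    lower_rt_ms: float
    upper_rt_ms: float = 3000.0
    exclude_practice: bool = True
    n_warmup: int = 2
    exclude_post_error: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.lower_rt_ms < self.upper_rt_ms):
            raise ValueError("require 0 < lower_rt_ms < upper_rt_ms")


@dataclass
class FilterReport:
    """Exclusive per-rule exclusion counts; rules applied in precedence
    order practice -> warm-up -> post-error -> RT range, so each trial is
    charged to the first rule that removes it."""

    n_input: int
    n_excluded_by_rule: dict[str, int] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return sum(self.n_excluded_by_rule.values())

    @property
    def n_survivors(self) -> int:
        return self.n_input - self.n_excluded

    @property
    def fraction_excluded(self) -> float:
        return self.n_excluded / self.n_input if self.n_input else 0.0

    def to_json(self) -> str:
        d = asdict(self)
        d["fraction_excluded"] = self.fraction_excluded
        d["n_survivors"] = self.n_survivors
        return json.dumps(d, indent=2)


def _validate_df(df: pd.DataFrame, paradigm: str) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    if paradigm not in PARADIGMS:
        raise ValidationError(f"unknown paradigm {paradigm!r}")
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad = df.index[rt.isna() | (rt <= 0)]
    if len(bad):
        raise ValidationError(f"missing or non-positive rt_ms in row(s) {list(bad[:5])}")
    df = df.assign(rt_ms=rt.astype(float), correct=df["correct"].astype(int).astype(bool))
    allowed = set(STIMULUS_TYPES[paradigm])
    unknown = set(df["stimulus_type"].unique()) - allowed
    if unknown:
        raise ValidationError(
            f"stimulus_type {sorted(unknown)} not valid for paradigm {paradigm!r}"
        )
    return df[list(COLUMNS) + [c for c in df.columns if c not in COLUMNS]]


def load_trials(path, paradigm: str, **design) -> TrialTable:
    """Read a comma-separated trial file (UTF-8, header row) into a
    :class:`TrialTable`, validating RTs and stimulus labels against the
    declared paradigm."""
    df = pd.read_csv(path)
    df = _validate_df(df, paradigm)
    return TrialTable(df, **design)


def write_trials(table: TrialTable, path) -> None:
    """Write the canonical CSV dialect (round-trips with :func:`load_trials`)."""
    out = table.df.copy()
    out["correct"] = out["correct"].astype(int)
    out[list(COLUMNS)].to_csv(path, index=False)


def determine_lower_bound(
    table: TrialTable, bin_width: float = 50.0, chance: float = 0.5
) -> float:
    """Adaptive fast-response cutoff from accuracy over successive RT bins.

    Pools all trials across participants into successive ``bin_width`` ms
    intervals starting at 0 ms, and computes per-bin mean accuracy plus
    cumulative accuracy (accuracy of all responses at or below the bin's
    upper edge).  Returns the lower edge of the first of two successive
    non-empty bins in which both measures exceed ``chance``; below that
    edge responses are treated as guesses.
    """
    rt = table.df["rt_ms"].to_numpy(float)
    correct = table.df["correct"].to_numpy(bool)
    if len(rt) == 0:
        raise ValueError("empty trial table")
    n_bins = int(np.ceil(rt.max() / bin_width))
    idx = np.minimum((rt / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    hits = np.bincount(idx, weights=correct.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = hits / counts
        cum_acc = np.cumsum(hits) / np.cumsum(counts)
    # empty bins are uninformative: the pair criterion runs over the
    # sequence of occupied bins
    occupied = np.flatnonzero(counts > 0)
    ok = (acc[occupied] > chance) & (cum_acc[occupied] > chance)
    for j, b in enumerate(occupied):
        if ok[j] and (j + 1 == len(occupied) or ok[j + 1]):
            return b * bin_width
    raise ValueError("no-bound-found: no two successive bins exceed chance in both measures")


def filter_trials(table: TrialTable, config: FilterConfig) -> tuple[TrialTable, FilterReport]:
    """Apply the exclusion cascade and account for every removed trial.

    Precedence: practice block, then the first ``n_warmup`` trials of every
    block, then post-error trials (a trial immediately following an error
    within the same block, judged on the sequence after practice/warm-up
    removal but before RT-range removal), then out-of-range RTs.  A trial
    is charged to the first rule that removes it, so the per-rule counts
    plus survivors always sum to the input count.
    """
    df = table.df
    n_input = len(df)
    report = FilterReport(n_input=n_input)

    keep = pd.Series(True, index=df.index)
    if config.exclude_practice:
        practice = df["block"] == 0
        report.n_excluded_by_rule["practice"] = int(practice.sum())
        keep &= ~practice
    warm = keep & (df["trial"] <= config.n_warmup)
    report.n_excluded_by_rule["warmup"] = int(warm.sum())
    keep &= ~warm

    if config.exclude_post_error:
        # the predecessor is the trial with index n-1 in the same
        # participant x block among rows surviving the previous rules, so
        # adjacency follows the design, not the surviving row order; an
        # error that is later RT-excluded still poisons its successor
        # (the error happened regardless of the RT filter)
        sub = df[keep]
        error_keys = set(
            map(
                tuple,
                sub.loc[~sub["correct"], ["participant", "block", "trial"]].itertuples(
                    index=False
                ),
            )
        )
        post_err = pd.Series(False, index=df.index)
        post_err.loc[sub.index] = [
            (p, b, t - 1) in error_keys
            for p, b, t in sub[["participant", "block", "trial"]].itertuples(index=False)
        ]
        report.n_excluded_by_rule["post_error"] = int((keep & post_err).sum())
        keep &= ~post_err

    out_of_range = keep & (
        (df["rt_ms"] < config.lower_rt_ms) | (df["rt_ms"] > config.upper_rt_ms)
    )
    report.n_excluded_by_rule["rt_range"] = int(out_of_range.sum())
    keep &= ~out_of_range

    filtered = TrialTable(
        df[keep].reset_index(drop=True),
        n_blocks=table.n_blocks,
        trials_per_block=table.trials_per_block,
        n_warmup_per_block=table.n_warmup_per_block,
    )
    assert report.n_survivors == len(filtered)
    return filtered, report


def exclude_participants(table: TrialTable) -> tuple[TrialTable, dict[str, list]]:
    """Drop non-compliant participants.

    Three rules, applied in order: (1) proportion correct below .70;
    (2) arcsine-square-root-transformed error rate (2*arcsin(sqrt(p)))
    more than 3 SD from the sample mean of transformed error rates;
    (3) mean log RT more than 3 SD from the sample mean log RT.  The
    SD-based rules are computed on the sample remaining after rule (1)
    and are skipped (with a warning) when only one participant remains.
    """
    df = table.df
    report: dict[str, list] = {"accuracy": [], "error_rate_3sd": [], "log_rt_3sd": []}

    pc = df.groupby("participant")["correct"].mean()
    report["accuracy"] = sorted(pc.index[pc < 0.70].tolist())
    kept = pc.index.difference(report["accuracy"])

    if len(kept) < 2:
        warnings.warn("fewer than 2 participants remain; SD-based rules skipped")
    else:
        err = 1.0 - pc.loc[kept]
        z = 2.0 * np.arcsin(np.sqrt(err))
        sd = z.std(ddof=1)
        if sd > 0:
            dev = (z - z.mean()).abs()
            report["error_rate_3sd"] = sorted(dev.index[dev > 3 * sd].tolist())
            kept = kept.difference(report["error_rate_3sd"])
        # 3-SD rule on mean log RT of the surviving sample
        logmean = df[df["participant"].isin(kept)].copy()
        logmean["lrt"] = np.log(logmean["rt_ms"])
        logrt = logmean.groupby("participant")["lrt"].mean()
        sd = logrt.std(ddof=1)
        if len(kept) >= 2 and sd > 0:
            dev = (logrt - logrt.mean()).abs()
            report["log_rt_3sd"] = sorted(dev.index[dev > 3 * sd].tolist())
            kept = kept.difference(report["log_rt_3sd"])

    out = TrialTable(
        df[df["participant"].isin(kept)].reset_index(drop=True),
        n_blocks=table.n_blocks,
        trials_per_block=table.trials_per_block,
        n_warmup_per_block=table.n_warmup_per_block,
    )
    return out, report


def _pair_label(paradigm: str, prev: pd.Series, cur: pd.Series) -> str:
    """Sequence label of ``cur`` given its true predecessor ``prev``."""
    if paradigm == "visual_search":
        if prev["stimulus_type"] == "absent" or cur["stimulus_type"] == "absent":
            return UNDEFINED
        return REPETITION if prev["stimulus_type"] == cur["stimulus_type"] else ALTERNATION
    if paradigm == "two_choice":
        # stimulus category and response are yoked; S-R repetition
        return REPETITION if prev["stimulus_type"] == cur["stimulus_type"] else ALTERNATION
    if paradigm in ("interference", "task_switching"):
        return REPETITION if prev["stimulus_type"] == cur["stimulus_type"] else ALTERNATION
    raise ValueError(f"unknown paradigm {paradigm!r}")


def code_sequence(table: TrialTable, neighbor: str = "design") -> TrialTable:
    """Attach a ``sequence`` column (repetition / alternation / undefined).

    Labels are paradigm-specific: visual search compares the target
    dimension and is undefined unless both trials are target-present;
    two-choice compares the stimulus-response category; interference
    compares congruency status; task switching compares the task.  The
    first trial of each block is always undefined.

    ``neighbor='design'`` (default) uses each trial's true within-block
    predecessor by trial index, so a predecessor later removed by the RT
    filter still defines its successor's history; ``neighbor='surviving'``
    instead uses the immediately preceding row present in the table.
    """
    if neighbor not in ("design", "surviving"):
        raise ValueError("neighbor must be 'design' or 'surviving'")
    paradigm = table.paradigm
    if paradigm not in PARADIGMS:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    df = table.df
    labels = np.full(len(df), UNDEFINED, dtype=object)

    part = df["participant"].to_numpy()
    block = df["block"].to_numpy()
    trial = df["trial"].to_numpy()
    same_block = np.zeros(len(df), dtype=bool)
    same_block[1:] = (part[1:] == part[:-1]) & (block[1:] == block[:-1])
    if neighbor == "design":
        same_block[1:] &= trial[1:] == trial[:-1] + 1

    rows = df.to_dict("records")
    for i in np.flatnonzero(same_block):
        labels[i] = _pair_label(paradigm, rows[i - 1], rows[i])

    out = table.copy()
    out.df["sequence"] = labels
    return out
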
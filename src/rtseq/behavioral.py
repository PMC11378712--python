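"""Condition summaries and inferential statistics for sequential effects.

The standard first-pass analysis: per participant x stimulus type x
sequence cell, mean correct RT and proportion correct; a 2 x 2
within-subject ANOVA (stimulus type x sequence) on the cell means; and
paired repetition-vs-alternation effects with d_z and confidence
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .preprocessing import UNDEFINED


@dataclass
class AnovaResult:
    """Per-effect F(df1, df2), p, and partial eta squared for the three
    effects of a 2 x 2 within design (both factors 1 df, so no sphericity
    correction arises)."""

    table: pd.DataFrame  # index: effect; columns F, df1, df2, p, eta_p2
    n_participants: int


@dataclass
class PairedEffect:
    """Paired comparison (alternation - repetition by convention):
    mean difference with 95% CI, t, df, p, and d_z = mean/sd with a
    noncentral-t CI."""

    delta: float
    ci95: tuple[float, float]
    t: float
    df: int
    p: float
    dz: float
    dz_ci95: tuple[float, float]
    n: int


def summarize_cells(table) -> pd.DataFrame:
    """One row per participant x stimulus_type x sequence cell with mean
    correct RT (ms), proportion correct over all trials, and trial count.
    Undefined-sequence trials are excluded; empty cells are omitted with
    a warning; cells with no correct trial carry NaN mean RT."""
    df = table.df if hasattr(table, "df") else table
    if "sequence" not in df.columns:
        raise ValueError("sequence labels required; run code_sequence first")
    df = df[df["sequence"] != UNDEFINED]
    if df.empty:
        warnings.warn("no defined-sequence trials; empty summary")
        return pd.DataFrame(
            columns=["participant", "stimulus_type", "sequence", "mean_rt", "pc", "n_trials"]
        )
    out = (
        df.groupby(["participant", "stimulus_type", "sequence"], sort=True)
        .apply(
            lambda g: pd.Series(
                {
                    "mean_rt": g.loc[g["correct"], "rt_ms"].mean(),
                    "pc": g["correct"].mean(),
                    "n_trials": len(g),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    out["n_trials"] = out["n_trials"].astype(int)
    return out


def anova_2x2_within(cells: pd.DataFrame, dv: str = "mean_rt",
                     factors=("stimulus_type", "sequence")) -> AnovaResult:
    """Repeated-measures ANOVA for a 2 x 2 within design.

    Uses the per-participant cell means; participants missing any of the
    four cells are dropped listwise with a warning.  For each 1-df effect
    F equals the square of the paired t on the corresponding contrast.
    """
    fa, fb = factors
    wide = cells.pivot_table(index="participant", columns=[fa, fb], values=dv)
    complete = wide.dropna()
    if len(complete) < len(wide):
        warnings.warn(f"{len(wide) - len(complete)} participant(s) dropped (incomplete cells)")
    n = len(complete)
    if n < 3:
        raise ValueError("need at least 3 complete participants")
    a_levels = sorted({c[0] for c in complete.columns})
    b_levels = sorted({c[1] for c in complete.columns})
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ValueError("both factors must have exactly 2 levels")
    y = np.stack(
        [[complete[(ai, bi)].to_numpy() for bi in b_levels] for ai in a_levels]
    )  # (2, 2, n)

    def effect(contrast: np.ndarray) -> tuple[float, float, float]:
        # per-participant contrast score; F = t^2 with df2 = n - 1
        score = np.tensordot(contrast, y, axes=([0, 1], [0, 1])) / 2.0
        m, sd = score.mean(), score.std(ddof=1)
        if sd == 0:
            return np.nan, np.nan, np.nan  # degenerate: zero error variance
        t = m / (sd / np.sqrt(n))
        F = t * t
        p = 2 * stats.t.sf(abs(t), n - 1)
        return F, p, F / (F + (n - 1))

    c_a = np.array([[1.0, 1.0], [-1.0, -1.0]])
    c_b = np.array([[1.0, -1.0], [1.0, -1.0]])
    c_ab = np.array([[1.0, -1.0], [-1.0, 1.0]])
    rows = {}
    for name, c in ((fa, c_a), (fb, c_b), ("interaction", c_ab)):
        F, p, eta = effect(c)
        rows[name] = {"F": F, "df1": 1, "df2": n - 1, "p": p, "eta_p2": eta}
    return AnovaResult(table=pd.DataFrame(rows).T, n_participants=n)


def _dz_ci(dz: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """CI for d_z by inverting the noncentral-t distribution of
    t = dz * sqrt(n)."""
    t_obs = dz * np.sqrt(n)
    df = n - 1
    alpha = 1 - level

    def lo_eq(nc):
        return stats.nct.sf(t_obs, df, nc) - alpha / 2

    def hi_eq(nc):
        return stats.nct.cdf(t_obs, df, nc) - alpha / 2

    span = abs(t_obs) + 10 + 5 * np.sqrt(df)
    try:
        nc_lo = optimize.brentq(lo_eq, t_obs - span, t_obs + span)
    except ValueError:
        nc_lo = t_obs - span
    try:
        nc_hi = optimize.brentq(hi_eq, t_obs - span, t_obs + span)
    except ValueError:
        nc_hi = t_obs + span
    return nc_lo / np.sqrt(n), nc_hi / np.sqrt(n)


def paired_effect(differences) -> PairedEffect:
    """Paired-difference inference from per-participant difference scores:
    t, p, 95% CI for the mean via central t, d_z with noncentral-t CI."""
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences (degenerate)")
    m = d.mean()
    se = sd / np.sqrt(n)
    t = m / se
    df = n - 1
    p = 2 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    dz = m / sd
    return PairedEffect(
        delta=m,
        ci95=(m - tcrit * se, m + tcrit * se),
        t=t,
        df=df,
        p=p,
        dz=dz,
        dz_ci95=_dz_ci(dz, n),
        n=n,
    )


def sequential_effect_table(cells: pd.DataFrame, dv: str = "mean_rt") -> pd.DataFrame:
    """Summary in the familiar per-stimulus-type layout: alternation and
    repetition means, their difference (alternation - repetition), the
    95% CI of the difference, and d_z."""
    rows = []
    for st, sub in cells.groupby("stimulus_type", sort=True):
        wide = sub.pivot_table(index="participant", columns="sequence", values=dv).dropna()
        if {"repetition", "alternation"} - set(wide.columns):
            continue
        eff = paired_effect(wide["alternation"] - wide["repetition"])
        rows.append(
            {
                "stimulus_type": st,
                "M_A": wide["alternation"].mean(),
                "M_R": wide["repetition"].mean(),
                "delta": eff.delta,
                "ci_low": eff.ci95[0],
                "ci_high": eff.ci95[1],
                "t": eff.t,
                "df": eff.df,
                "p": eff.p,
                "dz": eff.dz,
                "n": eff.n,
            }
        )
    return pd.DataFrame(rows)
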
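"""Simulation-based goodness of fit on pooled percentile ranks.

A fitted model (ex-Gaussian, EZ, four- or seven-parameter diffusion) is
evaluated by generating model-predicted RTs per participant and condition
from the fitted parameters, transforming both observed and predicted data
to percentile ranks exactly as in :mod:`rtseq.descriptive`, and comparing
the rank distributions with (i) a combined Pearson chi-square over
rank bins x sequence conditions (50 bins x 2 conditions -> df = 99 by
default) and (ii) per-condition two-sample Kolmogorov-Smirnov tests.
Neither test penalizes parameter count; they measure fit only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .descriptive import compute_ranks
from .diffusion import DiffusionParams7, simulate_diffusion
from .exgaussian import ExGaussParams, sample_exgauss
from .preprocessing import UNDEFINED

_DIFFUSION_MODELS = ("ez", "diff4", "diff7")
MODELS = ("exgauss",) + _DIFFUSION_MODELS


@dataclass
class GofResult:
    chi2: float
    chi2_df: int
    chi2_p: float
    ks_D: dict[str, float] = field(default_factory=dict)
    ks_p: dict[str, float] = field(default_factory=dict)
    n_obs: dict[str, int] = field(default_factory=dict)
    n_pred: dict[str, int] = field(default_factory=dict)


def _cell_params(row: pd.Series, model: str):
    if model == "exgauss":
        return ExGaussParams(row["mu"], row["sigma"], row["tau"])
    if model in ("ez", "diff4"):
        return DiffusionParams7(row["a"], row["v"], row["t0"], row["w"])
    return DiffusionParams7(
        row["a"], row["v"], row["t0"], row["w"],
        row["sigma_v"], row["sigma_w"], row["sigma_t0"],
    )


def predict_dataset(
    observed,
    fits: pd.DataFrame,
    model: str,
    multiplier: int = 10,
    seed=None,
    dt: float = 0.001,
) -> pd.DataFrame:
    """Model-predicted trials mirroring the observed cell structure.

    For every participant x stimulus_type x sequence cell of the observed
    (coded, filtered) data, draws ``multiplier`` times the observed trial
    count from the fitted model: ex-Gaussian samples are correct-RT draws;
    diffusion-family samples carry simulated correctness.  Returns a tidy
    frame tagged ``predicted=True``, deterministic under ``seed``.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    df = observed.df if hasattr(observed, "df") else observed
    df = df[df["sequence"] != UNDEFINED]
    key_cols = ["participant", "stimulus_type", "sequence"]
    fit_idx = fits.set_index(key_cols)
    rng = np.random.default_rng(seed)
    out = []
    for keys, cell in df.groupby(key_cols, sort=True):
        if model == "exgauss":
            n_obs = int(cell["correct"].sum())
        else:
            n_obs = len(cell)
        if n_obs == 0:
            continue
        try:
            row = fit_idx.loc[keys]
        except KeyError:
            raise KeyError(f"missing fit for cell {keys}") from None
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        params = _cell_params(row, model)
        n = multiplier * n_obs
        sub_seed = int(rng.integers(2**31))
        if model == "exgauss":
            rt_ms = sample_exgauss(params, n, seed=sub_seed)
            correct = np.ones(n, dtype=bool)
        else:
            sim = simulate_diffusion(params, n, seed=sub_seed, dt=dt)
            rt_ms = sim.rt * 1000.0
            correct = sim.upper
        part, st, seq = keys
        out.append(
            pd.DataFrame(
                {
                    "participant": part,
                    "stimulus_type": st,
                    "sequence": seq,
                    "correct": correct,
                    "rt_ms": rt_ms,
                    "predicted": True,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def _merge_zero_expected(obs: np.ndarray, exp: np.ndarray):
    """Merge bins with zero expected count into their neighbor."""
    obs, exp = list(obs), list(exp)
    i = 0
    merged = False
    while i < len(exp):
        if exp[i] == 0 and len(exp) > 1:
            j = i + 1 if i + 1 < len(exp) else i - 1
            exp[j] += exp[i]
            obs[j] += obs[i]
            del exp[i], obs[i]
            merged = True
        else:
            i += 1
    return np.array(obs), np.array(exp), merged


def chi2_percentile_test(
    observed,
    predicted,
    bins_per_condition: int = 50,
    group_by: str = "stimulus_type",
    correct_only: bool = True,
) -> dict[str, GofResult]:
    """Combined chi-square plus per-condition KS tests per stratum.

    Percentile ranks are computed per participant across the sequence
    conditions jointly (separately within observed and predicted data).
    Observed ranks are binned into ``bins_per_condition`` equal-width bins
    per condition; expected counts come from the predicted rank histogram
    rescaled to the observed total per condition, giving
    2 x bins_per_condition cells and df = cells - 1 (99 by default).
    Zero-expected cells are merged with a neighbor (df reduced, warned).
    """
    obs_ranked = compute_ranks(observed, group_by=group_by, correct_only=correct_only)
    pred_ranked = compute_ranks(predicted, group_by=group_by, correct_only=correct_only)
    edges = np.linspace(0.0, 1.0, bins_per_condition + 1)
    results: dict[str, GofResult] = {}
    for level, obs_sub in obs_ranked.groupby(group_by, sort=True):
        pred_sub = pred_ranked[pred_ranked[group_by] == level]
        obs_counts, exp_counts = [], []
        ks_D, ks_p, n_obs, n_pred = {}, {}, {}, {}
        for cond in sorted(obs_sub["sequence"].unique()):
            o = obs_sub.loc[obs_sub["sequence"] == cond, "rank"].to_numpy()
            p = pred_sub.loc[pred_sub["sequence"] == cond, "rank"].to_numpy()
            if len(o) == 0 or len(p) == 0:
                warnings.warn(f"condition {cond!r} empty in stratum {level!r}; omitted")
                continue
            ho, _ = np.histogram(o, bins=edges)
            hp, _ = np.histogram(p, bins=edges)
            obs_counts.append(ho)
            exp_counts.append(hp / hp.sum() * ho.sum())  # rescaled per condition
            D, pval = stats.ks_2samp(o, p, method="asymp")
            ks_D[cond], ks_p[cond] = float(D), float(pval)
            n_obs[cond], n_pred[cond] = int(len(o)), int(len(p))
        obs_all = np.concatenate(obs_counts)
        exp_all = np.concatenate(exp_counts)
        obs_all, exp_all, merged = _merge_zero_expected(obs_all, exp_all)
        if merged:
            warnings.warn(f"zero-expected cells merged in stratum {level!r}; df reduced")
        df_chi = len(exp_all) - 1
        chi2 = float(np.sum((obs_all - exp_all) ** 2 / exp_all))
        results[level] = GofResult(
            chi2=chi2,
            chi2_df=df_chi,
            chi2_p=float(stats.chi2.sf(chi2, df_chi)),
            ks_D=ks_D,
            ks_p=ks_p,
            n_obs=n_obs,
            n_pred=n_pred,
        )
    return results


def ks_percentile_test(observed_ranks, predicted_ranks) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p for one condition's rank
    samples (effective n = n1 n2 / (n1 + n2))."""
    o = np.asarray(observed_ranks, dtype=float)
    p = np.asarray(predicted_ranks, dtype=float)
    if len(o) == 0 or len(p) == 0:
        raise ValueError("both samples must be non-empty")
    D, pval = stats.ks_2samp(o, p, method="asymp")
    return float(D), float(pval)
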
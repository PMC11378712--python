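"""EZ-style diffusion estimation by moment matching.

The biased EZ approach summarizes a cell of trials by four moments —
proportion correct, mean and variance of correct RTs, and mean error RT —
and recovers the four main diffusion parameters (a, v, t0, w) from them.
The forward mapping uses the constant-parameter Wiener process with
diffusion coefficient s = 1 (matching :mod:`rtseq.diffusion`, so EZ output
can seed full diffusion fits directly): absorption probabilities in closed
form and conditional decision-time moments by term-wise integration of the
first-passage series.  Inversion minimizes a scale-free sum of squared
relative moment differences by Nelder-Mead with restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .diffusion import BoundaryData, DiffusionParams4, defective_moments, upper_probability
from .exgaussian import FitResult


@dataclass(frozen=True)
class EZMoments:
    """Cell moments in seconds: proportion correct, mean / variance of
    correct RTs, and (optionally) mean error RT."""

    pc: float
    mrt: float
    vrt: float
    mrt_err: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.pc < 1):
            raise ValueError("pc must lie strictly in (0, 1); apply the edge correction")
        if not (self.vrt > 0):
            raise ValueError("vrt must be positive")


def edge_correct(pc: float, n: int) -> float:
    """Replace boundary accuracies by 1/(2n) or 1 - 1/(2n)."""
    if pc <= 0.0:
        return 1.0 / (2 * n)
    if pc >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return pc


def observed_moments(cell) -> EZMoments:
    """Moments of one participant x condition cell.

    Accepts a trial DataFrame with ``rt_ms`` and ``correct`` columns (RTs
    converted to seconds) or a :class:`~rtseq.diffusion.BoundaryData`.
    The correct-RT variance uses the n-1 denominator; accuracy at 0 or 1
    is edge-corrected.
    """
    if isinstance(cell, BoundaryData):
        rt, correct = cell.rt, cell.upper
    else:
        df = cell.df if hasattr(cell, "df") else cell
        rt = df["rt_ms"].to_numpy(float) / 1000.0
        correct = df["correct"].to_numpy(bool)
    n = len(rt)
    n_corr = int(correct.sum())
    if n_corr < 2:
        raise ValueError("need at least 2 correct trials for moment estimation")
    pc = edge_correct(n_corr / n, n)
    crt = rt[correct]
    mrt_err = float(np.mean(rt[~correct])) if (~correct).any() else None
    return EZMoments(
        pc=pc, mrt=float(np.mean(crt)), vrt=float(np.var(crt, ddof=1)), mrt_err=mrt_err
    )


def ez_forward(params: DiffusionParams4, n_terms: int = 20000) -> EZMoments:
    """Predicted moments of the constant-parameter biased diffusion."""
    m = defective_moments(params, n_terms=n_terms)
    pc = m["p_upper"]
    if not (0 < pc < 1):
        raise ValueError("degenerate accuracy under these parameters")
    mrt_err = params.t0 + m["mean_lower"] if m["p_lower"] > 1e-12 else None
    return EZMoments(
        pc=pc,
        mrt=params.t0 + m["mean_upper"],
        vrt=m["var_upper"],
        mrt_err=mrt_err,
    )


def ez_point_estimate(moments: EZMoments) -> DiffusionParams4:
    """Closed-form unbiased (w = 0.5) EZ solution on the s = 1 scale;
    used as the starting value for the full moment fit."""
    pc, mrt, vrt = moments.pc, moments.mrt, moments.vrt
    L = logit(pc)
    x = L * (L * pc**2 - L * pc + pc - 0.5) / vrt
    v = float(np.sign(pc - 0.5) * abs(x) ** 0.25)
    if abs(v) < 1e-6:
        v = 1e-6
    a = float(L / v) if v != 0 else 1.0
    a = float(np.clip(abs(a), 0.2, 5.0))
    v = float(np.clip(v, -8.0, 8.0))
    y = -v * a
    mdt = (a / (2.0 * v)) * (1.0 - np.exp(y)) / (1.0 + np.exp(y))
    t0 = max(mrt - mdt, 1e-3)
    return DiffusionParams4(a, v, t0, 0.5)


def _sse(pred: EZMoments, obs: EZMoments, use_err: bool) -> float:
    # each residual standardized by the observed moment's magnitude
    terms = [
        (pred.pc - obs.pc) / obs.pc,
        (pred.mrt - obs.mrt) / obs.mrt,
        (pred.vrt - obs.vrt) / obs.vrt,
    ]
    if use_err:
        pe = pred.mrt_err if pred.mrt_err is not None else pred.mrt * 2.0
        terms.append((pe - obs.mrt_err) / obs.mrt_err)
    return float(sum(r * r for r in terms))


def fit_ez(moments: EZMoments, n_restarts: int = 50, seed=None, n_terms: int = 4000) -> FitResult:
    """Recover (a, v, t0, w) from observed moments by Nelder-Mead
    minimization of the standardized SSE, best of ``n_restarts`` starts.

    Without an error-RT moment the starting-point bias is not
    identifiable; w is then fixed at 0.5 (with a warning) and only
    (a, v, t0) are estimated.  Restarts stop early once the SSE falls
    below 1e-13 (an exact moment match up to numerical noise).
    ``objective`` on the returned result is the negated SSE, so larger
    remains better.
    """
    use_err = moments.mrt_err is not None
    if not use_err:
        warnings.warn("mrt_err absent: w fixed at 0.5 (bias not identifiable)")
    rng = np.random.default_rng(seed)
    start = ez_point_estimate(moments)
    t_cap = moments.mrt  # non-decision time cannot exceed the mean RT

    def unpack(theta: np.ndarray) -> DiffusionParams4:
        a = float(np.exp(theta[0]))
        v = float(theta[1])
        t0 = float(t_cap * expit(theta[2]))
        w = float(expit(theta[3])) if use_err else 0.5
        return DiffusionParams4(a, v, t0, w)

    def objective(theta: np.ndarray) -> float:
        try:
            pred = ez_forward(unpack(theta), n_terms=n_terms)
        except (ValueError, FloatingPointError, OverflowError):
            return 1e12
        return _sse(pred, moments, use_err)

    theta_start = np.array(
        [
            np.log(start.a),
            start.v,
            logit(np.clip(start.t0 / t_cap, 1e-4, 1 - 1e-4)),
            0.0,
        ]
    )
    n_free = 4 if use_err else 3
    best = None
    objectives = []
    for k in range(n_restarts):
        theta0 = theta_start.copy()
        if k > 0:
            theta0[:3] = theta0[:3] * rng.uniform(0.9, 1.1, 3)
            theta0[3] += rng.uniform(-0.4, 0.4)
        res = optimize.minimize(
            objective,
            theta0[:n_free] if not use_err else theta0,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 3000},
        )
        # one polish pass from the optimum tightens the simplex
        res = optimize.minimize(
            objective, res.x, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 3000},
        )
        objectives.append(res.fun)
        if best is None or res.fun < best[0]:
            best = (res.fun, res, k)
        if res.fun < 1e-13:
            break
    objectives = np.asarray(objectives)
    sse, res, k_best = best
    theta = np.concatenate([res.x, [0.0]]) if not use_err else res.x
    stable = len(objectives) < 2 or bool(
        np.isclose(np.min(objectives[:-1]), np.min(objectives), atol=1e-12)
    )
    return FitResult(
        params=unpack(theta),
        objective=-sse,
        n_restarts=n_restarts,
        best_restart_index=k_best,
        converged=bool(res.success),
        seed=seed,
        stable_without_last=stable,
        restart_objectives=objectives,
    )


def fit_ez_cells(
    table, n_restarts: int = 50, seed=None, by=("participant", "stimulus_type", "sequence")
) -> pd.DataFrame:
    """EZ fit per grouping cell of a coded trial table; returns a tidy
    frame of parameter estimates (one row per cell)."""
    from .preprocessing import UNDEFINED

    df = table.df if hasattr(table, "df") else table
    if "sequence" in by:
        df = df[df["sequence"] != UNDEFINED]
    rows = []
    rng = np.random.default_rng(seed)
    for keys, cell in df.groupby(list(by), sort=True):
        try:
            mom = observed_moments(cell)
        except ValueError:
            continue
        fit = fit_ez(mom, n_restarts=n_restarts, seed=int(rng.integers(2**31)))
        rec = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        p = fit.params
        rec.update(a=p.a, v=p.v, t0=p.t0, w=p.w, sse=-fit.objective, n_trials=len(cell))
        rows.append(rec)
    return pd.DataFrame(rows)
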
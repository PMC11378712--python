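"""Two-boundary Wiener diffusion: first-passage densities, likelihoods,
maximum-likelihood fitting, exact-path simulation, and a Fisher-information
parameter-correlation diagnostic.

Model
-----
Evidence X(t) starts at a*w (w in (0,1), relative to the lower boundary),
drifts at rate v toward the upper boundary, and diffuses with coefficient
s = 1 (all parameter magnitudes are on this scale).  Absorption at the
upper boundary (separation a) is coded as the *correct* response; the
lower boundary is the error.  RTs are decision time plus a non-decision
time t0 (all times in seconds).

The four-parameter model uses (a, v, t0, w).  The seven-parameter model
adds across-trial variability: drift normal with SD sigma_v, starting
point uniform with range sigma_w, non-decision time uniform with range
sigma_t0.  The normal drift mixture is integrated in closed form; the two
uniform mixtures by fixed-node Gauss-Legendre quadrature.

Density representation
----------------------
The standardized (a=1, v=0) lower-boundary density f(tau; w) is evaluated
by the small-time expansion for tau < 0.2 and the large-time expansion
otherwise, with enough terms for truncation error below 1e-7.  The general
lower-boundary defective density is

    f_lower(t; a, v, w) = a^{-2} exp(-v a w - v^2 t / 2) f(t / a^2; w)

and the upper-boundary density follows by the reflection (v, w) ->
(-v, 1-w).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

_K_SMALL = 7   # small-time terms k = -K..K; error < 1e-14 for tau < 0.2
_K_LARGE = 25  # large-time terms; error < 1e-12 for tau >= 0.2
_TAU_SWITCH = 0.2
_DENSITY_FLOOR = 1e-10
_MOMENT_TERMS = 20000


@dataclass(frozen=True)
class DiffusionParams4:
    """Boundary separation a, drift v (toward the correct boundary),
    non-decision time t0 (s), relative starting point w."""

    a: float
    v: float
    t0: float
    w: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError("a must be positive")
        if not (self.t0 >= 0):
            raise ValueError("t0 must be non-negative")
        if not (0 < self.w < 1):
            raise ValueError("w must be in (0, 1)")


@dataclass(frozen=True)
class DiffusionParams7:
    """Four-parameter set plus across-trial variability: sigma_v (SD of
    normal drift), sigma_w (range of uniform start), sigma_t0 (range of
    uniform non-decision time)."""

    a: float
    v: float
    t0: float
    w: float
    sigma_v: float = 0.0
    sigma_w: float = 0.0
    sigma_t0: float = 0.0

    def __post_init__(self) -> None:
        DiffusionParams4(self.a, self.v, self.t0, self.w)
        if self.sigma_v < 0 or self.sigma_w < 0 or self.sigma_t0 < 0:
            raise ValueError("variability parameters must be non-negative")
        if not (0 < self.w - self.sigma_w / 2 and self.w + self.sigma_w / 2 < 1):
            raise ValueError("w +- sigma_w/2 must stay inside (0, 1)")
        if self.t0 - self.sigma_t0 / 2 < 0:
            raise ValueError("t0 - sigma_t0/2 must be non-negative")

    @property
    def main(self) -> DiffusionParams4:
        return DiffusionParams4(self.a, self.v, self.t0, self.w)


@dataclass
class BoundaryData:
    """Multiset of first-passage outcomes: RT in seconds and a flag for
    the upper (correct) boundary."""

    rt: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.upper = np.asarray(self.upper, dtype=bool)
        if self.rt.shape != self.upper.shape:
            raise ValueError("rt and upper must have equal length")
        if np.any(self.rt <= 0):
            raise ValueError("all RTs must be positive")

    def __len__(self) -> int:
        return len(self.rt)


def _f_std(tau: np.ndarray, w) -> np.ndarray:
    """Standardized (a=1, v=0) lower-boundary FPT density; broadcasts
    over tau and w."""
    tau = np.asarray(tau, dtype=float)
    w = np.asarray(w, dtype=float)
    tau, w = np.broadcast_arrays(tau, w)
    out = np.zeros(tau.shape)
    pos = tau > 0
    if not pos.any():
        return out
    tp, wp = tau[pos], w[pos]
    small = tp < _TAU_SWITCH
    res = np.empty(tp.shape)
    if small.any():
        ts, ws = tp[small][:, None], wp[small][:, None]
        k = np.arange(-_K_SMALL, _K_SMALL + 1)[None, :]
        z = ws + 2.0 * k
        res[small] = np.sum(
            z * np.exp(-(z**2) / (2.0 * ts)), axis=1
        ) / np.sqrt(2.0 * np.pi * ts[:, 0] ** 3)
    if (~small).any():
        tl, wl = tp[~small][:, None], wp[~small][:, None]
        k = np.arange(1, _K_LARGE + 1)[None, :]
        res[~small] = np.pi * np.sum(
            k * np.exp(-(k**2) * np.pi**2 * tl / 2.0) * np.sin(k * np.pi * wl),
            axis=1,
        )
    out[pos] = np.maximum(res, 0.0)
    return out


def _lower_density_core(td, a, v, w, sigma_v=0.0):
    """Lower-boundary defective density at decision time td, with the
    normal across-trial drift mixture integrated analytically:

        f(td) = a^-2 f(td/a^2; w) (1+sigma_v^2 td)^{-1/2}
                * exp((a^2 w^2 sigma_v^2 - 2 a w v - v^2 td) / (2 (1+sigma_v^2 td)))

    which reduces to the fixed-drift kernel at sigma_v = 0.
    """
    td = np.asarray(td, dtype=float)
    base = _f_std(td / a**2, w) / a**2
    s2t = 1.0 + sigma_v**2 * td
    expo = (a**2 * np.asarray(w) ** 2 * sigma_v**2 - 2.0 * a * np.asarray(w) * v - v**2 * td) / (
        2.0 * s2t
    )
    return base * np.exp(expo) / np.sqrt(s2t)


def wiener_fpt_density(t, boundary: str, params: DiffusionParams4) -> np.ndarray:
    """Defective first-passage density (per second) at full RT ``t`` for
    the named boundary ('upper' = correct, 'lower' = error); zero for
    t <= t0."""
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    td = np.asarray(t, dtype=float) - params.t0
    if boundary == "upper":
        return _lower_density_core(td, params.a, -params.v, 1.0 - params.w)
    return _lower_density_core(td, params.a, params.v, params.w)


def _gl_nodes(center: float, rng: float, n: int):
    """Gauss-Legendre nodes/weights averaging over Uniform(center +- rng/2);
    collapses to the center when the range is zero."""
    if rng <= 0:
        return np.array([center]), np.array([1.0])
    x, wts = np.polynomial.legendre.leggauss(n)
    return center + 0.5 * rng * x, wts / 2.0


def wiener7_density(t, boundary: str, params: DiffusionParams7, n_nodes: int = 11) -> np.ndarray:
    """Defective density of the seven-parameter model at full RT ``t``:
    analytic over normal drift, ``n_nodes``-point Gauss-Legendre over the
    uniform starting-point and non-decision ranges."""
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    t = np.asarray(t, dtype=float)
    wn, ww = _gl_nodes(params.w, params.sigma_w, n_nodes)
    tn, tw = _gl_nodes(params.t0, params.sigma_t0, n_nodes)
    if boundary == "upper":
        v_eff, w_nodes = -params.v, 1.0 - wn
    else:
        v_eff, w_nodes = params.v, wn
    td = t[..., None, None] - tn[None, :, None]  # (t, t0-node, 1)
    dens = _lower_density_core(
        td, params.a, v_eff, w_nodes[None, None, :], sigma_v=params.sigma_v
    )
    return np.einsum("...ij,i,j->...", dens, tw, ww)


def upper_probability(params: DiffusionParams4) -> float:
    """Closed-form probability of absorption at the upper (correct)
    boundary: (1 - exp(-2 v a w)) / (1 - exp(-2 v a)), with the v -> 0
    limit w."""
    va = params.v * params.a
    if abs(va) < 1e-9:
        return params.w
    return float(np.expm1(-2.0 * va * params.w) / np.expm1(-2.0 * va))


def defective_moments(params: DiffusionParams4, n_terms: int = _MOMENT_TERMS) -> dict:
    """Absorption probabilities and conditional decision-time moments.

    The large-time series integrates term by term:
        integral t^m f_lower(t) dt
          = (pi/a^2) e^{-vaw} sum_k k sin(k pi w) m! / lambda_k^{m+1},
        lambda_k = (v^2 + k^2 pi^2 / a^2) / 2.
    Probabilities use the closed form.  Returns conditional mean and
    variance of *decision* time per boundary (add t0 for full RT).
    """
    a, v, w = params.a, params.v, params.w
    k = np.arange(1, n_terms + 1)

    def cond(vv, ww):
        lam = 0.5 * (vv**2 + (k * np.pi / a) ** 2)
        pref = (np.pi / a**2) * np.exp(-vv * a * ww)
        s = np.sin(k * np.pi * ww)
        m1 = pref * np.sum(k * s / lam**2)
        m2 = pref * np.sum(2.0 * k * s / lam**3)
        return m1, m2

    p_up = upper_probability(params)
    p_low = 1.0 - p_up
    m1_low, m2_low = cond(v, w)
    m1_up, m2_up = cond(-v, 1.0 - w)
    out = {"p_upper": p_up, "p_lower": p_low}
    out["mean_upper"] = m1_up / p_up if p_up > 0 else np.nan
    out["var_upper"] = m2_up / p_up - out["mean_upper"] ** 2 if p_up > 0 else np.nan
    out["mean_lower"] = m1_low / p_low if p_low > 0 else np.nan
    out["var_lower"] = m2_low / p_low - out["mean_lower"] ** 2 if p_low > 0 else np.nan
    return out


def loglik(data: BoundaryData, params, n_nodes: int = 11) -> float:
    """Summed log defective density over trials.  Accepts either
    parameter set; per-trial densities are floored at 1e-10 before the
    log to guard contaminant outliers."""
    if isinstance(params, DiffusionParams7) and (
        params.sigma_v > 0 or params.sigma_w > 0 or params.sigma_t0 > 0
    ):
        dens = np.empty(len(data))
        up = data.upper
        if up.any():
            dens[up] = wiener7_density(data.rt[up], "upper", params, n_nodes)
        if (~up).any():
            dens[~up] = wiener7_density(data.rt[~up], "lower", params, n_nodes)
    else:
        p4 = params.main if isinstance(params, DiffusionParams7) else params
        dens = np.empty(len(data))
        up = data.upper
        if up.any():
            dens[up] = wiener_fpt_density(data.rt[up], "upper", p4)
        if (~up).any():
            dens[~up] = wiener_fpt_density(data.rt[~up], "lower", p4)
    ll = float(np.sum(np.log(np.maximum(dens, _DENSITY_FLOOR))))
    if not np.isfinite(ll):
        bad = int(np.flatnonzero(~np.isfinite(np.log(np.maximum(dens, _DENSITY_FLOOR))))[0])
        raise FloatingPointError(f"non-finite log-likelihood at trial {bad}")
    return ll


def _ez_start(data: BoundaryData) -> DiffusionParams4:
    """Unbiased EZ-style moment inversion used for starting values."""
    n = len(data)
    pc = float(np.mean(data.upper))
    pc = min(max(pc, 1.0 / (2 * n)), 1.0 - 1.0 / (2 * n))
    rts = data.rt[data.upper] if data.upper.any() else data.rt
    mrt, vrt = float(np.mean(rts)), float(np.var(rts, ddof=1)) if len(rts) > 1 else 0.02
    vrt = max(vrt, 1e-4)
    L = logit(pc)
    x = L * (L * pc**2 - L * pc + pc - 0.5) / vrt
    v = np.sign(pc - 0.5) * abs(x) ** 0.25
    v = float(np.clip(v, 0.3, 8.0))
    a = float(np.clip(abs(L / v) if v != 0 else 1.0, 0.4, 4.0))
    mdt = (a / (2.0 * v)) * (1.0 - np.exp(-v * a)) / (1.0 + np.exp(-v * a))
    t0 = float(np.clip(mrt - mdt, 0.05, 0.95 * np.min(data.rt)))
    return DiffusionParams4(a, v, t0, 0.5)


def fit_diffusion(
    data: BoundaryData,
    model: str = "four",
    n_restarts: int = 10,
    seed=None,
    n_nodes: int = 11,
):
    """Best-of-restarts Nelder-Mead MLE of the four- or seven-parameter
    model.

    Starting values come from an EZ-style moment inversion; each restart
    perturbs a, v, t0 (and variabilities) multiplicatively by
    Uniform(0.85, 1.15) and w additively by +-0.05 (clamped).  Constraints
    are enforced by an internal reparameterization (log for a and the
    variabilities, scaled logistic for t0 and w).  The result carries the
    k vs. k-1 restart-stability flag.
    """
    from .exgaussian import FitResult  # shared container

    if model not in ("four", "seven"):
        raise ValueError("model must be 'four' or 'seven'")
    n = len(data)
    if data.upper.all() or not data.upper.any():
        if n < 50:
            raise ValueError(
                "all responses terminate at one boundary and n < 50: "
                "a and w are not identifiable"
            )
        warnings.warn("single-boundary data: a and w weakly identified")

    rng = np.random.default_rng(seed)
    tmin = float(np.min(data.rt))
    start = _ez_start(data)
    seven = model == "seven"

    def unpack(theta: np.ndarray):
        a = float(np.exp(theta[0]))
        v = float(theta[1])
        t0 = float(tmin * expit(theta[2]))
        w = float(expit(theta[3]))
        if not seven:
            return DiffusionParams4(a, v, t0, w)
        sv = float(np.exp(theta[4]))
        sw = float(2.0 * min(w, 1.0 - w) * 0.98 * expit(theta[5]))
        st = float(2.0 * t0 * 0.98 * expit(theta[6]))
        return DiffusionParams7(a, v, t0, w, sv, sw, st)

    def nll(theta: np.ndarray) -> float:
        try:
            p = unpack(theta)
        except ValueError:
            return 1e12
        try:
            return -loglik(data, p, n_nodes=n_nodes)
        except FloatingPointError:
            return 1e12

    def pack(a, v, t0, w, sv=0.5, sw_frac=0.2, st_frac=0.3):
        t0 = min(t0, 0.98 * tmin)
        th = [np.log(a), v, logit(np.clip(t0 / tmin, 1e-4, 1 - 1e-4)),
              logit(np.clip(w, 1e-4, 1 - 1e-4))]
        if seven:
            th += [np.log(sv), logit(sw_frac), logit(st_frac)]
        return np.array(th)

    best = None
    objectives = np.empty(n_restarts)
    for k in range(n_restarts):
        a0, v0, t00, w0 = start.a, start.v, start.t0, start.w
        sv0, swf, stf = 0.5, 0.2, 0.3
        if k > 0:
            m = rng.uniform(0.85, 1.15, 5)
            a0, v0, t00, sv0 = a0 * m[0], v0 * m[1], t00 * m[2], sv0 * m[3]
            w0 = float(np.clip(w0 + rng.uniform(-0.05, 0.05), 0.05, 0.95))
        theta0 = pack(a0, v0, t00, w0, sv0, swf, stf)
        res = optimize.minimize(
            nll, theta0, method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-6, "maxiter": 4000},
        )
        objectives[k] = -res.fun
        if best is None or -res.fun > best[0]:
            best = (-res.fun, res, k)
    ll, res, k_best = best
    stable = n_restarts < 2 or bool(
        np.isclose(np.max(objectives[:-1]), np.max(objectives), atol=1e-4)
    )
    return FitResult(
        params=unpack(res.x),
        objective=ll,
        n_restarts=n_restarts,
        best_restart_index=k_best,
        converged=bool(res.success),
        seed=seed,
        stable_without_last=stable,
        restart_objectives=objectives,
    )


def simulate_diffusion(
    params: DiffusionParams7,
    n: int,
    seed,
    dt: float = 0.0005,
    antithetic: bool = False,
    max_decision_time: float = 30.0,
) -> BoundaryData:
    """Euler-Maruyama first-passage simulation (step ``dt`` seconds).

    Per trial, drift / start / non-decision time are drawn from their
    across-trial distributions, the path is stepped until absorption, and
    the non-decision time is added.  ``antithetic`` pairs each trial's
    Gaussian increments with their negation for variance reduction.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    v = rng.normal(params.v, params.sigma_v, n) if params.sigma_v > 0 else np.full(n, params.v)
    w = (
        rng.uniform(params.w - params.sigma_w / 2, params.w + params.sigma_w / 2, n)
        if params.sigma_w > 0
        else np.full(n, params.w)
    )
    t0 = (
        rng.uniform(params.t0 - params.sigma_t0 / 2, params.t0 + params.sigma_t0 / 2, n)
        if params.sigma_t0 > 0
        else np.full(n, params.t0)
    )

    x = params.a * w
    dtime = np.zeros(n)
    upper = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    sqdt = np.sqrt(dt)
    n_steps = int(max_decision_time / dt)
    for step in range(n_steps):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        if antithetic:
            # mirrored increments within each step halve the odd-moment
            # error of the step noise
            half = rng.standard_normal((idx.size + 1) // 2)
            eps = np.concatenate([half, -half])[: idx.size]
        else:
            eps = rng.standard_normal(idx.size)
        x_old = x[idx].copy()
        x[idx] = x_old + v[idx] * dt + sqdt * eps
        x_new = x[idx]
        hit_up = x_new >= params.a
        hit_low = x_new <= 0.0
        # Brownian-bridge correction: an uncrossed step may still have
        # touched a boundary in continuous time
        open_ = ~(hit_up | hit_low)
        if open_.any():
            xo, xn = x_old[open_], x_new[open_]
            p_up = np.exp(-2.0 * (params.a - xo) * (params.a - xn) / dt)
            p_low = np.exp(-2.0 * xo * xn / dt)
            u = rng.random(open_.sum())
            bridge_up = u < p_up
            bridge_low = (~bridge_up) & (u < p_up + p_low)
            hu = hit_up.copy()
            hu[open_] = bridge_up
            hl = hit_low.copy()
            hl[open_] = bridge_low
            hit_up, hit_low = hu, hl
        done = hit_up | hit_low
        dtime[idx[done]] = (step + 1) * dt
        upper[idx[hit_up]] = True
        active[idx[done]] = False
    if active.any():
        warnings.warn(f"{int(active.sum())} path(s) unabsorbed at cap; assigned by position")
        idx = np.flatnonzero(active)
        dtime[idx] = max_decision_time
        upper[idx] = x[idx] >= params.a / 2
    return BoundaryData(rt=dtime + t0, upper=upper)


def fisher_param_correlations(
    data: BoundaryData, params: DiffusionParams7, rel_step: float = 1e-3
) -> np.ndarray:
    """Correlation matrix of (a, v, t0, w) from the observed Fisher
    information: numeric Hessian of the negative log-likelihood at
    ``params``, inverted to a covariance and normalized.  Falls back to a
    pseudo-inverse (with a warning) if the Hessian is not positive
    definite."""
    x0 = np.array([params.a, params.v, params.t0, params.w])
    h = rel_step * np.maximum(np.abs(x0), 0.1)

    def f(x):
        p = DiffusionParams7(
            x[0], x[1], max(x[2], 0.0), float(np.clip(x[3], 1e-4, 1 - 1e-4)),
            params.sigma_v, min(params.sigma_w, 2 * min(x[3], 1 - x[3]) * 0.99),
            min(params.sigma_t0, 2 * max(x[2], 0.0)),
        )
        return -loglik(data, p)

    H = np.empty((4, 4))
    f0 = f(x0)
    for i in range(4):
        for j in range(i, 4):
            if i == j:
                xp, xm = x0.copy(), x0.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
                xpp[[i, j]] += h[[i, j]]
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                xmm[[i, j]] -= h[[i, j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("Hessian not positive definite; pseudo-inverse used")
        cov = np.linalg.pinv(H)
        cov = cov + np.eye(4) * max(0.0, 1e-12 - np.min(np.diag(cov)))
    d = np.sqrt(np.abs(np.diag(cov)))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def fit_diffusion_cells(
    table,
    model: str = "four",
    n_restarts: int = 10,
    seed=None,
    by=("participant", "stimulus_type", "sequence"),
    n_nodes: int = 11,
):
    """Diffusion MLE per grouping cell of a coded trial table (RTs
    converted ms -> s, correctness as boundary); returns a tidy frame."""
    import pandas as pd

    from .preprocessing import UNDEFINED

    df = table.df if hasattr(table, "df") else table
    if "sequence" in by:
        df = df[df["sequence"] != UNDEFINED]
    rng = np.random.default_rng(seed)
    rows = []
    for keys, cell in df.groupby(list(by), sort=True):
        data = BoundaryData(
            rt=cell["rt_ms"].to_numpy(float) / 1000.0,
            upper=cell["correct"].to_numpy(bool),
        )
        if len(data) < 20:
            continue
        try:
            fit = fit_diffusion(
                data, model=model, n_restarts=n_restarts,
                seed=int(rng.integers(2**31)), n_nodes=n_nodes,
            )
        except ValueError:
            continue
        rec = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        p = fit.params
        rec.update(a=p.a, v=p.v, t0=p.t0, w=p.w)
        if model == "seven":
            rec.update(sigma_v=p.sigma_v, sigma_w=p.sigma_w, sigma_t0=p.sigma_t0)
        rec.update(loglik=fit.objective, n_trials=len(data))
        rows.append(rec)
    return pd.DataFrame(rows)
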
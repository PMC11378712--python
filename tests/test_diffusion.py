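"""Wiener first-passage density, likelihood, MLE, simulator, Fisher
diagnostic."""

import numpy as np
import pytest
from scipy import integrate, stats

from rtseq import (
    BoundaryData,
    DiffusionParams4,
    DiffusionParams7,
    defective_moments,
    fisher_param_correlations,
    fit_diffusion,
    loglik,
    simulate_diffusion,
    upper_probability,
    wiener7_density,
    wiener_fpt_density,
)

P4 = DiffusionParams4(a=1.5, v=3.0, t0=0.3, w=0.5)


class TestDensity:
    def test_zero_drift_symmetry(self):
        p = DiffusionParams4(a=1.2, v=0.0, t0=0.2, w=0.5)
        ts = np.linspace(0.21, 2.0, 50)
        assert np.allclose(
            wiener_fpt_density(ts, "upper", p), wiener_fpt_density(ts, "lower", p)
        )

    @pytest.mark.parametrize(
        "p",
        [
            P4,
            DiffusionParams4(a=0.8, v=1.0, t0=0.1, w=0.3),
            DiffusionParams4(a=2.2, v=4.5, t0=0.4, w=0.65),
            DiffusionParams4(a=1.0, v=-2.0, t0=0.0, w=0.5),
        ],
    )
    def test_conservation(self, p):
        iu = integrate.quad(
            lambda t: wiener_fpt_density(t, "upper", p), p.t0, p.t0 + 40, limit=300
        )[0]
        il = integrate.quad(
            lambda t: wiener_fpt_density(t, "lower", p), p.t0, p.t0 + 40, limit=300
        )[0]
        assert iu + il == pytest.approx(1.0, abs=1e-5)
        assert iu == pytest.approx(upper_probability(p), abs=1e-6)

    def test_closed_form_absorption(self):
        p = DiffusionParams4(a=1.0, v=1.0, t0=0.0, w=0.5)
        assert upper_probability(p) == pytest.approx(
            (1 - np.exp(-1)) / (1 - np.exp(-2)), abs=1e-12
        )
        iu = integrate.quad(lambda t: wiener_fpt_density(t, "upper", p), 0, 40, limit=300)[0]
        assert iu == pytest.approx(0.7311, abs=1e-4)

    def test_density_zero_before_t0(self):
        assert wiener_fpt_density(0.25, "upper", P4) == 0.0

    def test_small_large_time_continuity(self):
        # density must be smooth across the series switch tau = 0.2
        for p in (P4, DiffusionParams4(2.0, 1.5, 0.0, 0.4)):
            t_switch = 0.2 * p.a**2 + p.t0
            ts = np.linspace(t_switch - 0.01, t_switch + 0.01, 41)
            d = wiener_fpt_density(ts, "upper", p)
            assert np.all(np.abs(np.diff(d, 2)) < 1e-3)


class TestSevenParamDensity:
    P7 = DiffusionParams7(1.5, 2.0, 0.3, 0.45, sigma_v=1.0, sigma_w=0.15, sigma_t0=0.12)

    def test_reduces_to_four_param(self):
        p7 = DiffusionParams7(*[getattr(P4, f) for f in ("a", "v", "t0", "w")])
        data = BoundaryData(rt=np.linspace(0.35, 2.0, 30), upper=np.ones(30, bool))
        assert loglik(data, p7) == pytest.approx(loglik(data, P4), abs=1e-8)

    def test_matches_monte_carlo_integration(self, rng):
        n = 200_000
        vs = rng.normal(self.P7.v, self.P7.sigma_v, n)
        ws = rng.uniform(self.P7.w - self.P7.sigma_w / 2, self.P7.w + self.P7.sigma_w / 2, n)
        t0s = rng.uniform(
            self.P7.t0 - self.P7.sigma_t0 / 2, self.P7.t0 + self.P7.sigma_t0 / 2, n
        )
        from rtseq.diffusion import _lower_density_core

        for t in (0.45, 0.6, 0.9, 1.4):
            vals = _lower_density_core(t - t0s, self.P7.a, -vs, 1.0 - ws)
            mc, se = vals.mean(), vals.std() / np.sqrt(n)
            ours = wiener7_density(np.array([t]), "upper", self.P7)[0]
            assert abs(ours - mc) < 3 * se + 1e-9

    def test_variability_slows_mean_and_spreads(self):
        # defined via quadrature of the density: drift variability fattens
        # the tail relative to the fixed-drift process
        p7 = self.P7
        p4 = p7.main
        f7 = lambda t: wiener7_density(np.array([t]), "upper", p7)[0]
        f4 = lambda t: wiener_fpt_density(np.array([t]), "upper", p4)[0]
        tail7 = integrate.quad(f7, 1.5, 12, limit=200)[0]
        tail4 = integrate.quad(f4, 1.5, 12, limit=200)[0]
        assert tail7 > tail4


class TestLoglik:
    def test_additivity_on_duplication(self):
        data = BoundaryData(rt=np.array([0.4, 0.5, 0.8]), upper=np.array([1, 1, 0], bool))
        doubled = BoundaryData(rt=np.tile(data.rt, 2), upper=np.tile(data.upper, 2))
        assert loglik(doubled, P4) == pytest.approx(2 * loglik(data, P4), abs=1e-9)

    def test_floor_handles_outliers(self):
        data = BoundaryData(rt=np.array([0.4, 25.0]), upper=np.array([1, 1], bool))
        ll = loglik(data, P4)
        assert np.isfinite(ll)


class TestMomentsSeries:
    def test_mean_decision_time_monotonic(self):
        # mean decision time decreases with |v| and increases with a
        a_grid = [0.8, 1.2, 1.6, 2.0]
        means_a = [
            defective_moments(DiffusionParams4(a, 2.0, 0.0, 0.5))["mean_upper"]
            for a in a_grid
        ]
        assert np.all(np.diff(means_a) > 0)
        v_grid = [0.5, 1.5, 3.0, 5.0]
        means_v = [
            defective_moments(DiffusionParams4(1.5, v, 0.0, 0.5))["mean_upper"]
            for v in v_grid
        ]
        assert np.all(np.diff(means_v) < 0)


class TestSimulator:
    def test_absorption_probability(self):
        p = DiffusionParams7(1.0, 1.0, 0.0, 0.5)
        n = 20000
        sim = simulate_diffusion(p, n, seed=2)
        phat = sim.upper.mean()
        ptrue = 0.7310585786
        # 99% binomial CI
        half = 2.576 * np.sqrt(ptrue * (1 - ptrue) / n)
        assert abs(phat - ptrue) < half

    def test_min_rt_bound(self):
        p = DiffusionParams7(1.5, 3.0, 0.3, 0.5, sigma_t0=0.1)
        sim = simulate_diffusion(p, 2000, seed=3)
        assert sim.rt.min() >= p.t0 - p.sigma_t0 / 2

    def test_ks_against_density_cdf(self):
        p = DiffusionParams7(1.5, 2.0, 0.2, 0.5)
        n = 30000
        sim = simulate_diffusion(p, n, seed=4)
        rt_up = np.sort(sim.rt[sim.upper])
        p4 = p.main
        p_up = upper_probability(p4)
        grid = np.linspace(p4.t0 + 1e-4, rt_up.max() + 0.5, 400)
        dens = wiener_fpt_density(grid, "upper", p4)
        cdf_grid = np.concatenate([[0.0], integrate.cumulative_trapezoid(dens, grid)]) / p_up
        cdf_at = np.interp(rt_up, grid, np.clip(cdf_grid, 0, 1))
        emp = np.arange(1, len(rt_up) + 1) / len(rt_up)
        assert np.max(np.abs(cdf_at - emp)) < 0.02

    def test_determinism_and_validation(self):
        p = DiffusionParams7(1.0, 2.0, 0.2, 0.5)
        s1 = simulate_diffusion(p, 50, seed=8)
        s2 = simulate_diffusion(p, 50, seed=8)
        assert np.array_equal(s1.rt, s2.rt) and np.array_equal(s1.upper, s2.upper)
        with pytest.raises(ValueError):
            simulate_diffusion(p, 0, seed=1)


class TestFit:
    def test_recovery_four_param(self):
        truth = DiffusionParams7(1.5, 3.0, 0.3, 0.5)
        sim = simulate_diffusion(truth, 2000, seed=7)
        fit = fit_diffusion(sim, model="four", n_restarts=3, seed=7)
        p = fit.params
        # bootstrap SEs at this n are roughly (0.05, 0.15, 0.005, 0.01)
        assert abs(p.a - 1.5) < 0.15
        assert abs(p.v - 3.0) < 0.45
        assert abs(p.t0 - 0.3) < 0.02
        assert abs(p.w - 0.5) < 0.04

    def test_symmetric_design_w_recovery(self):
        truth = DiffusionParams7(1.4, 2.0, 0.25, 0.5)
        sim = simulate_diffusion(truth, 4000, seed=11)
        fit = fit_diffusion(sim, model="four", n_restarts=3, seed=11)
        assert abs(fit.params.w - 0.5) < 0.02

    def test_recovery_seven_param(self):
        # one moderate-size fit: the variability parameters are weakly
        # identified at this n, so only the main parameters are checked
        # tightly; the fit must at least beat the truth's likelihood
        truth = DiffusionParams7(1.5, 3.0, 0.3, 0.5, sigma_v=1.0, sigma_w=0.1,
                                 sigma_t0=0.1)
        sim = simulate_diffusion(truth, 600, seed=19)
        fit = fit_diffusion(sim, model="seven", n_restarts=1, seed=19, n_nodes=5)
        p = fit.params
        assert abs(p.a - truth.a) < 0.3
        assert abs(p.v - truth.v) < 0.8
        assert abs(p.t0 - truth.t0) < 0.04
        assert abs(p.w - truth.w) < 0.08
        assert 0.0 <= p.sigma_v < 2.5
        assert fit.objective >= loglik(sim, truth, n_nodes=5) - 1e-6

    def test_single_boundary_small_n_refused(self):
        data = BoundaryData(rt=np.linspace(0.4, 1.0, 30), upper=np.ones(30, bool))
        with pytest.raises(ValueError, match="identifiab"):
            fit_diffusion(data, model="four", n_restarts=1, seed=0)

    def test_parametric_bootstrap_sanity(self):
        truth = DiffusionParams7(1.5, 3.0, 0.3, 0.5)
        sim = simulate_diffusion(truth, 1500, seed=13)
        fit = fit_diffusion(sim, model="four", n_restarts=2, seed=13)
        p = fit.params
        refit_data = simulate_diffusion(
            DiffusionParams7(p.a, p.v, p.t0, p.w), 1500, seed=14
        )
        ll_orig = loglik(sim, p) / len(sim)
        ll_refit = loglik(refit_data, p) / len(refit_data)
        assert abs(ll_orig - ll_refit) < 0.1  # per-trial log-lik comparable


class TestFisher:
    def test_matrix_properties_and_magnitude(self):
        truth = DiffusionParams7(1.6, 3.9, 0.34, 0.45, sigma_v=1.0, sigma_w=0.1, sigma_t0=0.1)
        sim = simulate_diffusion(truth, 600, seed=17)
        corr = fisher_param_correlations(sim, truth)
        assert corr.shape == (4, 4)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) <= 1.0)
        # at typical fitted magnitudes the main parameters trade off:
        # medium-to-high correlations appear
        assert np.max(np.abs(off)) >= 0.3
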
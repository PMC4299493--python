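"""Deconvolution checks: EM correctness, joint-fit recovery, growth curves."""

import numpy as np
import pytest
from scipy import optimize
from scipy.stats import norm

from bistflux.deconvolution import (
    BiGaussianComponents,
    apparent_lag_time,
    decompose_growth_curve,
    fit_bigaussian,
    fit_subpopulations,
    mixture_loglik,
)
from bistflux.scenarios import get_scenario, scenario_names
from bistflux.synthetic import LOG10_E, CytometryEventSet, growing_mean, growing_weight, simulate_dye_dilution, simulate_growth_curve
from conftest import make_config


def _sample_mixture(rng, n, w, m1, s1, m2, s2):
    k = rng.random(n) < w
    x = np.where(k, rng.normal(m1, s1, n), rng.normal(m2, s2, n))
    return x


class TestBiGaussianEM:
    def test_weight_recovery_well_separated(self, rng):
        x = _sample_mixture(rng, 20000, 0.5, 2.0, 0.25, 3.0, 0.25)
        c = fit_bigaussian(x)
        assert abs(c.weight_g - 0.5) < 0.02
        assert c.mean_g == pytest.approx(2.0, abs=0.02)
        assert c.mean_ng == pytest.approx(3.0, abs=0.02)

    def test_label_convention_higher_mean_is_nongrowing(self, rng):
        x = _sample_mixture(rng, 5000, 0.3, 2.0, 0.1, 3.0, 0.1)
        c = fit_bigaussian(x)
        assert c.mean_ng > c.mean_g
        assert c.mean_ng == pytest.approx(3.0, abs=0.05)

    def test_matches_brute_force_maximization(self, rng):
        # independent oracle: coarse grid over the 5-parameter mixture
        # likelihood followed by a Nelder-Mead polish
        x = _sample_mixture(rng, 500, 0.4, 2.2, 0.15, 3.0, 0.2)
        c = fit_bigaussian(x)
        ll_em = c.loglik

        qs = np.percentile(x, np.arange(5, 100, 7.5))
        sds = np.std(x) * np.array([0.3, 0.5, 0.8, 1.1])
        ws = np.linspace(0.1, 0.9, 9)
        best, best_ll = None, -np.inf
        for m1 in qs:
            for m2 in qs:
                if m2 <= m1:
                    continue
                for s1 in sds:
                    for s2 in sds:
                        for w in ws:
                            ll = mixture_loglik(x, m1, s1, m2, s2, w)
                            if ll > best_ll:
                                best_ll, best = ll, (m1, s1, m2, s2, w)

        def nll(t):
            m1, ls1, m2, ls2, zw = t
            w = 1 / (1 + np.exp(-zw))
            return -mixture_loglik(x, m1, np.exp(ls1), m2, np.exp(ls2), w)

        t0 = [best[0], np.log(best[1]), best[2], np.log(best[3]),
              np.log(best[4] / (1 - best[4]))]
        res = optimize.minimize(nll, t0, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-10,
                                         "maxiter": 5000})
        ll_grid = -res.fun
        assert abs(ll_em - ll_grid) < 1e-3

    def test_matches_sklearn_mixture(self, rng):
        sklearn = pytest.importorskip("sklearn.mixture")
        x = _sample_mixture(rng, 5000, 0.35, 2.0, 0.15, 2.8, 0.2)
        c = fit_bigaussian(x)
        gm = sklearn.GaussianMixture(2, n_init=5, tol=1e-8,
                                     random_state=0).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        assert c.mean_g == pytest.approx(gm.means_.ravel()[order[0]], abs=0.01)
        assert c.weight_g == pytest.approx(gm.weights_[order[0]], abs=0.01)

    def test_degenerate_sd_is_clamped_and_flagged(self, rng):
        x = np.concatenate([np.full(300, 2.0), rng.normal(3.0, 0.2, 700)])
        c = fit_bigaussian(x, sd_min=0.01)
        assert "sd_clamped" in c.flags
        assert min(c.sd_g, c.sd_ng) >= 0.01

    def test_requires_enough_events(self):
        with pytest.raises(ValueError):
            fit_bigaussian(np.zeros(50))

    def test_init_permutation_invariance(self, rng):
        # feeding a swapped initialization must not change the labelled fit
        x = _sample_mixture(rng, 8000, 0.4, 2.0, 0.15, 3.0, 0.15)
        a = BiGaussianComponents(0.0, 2.1, 0.2, 2.9, 0.2, 0.5, 0.0)
        b = BiGaussianComponents(0.0, 2.9, 0.2, 2.1, 0.2, 0.5, 0.0)
        ca = fit_bigaussian(x, init=a)
        cb = fit_bigaussian(x, init=b)
        assert ca.mean_g == pytest.approx(cb.mean_g, abs=1e-6)
        assert ca.weight_g == pytest.approx(cb.weight_g, abs=1e-6)


class TestSubpopulationFit:
    def test_noise_free_limit_recovers_exactly(self):
        # deterministic quantile "events" of the exact mixture density
        alpha, mu, m0, sd = 0.4, 0.25, 4.0, 0.12
        series = []
        n = 40000
        for d in [0.0, 1.6, 2.4, 3.2, 4.0, 4.8]:
            t = d * np.log(2.0) / mu
            w = growing_weight(alpha, mu, t)
            mg = growing_mean(m0, mu, t)
            n_g = int(round(w * n))
            q_g = (np.arange(n_g) + 0.5) / max(n_g, 1)
            q_ng = (np.arange(n - n_g) + 0.5) / max(n - n_g, 1)
            vals = np.concatenate([
                norm.ppf(q_g, mg, sd) if n_g else np.empty(0),
                norm.ppf(q_ng, m0, sd),
            ])
            series.append(CytometryEventSet(time=t, values=vals))
        fit = fit_subpopulations(series)
        assert fit.alpha == pytest.approx(alpha, abs=2e-3)
        assert fit.mu_g == pytest.approx(mu, rel=2e-3)

    def test_label_swap_invariance_of_estimates(self):
        cfg = make_config(alpha=0.5, seed=3)
        ev = simulate_dye_dilution(cfg)
        f1 = fit_subpopulations(ev)
        f2 = fit_subpopulations(list(reversed(ev)))
        assert f1.alpha == pytest.approx(f2.alpha, abs=1e-9)
        assert f1.mu_g == pytest.approx(f2.mu_g, abs=1e-9)

    def test_all_growing_hits_upper_boundary(self):
        cfg = make_config(alpha=1.0, seed=4)
        fit = fit_subpopulations(simulate_dye_dilution(cfg))
        assert fit.alpha == 1.0
        assert "alpha_at_upper_boundary" in fit.flags
        assert fit.mu_g == pytest.approx(cfg.mu_g_true, rel=0.05)

    def test_none_growing_flags_upper_bound(self):
        cfg = make_config(alpha=0.0, seed=5, n_events=5000)
        fit = fit_subpopulations(simulate_dye_dilution(cfg))
        assert "upper_bound" in fit.flags
        assert fit.alpha == 0.0

    def test_early_unresolvable_timepoints_are_excluded(self):
        cfg = make_config(alpha=0.5, seed=6)
        fit = fit_subpopulations(simulate_dye_dilution(cfg))
        assert 0.0 in fit.excluded_times

    def test_recovery_across_registry_scenarios(self):
        # median parameter-recovery error over seeded replicates per scenario
        n_rep = 50
        for name in scenario_names():
            a_err, mu_err = [], []
            for seed in range(n_rep):
                cfg = get_scenario(name, seed=1000 + seed)
                if cfg.alpha_true > 0.01:
                    cfg = get_scenario(name, seed=1000 + seed, n_events=2000)
                fit = fit_subpopulations(simulate_dye_dilution(cfg))
                a_err.append(abs(fit.alpha - cfg.alpha_true))
                if fit.alpha > 0:
                    mu_err.append(abs(fit.mu_g - cfg.mu_g_true))
            tol_a = max(0.04, 0.2 * cfg.alpha_true)
            assert np.median(a_err) <= tol_a, name
            assert np.median(mu_err) <= 0.05 * cfg.mu_g_true, name

    def test_estimator_consistency_with_sample_size(self):
        errs = {}
        for n in (2000, 20000):
            e = []
            for seed in range(8):
                cfg = make_config(alpha=0.5, seed=50 + seed, n_events=n)
                fit = fit_subpopulations(simulate_dye_dilution(cfg))
                e.append(abs(fit.alpha - 0.5))
            errs[n] = np.median(e)
        assert errs[20000] < errs[2000]

    def test_global_likelihood_mode_agrees(self):
        cfg = make_config(alpha=0.5, seed=7)
        ev = simulate_dye_dilution(cfg)
        two_stage = fit_subpopulations(ev)
        joint = fit_subpopulations(ev, global_likelihood=True)
        assert "global_likelihood" in joint.flags
        assert joint.alpha == pytest.approx(two_stage.alpha, abs=0.03)
        assert joint.mu_g == pytest.approx(two_stage.mu_g, rel=0.05)


class TestGrowthCurveDecomposition:
    def test_noise_free_round_trip(self):
        t = np.linspace(0, 60, 20)
        gc = simulate_growth_curve(0.001, 0.2, 1e7, t, 0.0)
        dec = decompose_growth_curve(gc)
        assert dec.alpha == pytest.approx(0.001, rel=1e-3)
        assert dec.mu_g == pytest.approx(0.2, rel=1e-3)
        assert dec.n0 == pytest.approx(1e7, rel=1e-3)

    def test_all_growing_boundary(self):
        t = np.linspace(0, 10, 8)
        gc = simulate_growth_curve(1.0, 0.3, 1e7, t, 0.0)
        dec = decompose_growth_curve(gc)
        assert dec.alpha > 0.99
        assert dec.mu_g == pytest.approx(0.3, rel=0.01)

    def test_flat_curve_rejected(self):
        gc = simulate_growth_curve(0.0, 0.3, 1e7, np.linspace(0, 10, 8), 0.0)
        with pytest.raises(ValueError, match="no growth"):
            decompose_growth_curve(gc)


class TestApparentLag:
    @pytest.mark.parametrize("alpha,mu,expected", [
        (1.0, 0.5, 0.0),
        (np.exp(-1.0), 1.0, 1.0),
        (0.001, 0.2, np.log(1000.0) / 0.2),
    ])
    def test_closed_form(self, alpha, mu, expected):
        assert apparent_lag_time(alpha, mu) == pytest.approx(expected, rel=1e-12)

    def test_zero_alpha_signalled(self):
        with pytest.raises(ValueError):
            apparent_lag_time(0.0, 0.2)
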
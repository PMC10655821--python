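"""Zero-inflated beta regression: likelihood, fitting, LRT."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime
from scipy.special import expit, gammaln

from meadev.synthetic import ZibSimSpec, simulate_zib_dataset
from meadev.zib import (_designs, _grad_nore, fit_zib, lrt_zero_process,
                        zib_loglik)


def small_data(seed=3, n=50):
    spec = ZibSimSpec(cells_per_batch_per_group=n, n_batches=2, divs=(14, 42))
    return simulate_zib_dataset(spec, seed=seed).head(4 * n)


class TestLoglik:
    def test_zero_with_logit_zero_contributes_log_half(self):
        y = np.array([0.0])
        X = np.ones((1, 1))
        Z = np.ones((1, 1))
        ll = zib_loglik(np.array([0.0]), 0.0, np.array([0.0]), y, X, Z)
        assert ll == pytest.approx(np.log(0.5))

    def test_uniform_beta_case(self):
        # y=0.5, mu=0.5, phi=2 -> Beta(1,1) density 1; pi=0.2 -> log 0.8
        y = np.array([0.5])
        X = np.ones((1, 1))
        Z = np.ones((1, 1))
        gam = np.array([np.log(0.2 / 0.8)])
        ll = zib_loglik(np.array([0.0]), np.log(2.0), gam, y, X, Z)
        assert ll == pytest.approx(np.log(0.8), abs=1e-12)

    def test_matches_textbook_evaluation(self, rng):
        d = small_data()
        y, X, Z, b, groups, c = _designs(d, True, 28.0)
        for _ in range(5):
            beta = rng.normal(0, 0.5, 4)
            log_phi = rng.normal(2, 0.3)
            gam = rng.normal(0, 0.5, 2)
            ll = zib_loglik(beta, log_phi, gam, y, X, Z)
            phi = np.exp(log_phi)
            pi = expit(Z @ gam)
            mu = expit(X @ beta)
            direct = 0.0
            for i in range(y.size):
                if y[i] == 0:
                    direct += np.log(pi[i])
                else:
                    a_, b_ = mu[i] * phi, (1 - mu[i]) * phi
                    direct += (np.log(1 - pi[i]) + gammaln(phi)
                               - gammaln(a_) - gammaln(b_)
                               + (a_ - 1) * np.log(y[i])
                               + (b_ - 1) * np.log(1 - y[i]))
            assert ll == pytest.approx(direct, abs=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        d = small_data()
        y, X, Z, *_ = _designs(d, True, 28.0)
        theta = np.concatenate([rng.normal(0, 0.3, 4), [np.log(5.0)],
                                rng.normal(0, 0.3, 2)])

        def f(th):
            return -zib_loglik(th[:4], th[4], th[5:7], y, X, Z)

        num = approx_fprime(theta, f, 1e-7)
        assert np.max(np.abs(num - _grad_nore(theta, y, X, Z))) < 1e-3

    def test_quadrature_agrees_with_no_re_path_at_zero_sigma(self, rng):
        d = small_data()
        y, X, Z, batches, *_ = _designs(d, True, 28.0)
        beta = rng.normal(0, 0.3, 4)
        plain = zib_loglik(beta, np.log(8.0), np.array([-1.0, 0.02]),
                           y, X, Z)
        quad = zib_loglik(beta, np.log(8.0), np.array([-1.0, 0.02]),
                          y, X, Z, batches, np.log(1e-7))
        assert quad == pytest.approx(plain, abs=1e-8)

    def test_response_at_one_rejected(self):
        d = small_data()
        d.loc[0, "response"] = 1.0
        with pytest.raises(ValueError):
            _designs(d, True, 28.0)


class TestFit:
    def test_no_zeros_reduces_to_beta_regression(self):
        spec = ZibSimSpec(zero_coefs=(-40.0, 0.0), n_batches=1,
                          cells_per_batch_per_group=300, batch_sd=0.0)
        d = simulate_zib_dataset(spec, seed=6)
        assert (d["response"] > 0).all()
        fit = fit_zib(d, zero_on_div=False, div_center=28.0, n_starts=1)
        # zero intercept driven to the guard bound, pi ~ 0
        assert fit.gamma[0] == pytest.approx(-20.0, abs=1e-6)
        assert expit(fit.gamma[0]) < 1e-8
        # beta part matches a fit on the positive likelihood alone
        y, X, Z, *_ = _designs(d, False, 28.0)
        ll_beta_only = zib_loglik(fit.beta, np.log(fit.phi),
                                  np.array([-40.0]), y, X, Z)
        assert fit.loglik == pytest.approx(ll_beta_only, abs=1e-3)

    def test_permuted_group_labels_give_null_coefficient(self, rng):
        spec = ZibSimSpec(n_batches=1, cells_per_batch_per_group=400,
                          batch_sd=0.0)
        d = simulate_zib_dataset(spec, seed=8)
        d["group"] = rng.permutation(d["group"].to_numpy())
        fit = fit_zib(d, div_center=28.0, n_starts=1)
        s = fit.summary()
        z = abs(s.loc["beta_group", "estimate"] / s.loc["beta_group", "se"])
        assert z < 2.0

    def test_final_gradient_is_small(self):
        d = small_data(seed=9, n=150)
        fit = fit_zib(d, div_center=28.0, n_starts=1)
        y, X, Z, *_ = _designs(d, True, 28.0)
        g = _grad_nore(fit.params, y, X, Z)
        assert np.max(np.abs(g)) / max(1.0, abs(fit.loglik)) < 1e-5


class TestLrt:
    def test_identical_fits_give_zero_statistic(self):
        d = small_data(seed=10, n=120)
        null = fit_zib(d, zero_on_div=False, div_center=28.0, n_starts=1)
        alt = fit_zib(d, zero_on_div=True, div_center=28.0, n_starts=1,
                      start=np.insert(null.params, 6, 0.0))
        t = lrt_zero_process(null, alt)
        assert t["df"] == 1
        assert t["statistic"] >= 0.0
        assert 0.0 <= t["p_value"] <= 1.0

    def test_non_nested_rejected(self):
        d = small_data(seed=11, n=80)
        f = fit_zib(d, zero_on_div=True, div_center=28.0, n_starts=1)
        with pytest.raises(ValueError):
            lrt_zero_process(f, f)

    def test_power_against_time_varying_zero_process(self):
        spec = ZibSimSpec(n_batches=1, cells_per_batch_per_group=120,
                          divs=(14, 28, 42), zero_coefs=(-1.0, 0.08),
                          batch_sd=0.0)
        rej = 0
        for r in range(25):
            d = simulate_zib_dataset(spec, seed=300 + r)
            null = fit_zib(d, zero_on_div=False, n_starts=1)
            alt = fit_zib(d, zero_on_div=True, n_starts=1,
                          start=np.insert(null.params, 6, 0.0))
            rej += lrt_zero_process(null, alt)["p_value"] < 0.05
        assert rej / 25 > 0.8
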
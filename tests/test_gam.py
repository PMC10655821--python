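"""Penalized-spline gamma GAM: basis, fitting, genotype comparison."""

import numpy as np
import pandas as pd
import pytest

from meadev.gam import (GamConfig, _assemble, build_spline_basis, cr_basis,
                        fit_gamma_gam, genotype_difference)


def gamma_table(rng, n=600, log_mean=lambda d: 1 + np.sin(d / 6),
                shape=5.0, genotype=None, ratio=1.0):
    div = rng.uniform(4, 42, n)
    mu = np.exp(log_mean(div))
    df = pd.DataFrame({"div": div,
                       "f": rng.gamma(shape, mu / shape)})
    if genotype is not None:
        df["genotype"] = genotype
        df.loc[df["genotype"] == "b", "f"] *= ratio
    return df


class TestBasis:
    def test_design_at_knots_is_identity(self, rng):
        for _ in range(5):
            knots = np.sort(rng.uniform(0, 40, rng.integers(4, 12)))
            while np.min(np.diff(knots)) < 1e-3:
                knots = np.sort(rng.uniform(0, 40, 8))
            X, _ = cr_basis(knots, knots)
            assert np.allclose(X, np.eye(knots.size), atol=1e-9)
            assert np.linalg.matrix_rank(X) == knots.size

    def test_linear_function_unpenalized_before_shrinkage(self, rng):
        knots = np.sort(rng.uniform(0, 40, 9))
        _, S = cr_basis(knots, knots)
        beta = 3.0 - 0.7 * knots
        assert abs(beta @ S @ beta) < 1e-8
        # with shrinkage the penalty is positive definite
        _, S_sh, _ = build_spline_basis(np.linspace(4, 42, 20), k=9)
        assert beta[:S_sh.shape[0]] @ S_sh[:9, :9] @ beta[:9] > 0
        eigvals = np.linalg.eigvalsh((S_sh + S_sh.T) / 2)
        assert eigvals.min() > 0

    def test_too_few_divs_rejected(self):
        with pytest.raises(ValueError):
            build_spline_basis([1.0, 2.0, 3.0], k=10)


class TestFit:
    def test_gaussian_identity_matches_ridge_closed_form(self, rng):
        df = gamma_table(rng, n=200)
        cfg = GamConfig(family="gaussian", link="identity", lam=2.5,
                        by_genotype=False)
        fit = fit_gamma_gam(df, "f", cfg)
        X, S, *_ = _assemble(df["div"].to_numpy(), None, cfg)
        beta = np.linalg.solve(X.T @ X + 2.5 * S, X.T @ df["f"].to_numpy())
        assert np.max(np.abs(beta - fit.beta)) < 1e-8

    def test_gamma_curve_recovery(self, rng):
        df = gamma_table(rng, n=600)
        fit = fit_gamma_gam(df, "f", GamConfig(by_genotype=False))
        grid = np.linspace(5, 41, 60)
        pred = fit.predict(grid, "all", link_scale=True)
        mae = np.mean(np.abs(pred["fit"].to_numpy() - (1 + np.sin(grid / 6))))
        assert mae < 0.1

    def test_infinite_smoothing_collapses_to_intercept(self, rng):
        df = gamma_table(rng, n=300)
        fit = fit_gamma_gam(df, "f", GamConfig(by_genotype=False, lam=1e14))
        assert fit.edf <= 1.5
        y = df["f"].to_numpy()
        mu0 = y.mean()
        dev0 = 2 * np.sum(-np.log(y / mu0) + (y - mu0) / mu0)
        assert abs(fit.deviance - dev0) < 1e-6

    def test_near_constant_response_has_small_edf(self, rng):
        df = pd.DataFrame({"div": rng.uniform(4, 42, 200),
                           "f": 5.0 + rng.normal(0, 1e-4, 200)})
        fit = fit_gamma_gam(df, "f", GamConfig(by_genotype=False))
        assert fit.edf <= 1.5

    def test_unpenalized_full_rank_interpolates(self, rng):
        div = np.arange(4, 14, dtype=float)
        y = np.exp(rng.normal(0.5, 0.3, div.size))
        df = pd.DataFrame({"div": div, "f": y})
        fit = fit_gamma_gam(df, "f", GamConfig(k=div.size, lam=0.0,
                                               by_genotype=False,
                                               shrinkage_eps=0.0,
                                               tol=1e-12))
        pred = fit.predict(div, "all")
        assert np.allclose(pred["fit"].to_numpy(), y, rtol=1e-6)

    def test_zeros_dropped_with_warning(self, rng):
        df = gamma_table(rng, n=100)
        df.loc[:4, "f"] = 0.0
        with pytest.warns(RuntimeWarning):
            fit = fit_gamma_gam(df, "f", GamConfig(by_genotype=False))
        assert fit.n_obs == 95

    def test_ci_width_shrinks_with_n(self, rng):
        widths = []
        for n in (50, 200, 800):
            df = gamma_table(rng, n=n)
            fit = fit_gamma_gam(df, "f", GamConfig(by_genotype=False))
            pred = fit.predict(np.linspace(6, 40, 20), "all",
                               link_scale=True)
            widths.append(np.mean(pred["hi"] - pred["lo"]))
        assert widths[0] > widths[1] > widths[2]


class TestGenotypeDifference:
    def test_identical_data_gives_null_difference(self, rng):
        base = gamma_table(rng, n=300)
        df = pd.concat([base.assign(genotype="a"),
                        base.assign(genotype="b")], ignore_index=True)
        fit = fit_gamma_gam(df, "f", GamConfig())
        d = genotype_difference(fit, np.linspace(5, 41, 30))
        assert np.max(np.abs(d["difference"])) < 1e-8
        assert not d["significant"].any()

    def test_constant_fold_change_recovered(self, rng):
        rows = []
        for g, ratio in (("a", 1.0), ("b", 2.0)):
            div = np.repeat(np.arange(4, 43), 8).astype(float)
            mu = np.exp(1 + np.sin(div / 6)) * ratio
            rows.append(pd.DataFrame({
                "div": div, "genotype": g,
                "f": rng.gamma(5.0, mu / 5.0)}))
        fit = fit_gamma_gam(pd.concat(rows, ignore_index=True), "f",
                            GamConfig())
        grid = np.linspace(5, 41, 40)
        d = genotype_difference(fit, grid)
        covered = ((d["lo"] <= np.log(2)) & (np.log(2) <= d["hi"])).mean()
        assert covered >= 0.9

    def test_extrapolation_refused(self, rng):
        df = pd.concat([gamma_table(rng, n=100).assign(genotype=g)
                        for g in ("a", "b")], ignore_index=True)
        fit = fit_gamma_gam(df, "f", GamConfig())
        with pytest.raises(ValueError):
            genotype_difference(fit, [1.0, 50.0])
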
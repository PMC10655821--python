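"""Penalized-spline GAM for developmental trajectories of MEA features.

The longitudinal model smooths each well-level feature over day-in-vitro
(DIV) with a cubic regression spline carrying a shrinkage penalty, assuming
gamma-distributed response with a log link: with two genotypes, each gets
its own smooth plus an intercept contrast, and trajectories are compared
pointwise via 95% confidence intervals of the link-scale difference.

Implementation notes
--------------------
* Basis: Wood-style cubic regression spline parameterised by its values at
  ``k`` knots placed at quantiles of the observed DIVs; the penalty is the
  integrated squared second derivative.  The *shrinkage* variant adds
  ``eps`` times the projection onto the penalty null space (constant +
  linear), so as the smoothing parameter grows the whole smooth — not just
  its wiggly part — is pulled to zero and the fit collapses to the
  parametric terms.
* Fitting: penalized iteratively reweighted least squares.  For the gamma
  family with log link the IRLS working weights are identically 1, so each
  step is a penalized least squares solve on the working response
  ``z = eta + (y - mu)/mu``.
* Smoothing parameter: generalized cross-validation on a log-spaced grid
  (one shared lambda for all smooths), or a fixed value.
* Intervals: Bayesian posterior covariance ``phi * (X'X + lam*S)^{-1}``
  with the Pearson dispersion estimate; pointwise 1.96-sigma bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GamConfig",
    "TrajectoryFit",
    "build_spline_basis",
    "cr_basis",
    "fit_gamma_gam",
    "genotype_difference",
]


@dataclass(frozen=True)
class GamConfig:
    k: int = 10
    shrinkage_eps: float = 1e-3
    family: str = "gamma"        # or "gaussian"
    link: str = "log"            # or "identity"
    lam: float | None = None     # None -> GCV selection
    lam_grid: tuple = tuple(np.logspace(-4, 6, 40))
    by_genotype: bool = True
    max_iter: int = 200
    tol: float = 1e-9
    z_crit: float = 1.96

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ValueError("basis dimension k must be >= 4")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be >= 0")


def _cr_penalty_parts(knots: np.ndarray):
    """Banded matrices of the natural-cubic-spline construction."""
    k = knots.size
    h = np.diff(knots)
    if np.any(h <= 0):
        raise ValueError("knots must be strictly increasing")
    B = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    return B, D, h


def cr_basis(x: np.ndarray, knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-regression-spline design and second-derivative penalty.

    The spline is parameterised by its values at the knots, so the design
    evaluated at the knots is the identity.  Evaluation outside the knot
    range extends linearly (natural spline).
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = knots.size
    B, D, h = _cr_penalty_parts(knots)
    F = np.vstack([np.zeros(k), np.linalg.solve(B, D), np.zeros(k)])
    S = D.T @ np.linalg.solve(B, D)
    S = (S + S.T) / 2.0

    X = np.zeros((x.size, k))
    xc = np.clip(x, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, xc, side="right") - 1, 0, k - 2)
    hj = h[j]
    dm = knots[j + 1] - xc
    dp = xc - knots[j]
    am, ap = dm / hj, dp / hj
    cm = (dm**3 / hj - hj * dm) / 6.0
    cp = (dp**3 / hj - hj * dp) / 6.0
    rows = np.arange(x.size)
    X[rows, j] += am
    X[rows, j + 1] += ap
    X += cm[:, None] * F[j] + cp[:, None] * F[j + 1]
    # linear extension beyond the boundary knots
    for side, knot_idx in ((x < knots[0], 0), (x > knots[-1], k - 1)):
        if side.any():
            eps_ = 1e-6 * (knots[-1] - knots[0])
            x0 = knots[knot_idx]
            b0 = cr_basis(np.array([x0]), knots)[0][0]
            b1 = cr_basis(np.array([x0 - eps_ if knot_idx else x0 + eps_]),
                          knots)[0][0]
            slope = (b0 - b1) / eps_ * (1 if knot_idx else -1)
            X[side] = b0 + (x[side] - x0)[:, None] * slope
    return X, S


def build_spline_basis(div_values, k: int = 10,
                       shrinkage_eps: float = 1e-3
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design and shrinkage penalty for observed DIVs.

    Knots sit at quantiles of the unique observed values; the penalty is the
    second-derivative penalty plus ``shrinkage_eps`` times the projection
    onto its null space (constant and linear functions), making it positive
    definite.  Returns ``(design, penalty, knots)``.
    """
    div_values = np.asarray(div_values, dtype=float)
    uniq = np.unique(div_values)
    if uniq.size < 4:
        raise ValueError("need at least 4 distinct DIV values")
    kk = min(k, uniq.size)
    qs = np.linspace(0, 1, kk)
    knots = np.quantile(uniq, qs)
    knots = np.unique(knots)
    X, S = cr_basis(div_values, knots)
    # null space of S: constant + linear evaluated at the knots
    N = np.column_stack([np.ones(knots.size), knots - knots.mean()])
    Q, _ = np.linalg.qr(N)
    S = S + shrinkage_eps * (Q @ Q.T)
    return X, S, knots


def _center_constraint(Xs: np.ndarray) -> np.ndarray:
    """Sum-to-zero reparameterisation: columns spanning the null space of
    the column-mean vector, so the smooth is orthogonal to the intercept."""
    c = Xs.mean(axis=0)
    Q, _ = np.linalg.qr(c.reshape(-1, 1), mode="complete")
    return Q[:, 1:]


@dataclass
class TrajectoryFit:
    config: GamConfig
    feature: str
    genotypes: list
    knots: np.ndarray
    Z: np.ndarray                   # constraint reparameterisation (k x k-1)
    beta: np.ndarray
    cov: np.ndarray
    lam: float
    edf: float
    dispersion: float
    deviance: float
    div_range: tuple
    n_obs: int
    n_iter: int
    converged: bool
    gcv_path: pd.DataFrame | None = None

    def _row(self, div: np.ndarray, genotype: str) -> np.ndarray:
        div = np.atleast_1d(np.asarray(div, dtype=float))
        ng = len(self.genotypes)
        Bs = cr_basis(div, self.knots)[0] @ self.Z
        p_par = 1 + (ng - 1)
        rows = np.zeros((div.size, self.beta.size))
        rows[:, 0] = 1.0
        gi = self.genotypes.index(genotype)
        if gi > 0:
            rows[:, gi] = 1.0
        w = self.Z.shape[1]
        rows[:, p_par + gi * w: p_par + (gi + 1) * w] = Bs
        return rows

    def predict(self, div, genotype=None, link_scale: bool = False
                ) -> pd.DataFrame:
        """Pointwise fit and 95% CI on a DIV grid."""
        gens = [genotype] if genotype is not None else self.genotypes
        out = []
        for g in gens:
            rows = self._row(div, g)
            eta = rows @ self.beta
            se = np.sqrt(np.einsum("ij,jk,ik->i", rows, self.cov, rows))
            lo = eta - self.config.z_crit * se
            hi = eta + self.config.z_crit * se
            if self.config.link == "log" and not link_scale:
                eta, lo, hi = np.exp(eta), np.exp(lo), np.exp(hi)
            out.append(pd.DataFrame({
                "div": np.atleast_1d(div), "genotype": g,
                "fit": eta, "lo": lo, "hi": hi, "se_link": se}))
        return pd.concat(out, ignore_index=True)


def _assemble(div, genotype, config):
    genotypes = sorted(pd.unique(genotype)) if config.by_genotype else ["all"]
    Xs, S, knots = build_spline_basis(div, config.k, config.shrinkage_eps)
    Z = _center_constraint(Xs)
    XsZ = Xs @ Z
    Sz = Z.T @ S @ Z
    ng = len(genotypes)
    n = div.size
    p_par = 1 + (ng - 1)
    w = Z.shape[1]
    X = np.zeros((n, p_par + ng * w))
    X[:, 0] = 1.0
    S_blocks = np.zeros((X.shape[1], X.shape[1]))
    for gi, g in enumerate(genotypes):
        mask = np.ones(n, dtype=bool) if not config.by_genotype \
            else (np.asarray(genotype) == g)
        if gi > 0:
            X[mask, gi] = 1.0
        sl = slice(p_par + gi * w, p_par + (gi + 1) * w)
        X[mask, sl] = XsZ[mask]
        S_blocks[sl, sl] = Sz
    return X, S_blocks, knots, Z, genotypes


def _pirls(X, S, y, lam, config):
    n, p = X.shape
    if config.family == "gaussian" and config.link == "identity":
        A = X.T @ X + lam * S
        beta = np.linalg.solve(A, X.T @ y)
        mu = X @ beta
        edf = float(np.trace(np.linalg.solve(A, X.T @ X)))
        rss = float(np.sum((y - mu) ** 2))
        return beta, mu, edf, rss, 1, True
    eta = np.log(np.clip(y, np.quantile(y, 0.01) * 0.5 + 1e-12, None))
    beta = np.zeros(p)
    ok = False
    it = 0
    for it in range(1, config.max_iter + 1):
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        A = X.T @ X + lam * S
        beta_new = np.linalg.solve(A, X.T @ z)
        eta_new = X @ beta_new
        if np.max(np.abs(eta_new - eta)) < config.tol * (1 + np.max(np.abs(eta))):
            beta, eta, ok = beta_new, eta_new, True
            break
        beta, eta = beta_new, eta_new
    mu = np.exp(eta)
    edf = float(np.trace(np.linalg.solve(X.T @ X + lam * S, X.T @ X)))
    # at convergence eta = X beta, so the working RSS equals the Pearson
    # statistic sum(((y-mu)/mu)^2)
    rss = float(np.sum(((y - mu) / mu) ** 2))
    return beta, mu, edf, rss, it, ok


def fit_gamma_gam(features: pd.DataFrame, feature: str,
                  config: GamConfig | None = None) -> TrajectoryFit:
    """Fit the trajectory GAM for one feature.

    Rows with missing or (for the gamma family) non-positive response are
    dropped with a warning: a zero daily value means the defining events
    were absent, which the inclusion rules treat as missing.
    """
    config = config or GamConfig()
    df = features[["div", feature] + (["genotype"] if config.by_genotype
                                      else [])].copy()
    df = df.dropna()
    if config.family == "gamma":
        n_zero = int((df[feature] <= 0).sum())
        if n_zero:
            warnings.warn(f"dropping {n_zero} non-positive {feature} values "
                          "(gamma family requires positive response)",
                          RuntimeWarning, stacklevel=2)
            df = df[df[feature] > 0]
    y = df[feature].to_numpy(dtype=float)
    div = df["div"].to_numpy(dtype=float)
    genotype = df["genotype"].to_numpy() if config.by_genotype else None
    X, S, knots, Z, genotypes = _assemble(div, genotype, config)
    n = y.size

    def gcv_at(lam):
        beta, mu, edf, rss, it, ok = _pirls(X, S, y, lam, config)
        if config.family == "gamma":
            pearson = float(np.sum(((y - mu) / mu) ** 2))
        else:
            pearson = rss
        denom = max(n - edf, 1e-8) ** 2
        g = n * pearson / denom
        return g, (beta, mu, edf, it, ok)

    path = []
    if config.lam is None:
        results = []
        for lam in config.lam_grid:
            g, res = gcv_at(lam)
            path.append((lam, g, res[2]))
            results.append((lam, g, res))
        gmin = min(g for _, g, _ in results)
        # Occam tie-break: GCV differences below 0.5% are selection noise,
        # so take the smoothest model (largest lambda) within that band
        lam, _, (beta, mu, edf, it, ok) = max(
            (r for r in results if r[1] <= gmin * 1.005),
            key=lambda r: r[0])
    else:
        lam = config.lam
        _, (beta, mu, edf, it, ok) = gcv_at(lam)
    if not ok:
        warnings.warn(f"PIRLS did not converge in {config.max_iter} "
                      "iterations", RuntimeWarning, stacklevel=2)

    if config.family == "gamma":
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = 2.0 * float(np.sum(-np.log(y / mu) + (y - mu) / mu))
        pearson = float(np.sum(((y - mu) / mu) ** 2))
    else:
        dev = pearson = float(np.sum((y - mu) ** 2))
    dispersion = pearson / max(n - edf, 1.0)
    cov = dispersion * np.linalg.inv(X.T @ X + lam * S)
    return TrajectoryFit(
        config=config, feature=feature, genotypes=list(genotypes),
        knots=knots, Z=Z, beta=beta, cov=cov, lam=float(lam), edf=edf,
        dispersion=dispersion, deviance=dev,
        div_range=(float(div.min()), float(div.max())), n_obs=n, n_iter=it,
        converged=ok,
        gcv_path=pd.DataFrame(path, columns=["lam", "gcv", "edf"])
        if path else None)


def genotype_difference(fit: TrajectoryFit, div_grid) -> pd.DataFrame:
    """Link-scale genotype contrast with 95% CI and significance flags.

    Positive values mean the second genotype (alphabetically) exceeds the
    first.  Grid points outside the fitted DIV range are refused.
    """
    if len(fit.genotypes) < 2:
        raise ValueError("fit contains a single genotype")
    div_grid = np.atleast_1d(np.asarray(div_grid, dtype=float))
    lo, hi = fit.div_range
    if div_grid.min() < lo - 1e-9 or div_grid.max() > hi + 1e-9:
        raise ValueError(
            f"grid extends outside the fitted DIV range [{lo}, {hi}]; "
            "extrapolation refused")
    g0, g1 = fit.genotypes[0], fit.genotypes[1]
    c = fit._row(div_grid, g1) - fit._row(div_grid, g0)
    delta = c @ fit.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", c, fit.cov, c))
    z = fit.config.z_crit
    out = pd.DataFrame({
        "div": div_grid, "difference": delta, "se": se,
        "lo": delta - z * se, "hi": delta + z * se})
    out["significant"] = (out["lo"] > 0) | (out["hi"] < 0)
    return out
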
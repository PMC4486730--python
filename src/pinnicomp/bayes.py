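"""Bayesian linear-model fits by Metropolis-within-Gibbs.

Three model shapes are supported, matching the calibrations the
composition pipelines need: a simple linear regression (traditional vs
modified blubber volume), a shared-slope regression with per-site
intercepts (ultrasound instrument cross-calibration), and a
heteroscedastic logit regression whose residual SD grows with the water
ratio (proportion fat vs proportion water).

All three are Gaussian likelihoods with uniform priors on the
coefficients and a uniform prior (> 0) on the inverse error variance.
The sampler is a one-parameter-at-a-time Gaussian random-walk
Metropolis with step sizes adapted during burn-in to a 0.3-0.5
acceptance rate; the precision parameter is updated on the log scale
(with the Jacobian term in the acceptance ratio) so that chains mix
across orders of magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegressionSpec",
    "PosteriorSamples",
    "fit_simple",
    "fit_shared_slope",
    "fit_logit_water_fat",
    "diagnostics",
]


@dataclass
class RegressionSpec:
    """Chain settings and prior bounds for one regression fit.

    Prior bounds are data-scaled by default: each coefficient gets a
    uniform prior centered on its least-squares estimate and spanning
    ``prior_scale`` times the larger of the estimate's magnitude and its
    standard error.
    """

    n_chains: int = 3
    iterations: int = 2000  # kept draws per chain
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    prior_scale: float = 100.0
    adapt_window: int = 50

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.iterations < 1 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("invalid chain settings")


@dataclass
class PosteriorSamples:
    """Posterior draws and summaries for one fitted regression."""

    names: list
    chains: list  # one (kept, p) array per chain
    acceptance: np.ndarray = field(default=None)

    @property
    def draws(self) -> np.ndarray:
        """Pooled draws, shape (n_chains * kept, p)."""
        return np.concatenate(self.chains, axis=0)

    def mean(self) -> dict:
        m = self.draws.mean(axis=0)
        return dict(zip(self.names, m))

    def sd(self) -> dict:
        s = self.draws.std(axis=0, ddof=1)
        return dict(zip(self.names, s))

    def interval(self, level: float = 0.95) -> dict:
        lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
        q = np.percentile(self.draws, [lo, hi], axis=0)
        return {n: (q[0, i], q[1, i]) for i, n in enumerate(self.names)}

    def correlations(self) -> np.ndarray:
        """Pairwise posterior parameter correlations."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.corrcoef(self.draws, rowvar=False)

    def lag1_autocorrelation(self) -> np.ndarray:
        """Lag-1 autocorrelation, shape (n_chains, p)."""
        out = np.zeros((len(self.chains), len(self.names)))
        for c, ch in enumerate(self.chains):
            for j in range(ch.shape[1]):
                x = ch[:, j]
                v = x.var()
                if v == 0:
                    out[c, j] = 0.0
                else:
                    x0 = x - x.mean()
                    out[c, j] = float(np.dot(x0[:-1], x0[1:]) / (v * (x.size - 1)))
        return out

    def summary(self) -> dict:
        return {
            "mean": self.mean(),
            "sd": self.sd(),
            "interval_95": self.interval(),
            "n_draws": int(self.draws.shape[0]),
            "n_chains": len(self.chains),
        }


# ---------------------------------------------------------------------------
# Core sampler on the sufficient statistics of a Gaussian linear model


def _ols(xmat: np.ndarray, y: np.ndarray):
    """Least-squares point fit: coefficients, SEs, residual variance."""
    n, p = xmat.shape
    gram = xmat.T @ xmat
    if np.linalg.cond(gram) > 1e12:
        raise np.linalg.LinAlgError("singular or near-singular design")
    beta, *_ = np.linalg.lstsq(xmat, y, rcond=None)
    resid = y - xmat @ beta
    ssr = float(resid @ resid)
    dof = max(n - p, 1)
    s2 = ssr / dof
    var_scale = max(s2, 1e-12 * max(float(y.var()), 1e-12))
    se = np.sqrt(np.diag(np.linalg.inv(gram)) * var_scale)
    return beta, se, s2, var_scale


def _mwg_gaussian_linear(xmat: np.ndarray, y: np.ndarray, names: list,
                         spec: RegressionSpec) -> PosteriorSamples:
    """Metropolis-within-Gibbs for y = X beta + eps, eps ~ N(0, 1/tau).

    Works on the sufficient statistics (X'X, X'y, y'y), so each
    likelihood evaluation is O(p^2) regardless of n.
    """
    n, p = xmat.shape
    if n < 3:
        raise ValueError("need at least 3 data points")
    beta_hat, se, s2, var_scale = _ols(xmat, y)

    # Orthogonalized frame: X = Q R, theta = R beta.  Q'Q = I makes the
    # coefficient components a-posteriori independent given tau, so the
    # one-at-a-time random walk mixes well even when the original
    # slope/intercept posterior is strongly correlated.  Draws are mapped
    # back through R^-1, and the uniform prior box is enforced in the
    # original parameterization.
    q, r = np.linalg.qr(xmat)
    r_inv = np.linalg.inv(r)
    qty = q.T @ y
    yty = float(y @ y)
    theta_hat = r @ beta_hat

    def ssr_of(theta):
        return yty - 2.0 * float(theta @ qty) + float(theta @ theta)

    # data-scaled uniform prior bounds (on the original coefficients)
    half = spec.prior_scale * np.maximum(np.abs(beta_hat), se)
    half = np.maximum(half, 1e-6)
    lo, hi = beta_hat - half, beta_hat + half

    def in_box(theta):
        beta = r_inv @ theta
        return bool(np.all((beta >= lo) & (beta <= hi)))

    tau_hat = 1.0 / var_scale
    tau_lo, tau_hi = tau_hat / 1e8, tau_hat * 1e8
    theta_sd = np.sqrt(var_scale)

    rng = np.random.default_rng(spec.seed)
    kept_chains = []
    accept_all = np.zeros((spec.n_chains, p + 1))
    n_iter = spec.burn_in + spec.iterations * spec.thin

    for _c in range(spec.n_chains):
        theta = theta_hat + rng.standard_normal(p) * theta_sd
        tau = float(np.clip(tau_hat * np.exp(rng.standard_normal()), tau_lo, tau_hi))
        ssr = ssr_of(theta)
        steps = np.full(p, max(theta_sd * 2.4, 1e-8))
        ltau_step = 0.5
        acc = np.zeros(p + 1)
        win = np.zeros(p + 1)
        kept = np.empty((spec.iterations, p + 1))
        k = 0
        for it in range(n_iter):
            # coefficient updates (orthogonalized frame)
            for j in range(p):
                prop = theta.copy()
                prop[j] += rng.standard_normal() * steps[j]
                if in_box(prop):
                    ssr_p = ssr_of(prop)
                    if np.log(rng.random()) < -0.5 * tau * (ssr_p - ssr):
                        theta, ssr = prop, ssr_p
                        acc[j] += 1
                        win[j] += 1
            # precision update on the log scale (uniform prior on tau itself,
            # hence a Jacobian factor tau'/tau in the acceptance ratio)
            ltau_p = np.log(tau) + rng.standard_normal() * ltau_step
            tau_p = np.exp(ltau_p)
            if tau_lo <= tau_p <= tau_hi:
                logr = (0.5 * n * (ltau_p - np.log(tau))
                        - 0.5 * (tau_p - tau) * ssr
                        + (ltau_p - np.log(tau)))
                if np.log(rng.random()) < logr:
                    tau = tau_p
                    acc[p] += 1
                    win[p] += 1
            # adaptation during burn-in only
            if it < spec.burn_in and (it + 1) % spec.adapt_window == 0:
                rate = win / spec.adapt_window
                scale = np.where(rate > 0.5, 1.4, np.where(rate < 0.3, 0.7, 1.0))
                steps *= scale[:p]
                ltau_step *= scale[p]
                win[:] = 0
            if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
                kept[k, :p] = r_inv @ theta
                kept[k, p] = 1.0 / tau  # report sigma^2
                k += 1
        kept_chains.append(kept[:k])
        accept_all[_c] = acc / n_iter
    return PosteriorSamples(names=list(names) + ["sigma2"], chains=kept_chains,
                            acceptance=accept_all)


# ---------------------------------------------------------------------------
# Model shapes


def fit_simple(x, y, spec: RegressionSpec | None = None) -> PosteriorSamples:
    """Posterior of Y = beta0 + beta1 * X + eps, eps ~ N(0, sigma2)."""
    spec = spec or RegressionSpec()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with at least 3 points")
    if x.var() == 0:
        raise ValueError("degenerate x (zero variance): slope not identifiable")
    xmat = np.column_stack([np.ones_like(x), x])
    return _mwg_gaussian_linear(xmat, y, ["beta0", "beta1"], spec)


def fit_shared_slope(x, y, site, spec: RegressionSpec | None = None) -> PosteriorSamples:
    """Posterior of Y = beta_u * X + beta_site + eps (one slope, per-site intercepts)."""
    spec = spec or RegressionSpec()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    site = np.asarray(site)
    if not (x.shape == y.shape == site.shape):
        raise ValueError("x, y, site must have the same length")
    levels = list(dict.fromkeys(site.tolist()))  # first-appearance order
    if len(levels) < 2:
        raise ValueError("need at least 2 sites")
    counts = {s: int((site == s).sum()) for s in levels}
    for s, c in counts.items():
        if c < 2:
            warnings.warn(f"site {s!r} has fewer than 2 points", UserWarning)
    dummies = np.column_stack([(site == s).astype(float) for s in levels])
    xmat = np.column_stack([x, dummies])
    names = ["beta_u"] + [f"beta_{s}" for s in levels]
    return _mwg_gaussian_linear(xmat, y, names, spec)


def fit_logit_water_fat(p_h2o, p_fat, spec: RegressionSpec | None = None) -> PosteriorSamples:
    """Posterior of logit(P_fat) = alpha0 + alpha1 * x + x * eps.

    x is the water ratio P_H2O / (1 - P_H2O); the residual enters scaled
    by x, so its SD expands at higher water ratios.  Dividing through by
    x turns the fit into an ordinary weighted Gaussian regression.
    """
    spec = spec or RegressionSpec()
    p_h2o = np.asarray(p_h2o, dtype=float)
    p_fat = np.asarray(p_fat, dtype=float)
    if p_h2o.shape != p_fat.shape or p_h2o.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.any((p_h2o <= 0) | (p_h2o >= 1) | (p_fat <= 0) | (p_fat >= 1)):
        raise ValueError("proportions must lie strictly in (0, 1)")
    x = p_h2o / (1.0 - p_h2o)
    z = np.log(p_fat / (1.0 - p_fat))
    # z / x = alpha0 * (1/x) + alpha1 + eps  — homoscedastic in the scaled frame
    xmat = np.column_stack([1.0 / x, np.ones_like(x)])
    samples = _mwg_gaussian_linear(xmat, z / x, ["alpha0", "alpha1"], spec)
    return samples


# ---------------------------------------------------------------------------
# Convergence diagnostics


def diagnostics(samples: PosteriorSamples, lag1_threshold: float = 0.9,
                discrepancy_threshold: float = 0.5) -> dict:
    """Mixing and convergence report.

    Checks lag-1 autocorrelation per parameter per chain and the spread
    of per-chain posterior means in units of the pooled posterior SD.
    """
    n_chains = len(samples.chains)
    if n_chains < 2:
        warnings.warn("single chain: between-chain diagnostics unavailable",
                      UserWarning)
    lag1 = samples.lag1_autocorrelation()
    pooled_sd = samples.draws.std(axis=0, ddof=1)
    pooled_sd = np.where(pooled_sd == 0, 1.0, pooled_sd)
    chain_means = np.array([c.mean(axis=0) for c in samples.chains])
    discrepancy = (chain_means.max(axis=0) - chain_means.min(axis=0)) / pooled_sd
    ok_lag1 = bool(np.all(lag1 <= lag1_threshold))
    ok_disc = bool(np.all(discrepancy <= discrepancy_threshold)) if n_chains > 1 else None
    return {
        "lag1": {n: lag1[:, j].tolist() for j, n in enumerate(samples.names)},
        "between_chain_discrepancy_sd": dict(zip(samples.names, discrepancy)),
        "lag1_ok": ok_lag1,
        "between_chain_ok": ok_disc,
        "passed": ok_lag1 and (ok_disc is not False),
    }
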
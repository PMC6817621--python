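"""Bayesian combination of text scores and item responses.

The standardized text score y_n of person n enters latent-trait estimation
through a latent regression

    theta_n = b0 + b1 * y_n + eps_n,     eps_n ~ N(0, sigma^2),

equivalently an informative prior theta_n | y_n ~ N(b0 + b1 y_n, sigma^2)
multiplied into the 2PL likelihood. Two modes are provided:

* two-stage: fix (b0, b1, sigma^2) and score persons by the same quadrature
  engine as the standard EAP (:func:`hybrid_eap`);
* joint: fit {theta_1..N, b0, b1, sigma^2} by Metropolis-within-Gibbs with
  item parameters fixed (:func:`fit_latent_regression`), mirroring a
  general-purpose MCMC fit with 5,000 iterations and 1,000 burn-in.

Regression-block priors are weakly informative conventional choices:
b0, b1 ~ N(0, 100) and sigma^2 ~ Inv-Gamma(0.01, 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .irt_core import (
    ItemBank,
    LatentPosterior,
    QuadratureGrid,
    ResponseMatrix,
    eap_estimate,
    irf_2pl,
)

__all__ = [
    "LatentRegression",
    "McmcConfig",
    "McmcResult",
    "text_prior",
    "hybrid_eap",
    "fit_latent_regression",
]


@dataclass(frozen=True)
class LatentRegression:
    """Latent regression coefficients: intercept b0, slope b1 on the
    standardized text score, residual variance sigma2 > 0."""

    b0: float
    b1: float
    sigma2: float

    def __post_init__(self):
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings. Defaults: 5,000 iterations with 1,000 burn-in,
    2 chains for the split-chain convergence diagnostic."""

    n_iter: int = 5000
    burn_in: int = 1000
    seed: int = 0
    n_chains: int = 2
    init_step: float = 1.0
    prior_coef_var: float = 100.0   # N(0, 100) on b0 and b1
    prior_ig_shape: float = 0.01    # Inv-Gamma(0.01, 0.01) on sigma2
    prior_ig_scale: float = 0.01

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must be in [0, n_iter)")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


def text_prior(reg: LatentRegression, y: float) -> tuple[float, float]:
    """Informative normal prior for theta given text score y: (b0 + b1*y, sigma2)."""
    return reg.b0 + reg.b1 * float(y), reg.sigma2


def hybrid_eap(
    responses,
    bank: ItemBank,
    reg: LatentRegression,
    y: float,
    grid: QuadratureGrid | None = None,
) -> LatentPosterior:
    """EAP latent trait under the text-informed prior.

    Identical quadrature engine to the standard estimate; only the prior
    changes, so with (b0, b1, sigma2) = (0, 0, 1) the two coincide exactly.
    """
    mean, var = text_prior(reg, y)
    post = eap_estimate(responses, bank, prior_mean=mean, prior_var=var, grid=grid)
    spec = f"text(b0={reg.b0:g}, b1={reg.b1:g}, s2={reg.sigma2:g}, y={float(y):g})"
    return LatentPosterior(post.theta_hat, post.post_sd, spec)


@dataclass(frozen=True)
class McmcResult:
    """Posterior summaries from the joint fit.

    ``reg`` holds posterior means of (b0, b1, sigma2); ``coef_sd`` their
    posterior SDs; ``theta_hat``/``theta_sd`` per-person posterior summaries;
    ``draws`` the retained coefficient draws stacked as (chain, draw, 3);
    ``theta_draws`` retained latent-trait draws (chain, draw, n_persons).
    """

    reg: LatentRegression
    coef_sd: np.ndarray
    theta_hat: np.ndarray
    theta_sd: np.ndarray
    acceptance: np.ndarray
    rhat: dict[str, float]
    draws: np.ndarray = field(repr=False)
    theta_draws: np.ndarray = field(repr=False)

    def credible_interval(self, param: str, level: float = 0.95) -> tuple[float, float]:
        idx = {"b0": 0, "b1": 1, "sigma2": 2}[param]
        flat = self.draws[..., idx].ravel()
        tail = (1.0 - level) / 2.0
        return tuple(np.quantile(flat, [tail, 1.0 - tail]))

    def theta_mcse(self, n_batches: int = 50) -> np.ndarray:
        """Monte-Carlo standard error of each theta posterior mean.

        Batch-means estimator: retained draws in each chain are cut into
        consecutive batches; the MCSE is the SD of batch means over all
        chains divided by sqrt(#batches), which absorbs autocorrelation at
        the batch scale.
        """
        chains, kept, n_persons = self.theta_draws.shape
        per_chain = max(2, n_batches // chains)
        usable = (kept // per_chain) * per_chain
        batches = self.theta_draws[:, :usable].reshape(
            chains, per_chain, usable // per_chain, n_persons
        ).mean(axis=2)
        batches = batches.reshape(chains * per_chain, n_persons)
        return batches.std(axis=0, ddof=1) / np.sqrt(batches.shape[0])


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor on (chain, draw) draws."""
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + b / (w * n)))


def fit_latent_regression(
    responses: ResponseMatrix,
    bank: ItemBank,
    y: np.ndarray,
    cfg: McmcConfig = McmcConfig(),
    fix_reg: LatentRegression | None = None,
) -> McmcResult:
    """Joint Metropolis-within-Gibbs fit of latent traits and regression block.

    Per iteration: each theta_n is updated by random-walk Metropolis against
    the 2PL likelihood times its N(b0 + b1 y_n, sigma2) prior (step size
    adapted toward ~40% acceptance during burn-in); (b0, b1) then sigma2 are
    drawn from their conjugate conditionals given the current thetas. Runs
    are reproducible given the config seed.

    With ``fix_reg`` the coefficient block is held at the given values and
    only the latent traits are sampled (two-stage scoring by MCMC, directly
    comparable to the quadrature estimate under the same prior).
    """
    y = np.asarray(y, dtype=float)
    if responses.n_persons < 2:
        raise ValueError("need at least 2 persons to fit the latent regression")
    if y.shape != (responses.n_persons,):
        raise ValueError("y must have one score per person")
    if not np.all(np.isfinite(y)):
        raise ValueError("text scores must be finite")
    if tuple(responses.item_ids) != tuple(bank.item_ids):
        raise ValueError("response matrix items must match the bank")

    x = responses.values  # (N, I), may contain NaN
    seen = ~np.isnan(x)
    x0 = np.nan_to_num(x)
    n_persons = responses.n_persons
    n_keep = cfg.n_iter - cfg.burn_in

    def loglik(theta: np.ndarray) -> np.ndarray:
        # vectorized over persons
        p = irf_2pl(theta[:, None], bank.alpha[None, :], bank.beta[None, :])
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll = np.where(seen, x0 * np.log(p) + (1 - x0) * np.log1p(-p), 0.0)
        return ll.sum(axis=1)

    design = np.column_stack([np.ones(n_persons), y])  # (N, 2)
    xtx = design.T @ design

    all_draws = np.empty((cfg.n_chains, n_keep, 3))
    all_theta = np.empty((cfg.n_chains, n_keep, n_persons))
    acc_rates = np.empty((cfg.n_chains, n_persons))

    root = np.random.SeedSequence(cfg.seed)
    for chain, child in enumerate(root.spawn(cfg.n_chains)):
        rng = np.random.default_rng(child)
        theta = rng.normal(0.0, 1.0, n_persons)
        if fix_reg is not None:
            b = np.array([fix_reg.b0, fix_reg.b1])
            sigma2 = fix_reg.sigma2
        else:
            b = np.zeros(2)
            sigma2 = 1.0
        step = np.full(n_persons, cfg.init_step)
        accepted = np.zeros(n_persons)
        ll_cur = loglik(theta)

        for it in range(cfg.n_iter):
            # --- theta block: random-walk Metropolis, all persons at once
            prop = theta + rng.normal(0.0, step)
            ll_prop = loglik(prop)
            mu = design @ b
            logr = (
                ll_prop - ll_cur
                - 0.5 * ((prop - mu) ** 2 - (theta - mu) ** 2) / sigma2
            )
            take = np.log(rng.uniform(size=n_persons)) < logr
            theta = np.where(take, prop, theta)
            ll_cur = np.where(take, ll_prop, ll_cur)
            accepted += take

            if cfg.burn_in and it < cfg.burn_in and (it + 1) % 100 == 0:
                rate = accepted / (it + 1)
                step *= np.where(rate < 0.3, 0.8, np.where(rate > 0.5, 1.25, 1.0))
                step = np.clip(step, 0.05, 10.0)

            if fix_reg is None:
                # --- (b0, b1): conjugate normal given theta, sigma2
                prec = xtx / sigma2 + np.eye(2) / cfg.prior_coef_var
                cov = np.linalg.inv(prec)
                mean = cov @ (design.T @ theta) / sigma2
                b = rng.multivariate_normal(mean, cov, method="cholesky")

                # --- sigma2: conjugate inverse-gamma
                resid = theta - design @ b
                shape = cfg.prior_ig_shape + n_persons / 2.0
                scale = cfg.prior_ig_scale + 0.5 * resid @ resid
                sigma2 = scale / rng.gamma(shape)

            if it >= cfg.burn_in:
                k = it - cfg.burn_in
                all_draws[chain, k] = (b[0], b[1], sigma2)
                all_theta[chain, k] = theta

        acc_rates[chain] = accepted / cfg.n_iter

    flat = all_draws.reshape(-1, 3)
    reg = LatentRegression(*flat.mean(axis=0))
    rhat = {
        name: _split_rhat(all_draws[..., i])
        for i, name in enumerate(("b0", "b1", "sigma2"))
    }
    return McmcResult(
        reg=reg,
        coef_sd=flat.std(axis=0, ddof=1),
        theta_hat=all_theta.reshape(-1, n_persons).mean(axis=0),
        theta_sd=all_theta.reshape(-1, n_persons).std(axis=0, ddof=1),
        acceptance=acc_rates.mean(axis=0),
        rhat=rhat,
        draws=all_draws,
        theta_draws=all_theta,
    )
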
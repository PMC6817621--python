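"""Two-parameter logistic (2PL) IRT model: response functions, likelihoods,
item/test information, and EAP latent-trait estimation by fixed quadrature.

The 2PL item response function for a dichotomous symptom item i is

    P(X_i = 1 | theta) = exp[alpha_i (theta - beta_i)] / (1 + exp[alpha_i (theta - beta_i)])

on the logit scale (no D = 1.7 scaling). ``alpha`` is the discrimination,
``beta`` the difficulty (symptom severity); the Rasch model is the special
case alpha = 1 for every item. Latent traits are estimated as posterior means
(EAP) under a normal prior via deterministic Gauss-rectangle quadrature on an
equally spaced grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "ItemBank",
    "ResponseMatrix",
    "LatentPosterior",
    "QuadratureGrid",
    "irf_2pl",
    "response_loglik",
    "item_information",
    "test_information",
    "eap_estimate",
]

_PROB_FLOOR = 1e-12  # clamp inside log-likelihood


@dataclass(frozen=True)
class ItemBank:
    """Fixed 2PL item parameters with metadata.

    Parameters
    ----------
    item_ids : item labels, unique.
    alpha : discriminations, all > 0.
    beta : difficulties on the logit scale.
    se_alpha, se_beta : calibration standard errors (metadata only).
    validity_r : optional criterion correlations (metadata only).
    """

    item_ids: tuple[str, ...]
    alpha: np.ndarray
    beta: np.ndarray
    se_alpha: np.ndarray | None = None
    se_beta: np.ndarray | None = None
    validity_r: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "item_ids", tuple(str(i) for i in self.item_ids))
        for name in ("alpha", "beta", "se_alpha", "se_beta", "validity_r"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))
        if len(set(self.item_ids)) != len(self.item_ids):
            dupes = sorted({i for i in self.item_ids if self.item_ids.count(i) > 1})
            raise ValueError(f"duplicate item ids: {dupes}")
        if self.alpha.shape != (len(self.item_ids),) or self.beta.shape != self.alpha.shape:
            raise ValueError("alpha/beta must be 1-d and match item_ids length")
        if np.any(self.alpha <= 0):
            bad = [self.item_ids[i] for i in np.flatnonzero(self.alpha <= 0)]
            raise ValueError(f"non-positive discrimination for items: {bad}")

    def __len__(self) -> int:
        return len(self.item_ids)

    def subset(self, ids: Sequence[str]) -> "ItemBank":
        """Bank restricted to ``ids``, in the given order."""
        idx = [self.item_ids.index(i) for i in ids]
        pick = lambda a: None if a is None else a[idx]
        return ItemBank(
            tuple(self.item_ids[i] for i in idx),
            self.alpha[idx], self.beta[idx],
            pick(self.se_alpha), pick(self.se_beta), pick(self.validity_r),
        )

    def as_rasch(self) -> "ItemBank":
        """Same difficulties with every discrimination fixed at 1."""
        return ItemBank(self.item_ids, np.ones(len(self)), self.beta,
                        self.se_alpha, self.se_beta, self.validity_r)


@dataclass(frozen=True)
class ResponseMatrix:
    """Persons x items dichotomous responses; NaN marks missing."""

    person_ids: tuple[str, ...]
    item_ids: tuple[str, ...]
    values: np.ndarray  # float array, cells in {0, 1, nan}

    def __post_init__(self):
        object.__setattr__(self, "person_ids", tuple(str(p) for p in self.person_ids))
        object.__setattr__(self, "item_ids", tuple(str(i) for i in self.item_ids))
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.person_ids), len(self.item_ids)):
            raise ValueError("values shape must be (n_persons, n_items)")
        ok = np.isnan(v) | (v == 0) | (v == 1)
        if not ok.all():
            raise ValueError("response cells must be 0, 1 or missing")
        object.__setattr__(self, "values", v)

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    def subset_items(self, ids: Sequence[str]) -> "ResponseMatrix":
        idx = [self.item_ids.index(i) for i in ids]
        return ResponseMatrix(self.person_ids, tuple(ids), self.values[:, idx])


@dataclass(frozen=True)
class LatentPosterior:
    """Posterior summary for one person's latent trait."""

    theta_hat: float
    post_sd: float
    prior_spec: str = "normal(0, 1)"

    def __post_init__(self):
        if not self.post_sd > 0:
            raise ValueError("post_sd must be positive")


@dataclass(frozen=True)
class QuadratureGrid:
    """Equally spaced quadrature nodes for posterior integrals.

    Defaults to 121 points spanning prior mean +/- 6 prior SDs, which for the
    standard normal prior is the conventional [-6, 6] grid. A custom grid must
    cover at least 99.999% of the prior mass, otherwise the posterior
    integrals silently lose tail weight and an error is raised instead.
    """

    lo: float = -6.0
    hi: float = 6.0
    n: int = 121
    points: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if not (np.isfinite(self.lo) and np.isfinite(self.hi) and self.lo < self.hi):
            raise ValueError("invalid grid bounds")
        if self.n < 5:
            raise ValueError("grid needs at least 5 points")
        object.__setattr__(self, "points", np.linspace(self.lo, self.hi, self.n))

    @classmethod
    def for_prior(cls, mean: float, sd: float, n: int = 121, span: float = 6.0) -> "QuadratureGrid":
        return cls(mean - span * sd, mean + span * sd, n)

    def check_covers(self, mean: float, sd: float) -> None:
        mass = norm.cdf(self.hi, mean, sd) - norm.cdf(self.lo, mean, sd)
        if mass < 0.99999:
            raise ValueError(
                f"quadrature grid [{self.lo}, {self.hi}] covers only {mass:.6f} "
                f"of the N({mean}, {sd**2}) prior mass"
            )


def irf_2pl(theta, alpha, beta):
    """2PL probability of a positive ("yes") response.

    Vectorized over any broadcastable combination of arguments. ``alpha = 0``
    degenerates to a flat 0.5; the Rasch model is ``alpha = 1``.
    """
    theta, alpha, beta = np.asarray(theta), np.asarray(alpha), np.asarray(beta)
    if np.any(alpha < 0):
        raise ValueError("discrimination must be non-negative")
    out = expit(alpha * (theta - beta))
    return float(out) if out.ndim == 0 else out


def item_information(theta, alpha, beta):
    """Fisher information of one 2PL item: alpha^2 * P * (1 - P); peaks at theta = beta."""
    p = irf_2pl(theta, alpha, beta)
    return np.asarray(alpha) ** 2 * p * (1.0 - p)


def test_information(theta, bank: ItemBank):
    """Test information: sum of item informations over the bank (0 for an empty bank)."""
    if len(bank) == 0:
        return np.zeros_like(np.asarray(theta, dtype=float)) if np.ndim(theta) else 0.0
    theta = np.asarray(theta, dtype=float)
    info = item_information(theta[..., None], bank.alpha, bank.beta).sum(axis=-1)
    return float(info) if info.ndim == 0 else info


def response_loglik(theta, responses, bank: ItemBank):
    """Bernoulli log-likelihood of a response pattern under the 2PL.

    ``theta`` may be a scalar or a grid; ``responses`` is aligned to the bank
    and may contain NaN for items not administered (skipped). Probabilities
    are clamped to [1e-12, 1 - 1e-12] before taking logs.
    """
    x = np.asarray(responses, dtype=float)
    if x.shape != (len(bank),):
        raise ValueError("responses must align with the bank")
    seen = ~np.isnan(x)
    if not np.all((x[seen] == 0) | (x[seen] == 1)):
        raise ValueError("responses must be 0/1 or missing")
    theta = np.asarray(theta, dtype=float)
    if not seen.any():
        return np.zeros(theta.shape) if theta.ndim else 0.0
    p = irf_2pl(theta[..., None], bank.alpha[seen], bank.beta[seen])
    p = np.clip(p, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    ll = (x[seen] * np.log(p) + (1.0 - x[seen]) * np.log1p(-p)).sum(axis=-1)
    return float(ll) if ll.ndim == 0 else ll


def eap_estimate(
    responses,
    bank: ItemBank,
    prior_mean: float = 0.0,
    prior_var: float = 1.0,
    grid: QuadratureGrid | None = None,
) -> LatentPosterior:
    """Expected-a-posteriori latent trait under a normal prior.

    Computes posterior mean and SD of theta by normalized quadrature on an
    equally spaced grid. With no (or all-missing) responses the posterior is
    the prior, recovered to grid accuracy; an explicitly empty pattern returns
    the prior moments exactly.
    """
    if prior_var <= 0:
        raise ValueError("prior variance must be positive")
    sd = float(np.sqrt(prior_var))
    if grid is None:
        grid = QuadratureGrid.for_prior(prior_mean, sd)
    grid.check_covers(prior_mean, sd)
    spec = f"normal({prior_mean:g}, {prior_var:g})"

    x = np.asarray(responses, dtype=float)
    if x.size == 0 or np.all(np.isnan(x)):
        return LatentPosterior(float(prior_mean), sd, spec)

    t = grid.points
    logw = response_loglik(t, x, bank) + norm.logpdf(t, prior_mean, sd)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    mean = float(w @ t)
    var = float(w @ (t - mean) ** 2)
    return LatentPosterior(mean, float(np.sqrt(var)), spec)
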
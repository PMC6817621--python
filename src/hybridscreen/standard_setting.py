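"""Standard setting: locating a diagnostic cutoff on the latent scale.

Three methods are implemented, to be averaged for the operational cutoff:

1. midpoint of the two group medians;
2. contrasting groups — logistic regression of diagnosed status on the
   latent score, returning the score where the fitted probability of the
   positive class is 50% (i.e. -intercept/slope);
3. Bayesian discriminant — normal densities fitted per group, returning the
   boundary where prior-weighted densities are equal (zero-one loss).

The operational screening cutoff used downstream, -0.15, comes from an
external large-sample calibration and is consumed as configuration rather
than recomputed from small cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = [
    "GroupScores",
    "cutoff_midpoint_medians",
    "cutoff_contrasting_groups",
    "cutoff_bayes_discriminant",
    "cutoff_average",
]


@dataclass(frozen=True)
class GroupScores:
    """Latent scores split by structured-interview diagnosis."""

    scores_pos: np.ndarray
    scores_neg: np.ndarray

    def __post_init__(self):
        for name in ("scores_pos", "scores_neg"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.size == 0:
                raise ValueError(f"{name} must be nonempty")
            object.__setattr__(self, name, v)


def cutoff_midpoint_medians(g: GroupScores) -> float:
    """Midpoint between the medians of the diagnosed and non-diagnosed groups."""
    return float((np.median(g.scores_pos) + np.median(g.scores_neg)) / 2.0)


def cutoff_contrasting_groups(g: GroupScores) -> float:
    """Contrasting-groups cutoff via logistic regression.

    Fits P(positive | score) by maximum likelihood and returns the score where
    the fitted probability is 0.5 (linear predictor zero). Complete separation
    makes the MLE non-finite and raises a ValueError.
    """
    x = np.concatenate([g.scores_pos, g.scores_neg])
    lab = np.concatenate([np.ones(g.scores_pos.size), np.zeros(g.scores_neg.size)])
    if g.scores_pos.min() > g.scores_neg.max() or g.scores_neg.min() > g.scores_pos.max():
        raise ValueError("groups are completely separated; logistic MLE is not finite")
    model = sm.GLM(lab, sm.add_constant(x), family=sm.families.Binomial())
    try:
        fit = model.fit(maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels failure modes
        raise ValueError(f"logistic fit failed: {exc}") from exc
    intercept, slope = fit.params
    if not np.all(np.isfinite(fit.params)) or abs(slope) > 1e6:
        raise ValueError("logistic estimates are non-finite (quasi-separation)")
    if slope == 0:
        raise ValueError("zero slope: score carries no group information")
    return float(-intercept / slope)


def cutoff_bayes_discriminant(
    g: GroupScores, priors: tuple[float, float] | None = None
) -> float:
    """Zero-one-loss decision boundary of the Gaussian discriminant.

    Normal densities N(mu, sigma^2) are fitted per group by sample moments;
    priors default to group proportions. The boundary solves
    P_pos * phi(x; mu_pos, sd_pos) = P_neg * phi(x; mu_neg, sd_neg). With
    unequal variances the quadratic may have two roots; the root between the
    group means is returned (or the root nearest that interval if none lies
    within it).
    """
    pos, neg = g.scores_pos, g.scores_neg
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each group needs >= 2 values to fit a normal density")
    m1, s1 = pos.mean(), pos.std(ddof=1)
    m2, s2 = neg.mean(), neg.std(ddof=1)
    if s1 == 0 or s2 == 0:
        raise ValueError("zero within-group variance; densities degenerate")
    if priors is None:
        p1 = pos.size / (pos.size + neg.size)
        p2 = 1.0 - p1
    else:
        p1, p2 = priors

    # equate log densities: quadratic A x^2 + B x + C = 0
    a_coef = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b_coef = m1 / s1**2 - m2 / s2**2
    c_coef = (
        m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2)
        + math.log(p1 / p2) + math.log(s2 / s1)
    )
    if abs(a_coef) < 1e-14:  # equal variances: linear boundary, closed form
        if b_coef == 0:
            raise ValueError("identical group densities; boundary undefined")
        return float(-c_coef / b_coef)
    roots = np.roots([a_coef, b_coef, c_coef])
    roots = roots[np.isreal(roots)].real
    if roots.size == 0:
        raise ValueError("no real decision boundary for these densities")
    lo, hi = min(m1, m2), max(m1, m2)
    inside = roots[(roots >= lo) & (roots <= hi)]
    if inside.size:
        return float(inside[0])
    # fall back to the root nearest the between-means interval
    dist = np.minimum(np.abs(roots - lo), np.abs(roots - hi))
    return float(roots[np.argmin(dist)])


def cutoff_average(c1: float, c2: float, c3: float) -> float:
    """Arithmetic mean of the three standard-setting cutoffs."""
    cs = np.array([c1, c2, c3], dtype=float)
    if not np.all(np.isfinite(cs)):
        raise ValueError("all three cutoffs must be finite")
    return float(cs.mean())
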
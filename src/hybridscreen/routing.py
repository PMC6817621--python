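"""Information-based adaptive item administration.

Items are ranked once by Fisher information evaluated at the diagnostic
cutoff (default theta = -0.15) and administered in descending order, the item
selection logic of a screening-oriented adaptive test. SE-vs-test-length
curves compare latent-trait posterior SDs with and without the text-score
prior; the crossing of the with-prior curve below the full-length
without-prior SE gives the number of items saved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hybrid_bayes import LatentRegression, hybrid_eap
from .irt_core import ItemBank, ResponseMatrix, eap_estimate, item_information

__all__ = [
    "RoutingPlan",
    "SeCurve",
    "DEFAULT_CUTOFF",
    "rank_items",
    "se_curve",
    "items_saved",
]

#: Diagnostic cutoff on the latent scale from the external large-sample calibration.
DEFAULT_CUTOFF = -0.15


@dataclass(frozen=True)
class RoutingPlan:
    """Item administration order: descending information at the cutoff,
    ties broken by bank order."""

    cutoff_theta: float
    ranked_items: tuple[str, ...]
    tie_rule: str = "bank order"


@dataclass(frozen=True)
class SeCurve:
    """Mean posterior SD over a cohort as the first m ranked items are
    administered, m = 1..M."""

    mean_sd: np.ndarray
    with_text_prior: bool

    def __post_init__(self):
        object.__setattr__(self, "mean_sd", np.asarray(self.mean_sd, dtype=float))

    def __len__(self) -> int:
        return self.mean_sd.size


def rank_items(bank: ItemBank, cutoff_theta: float = DEFAULT_CUTOFF) -> RoutingPlan:
    """Rank items by descending information at the cutoff (stable ties)."""
    if len(bank) == 0:
        raise ValueError("bank must be nonempty")
    info = item_information(cutoff_theta, bank.alpha, bank.beta)
    order = np.argsort(-info, kind="stable")
    return RoutingPlan(cutoff_theta, tuple(bank.item_ids[i] for i in order))


def se_curve(
    responses: ResponseMatrix,
    bank: ItemBank,
    plan: RoutingPlan,
    reg: LatentRegression | None = None,
    y: np.ndarray | None = None,
    prior_mean: float = 0.0,
    prior_var: float = 1.0,
) -> SeCurve:
    """Mean posterior SD after each additional ranked item.

    With ``reg`` and ``y`` supplied each person is estimated under their
    text-informed prior N(b0 + b1*y_n, sigma^2); otherwise under
    N(prior_mean, prior_var), the standard N(0, 1) prior by default. Passing
    a large ``prior_var`` gives an effectively prior-free (likelihood-driven)
    reference curve. Deterministic given inputs.
    """
    if responses.n_persons == 0:
        raise ValueError("cohort must be nonempty")
    use_text = reg is not None
    if use_text:
        y = np.asarray(y, dtype=float)
        if y.shape != (responses.n_persons,):
            raise ValueError("y must have one score per person")

    means = np.empty(len(plan.ranked_items))
    for m in range(1, len(plan.ranked_items) + 1):
        ids = plan.ranked_items[:m]
        sub_bank = bank.subset(ids)
        sub_resp = responses.subset_items(ids)
        sds = np.empty(responses.n_persons)
        for n in range(responses.n_persons):
            pattern = sub_resp.values[n]
            if use_text:
                post = hybrid_eap(pattern, sub_bank, reg, y[n])
            else:
                post = eap_estimate(pattern, sub_bank,
                                    prior_mean=prior_mean, prior_var=prior_var)
            sds[n] = post.post_sd
        means[m - 1] = sds.mean()
    return SeCurve(means, use_text)


def items_saved(curve_with: SeCurve, curve_without: SeCurve) -> tuple[int, int]:
    """Test-length saving from the text prior.

    Returns (m_star, saving): m_star is the smallest number of ranked items at
    which the with-prior mean SE falls to or below the full-length
    without-prior mean SE; saving = M - m_star. If even the full with-prior
    test stays above that benchmark, m_star = M and saving = 0.
    """
    if len(curve_with) != len(curve_without):
        raise ValueError("curves must have the same length")
    m_total = len(curve_without)
    benchmark = curve_without.mean_sd[-1]
    below = np.flatnonzero(curve_with.mean_sd <= benchmark)
    m_star = int(below[0]) + 1 if below.size else m_total
    return m_star, m_total - m_star
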
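"""Synthetic cohorts with the statistical structure of the hybrid screening
study: a two-class diagnosed population (prevalence 34/99), class-conditional
unigram narratives, standardized text scores, latent traits generated by the
latent regression theta = b0 + b1*y + eps with (b0, b1, sigma^2) =
(-0.41, 1.44, 3.57), and 2PL item responses under the fixed 21-item bank.

The original respondent data is not public; these generators emulate its
moment structure so every stage of the pipeline is testable. Narratives are
bags of stems, not natural language: class separation is a single tilt
parameter on marker-word rates, calibrated so that PSM accuracy on held-out
synthetic narratives lands in the mid-0.8 regime reported for real
narratives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hybrid_bayes import LatentRegression
from .irt_core import ItemBank, ResponseMatrix, irf_2pl
from .porter import stem
from .psm_text import TokenizedDoc, psm_score, standardize_scores, train_psm

__all__ = [
    "CohortSpec",
    "Cohort",
    "Study",
    "PTSD_MARKERS",
    "NONPTSD_MARKERS",
    "gen_cohort",
    "gen_item_responses",
    "gen_narratives",
    "gen_study",
]

#: Marker stems most associated with each diagnostic class in prior
#: narrative-classification work (Porter-stemmed at import time).
PTSD_MARKERS = tuple(stem(w) for w in (
    "rape", "flashback", "fire", "involve", "avoid",
    "incident", "date", "tower", "men", "fault",
))
NONPTSD_MARKERS = tuple(stem(w) for w in (
    "test", "hardly", "tumor", "tight", "excite",
    "evil", "pleasure", "vision", "frantic", "funny",
))
#: Shared filler stems carrying no class signal.
NEUTRAL_STEMS = tuple(stem(w) for w in (
    "remember", "night", "sleep", "work", "family", "friend", "time", "year",
    "day", "life", "feel", "think", "happen", "event", "moment", "place",
    "people", "thing", "home", "week", "talk", "walk", "drive", "house",
    "story", "word", "hand", "room", "door", "street",
))


@dataclass(frozen=True)
class CohortSpec:
    """Generation settings for one synthetic cohort.

    ``y_class_gap`` is the separation (in pre-standardization SD units)
    between the diagnosed and non-diagnosed text-score distributions;
    ``text_effect`` is the log-rate tilt applied to marker stems in the
    class-conditional unigram distributions (0 = no signal).
    """

    n: int = 99
    prevalence: float = 34 / 99
    reg: LatentRegression = field(default_factory=lambda: LatentRegression(-0.41, 1.44, 3.57))
    y_class_gap: float = 2.0
    text_effect: float = 0.12
    min_length: int = 150
    mean_extra_length: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.n < 2:
            raise ValueError("cohort size must be >= 2")
        if self.min_length < 1:
            raise ValueError("min_length must be positive")


@dataclass(frozen=True)
class Cohort:
    """Direct draw of (diagnosis, text score, latent trait) triples."""

    is_ptsd: np.ndarray  # bool
    y: np.ndarray        # standardized text score
    theta: np.ndarray    # latent trait


@dataclass(frozen=True)
class Study:
    """Full synthetic study: narratives scored by an in-sample PSM, latent
    traits generated from the resulting standardized scores, and 2PL
    responses. Mirrors the observable layout of the real cohort."""

    person_ids: tuple[str, ...]
    is_ptsd: np.ndarray
    docs: list[TokenizedDoc]
    raw_scores: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    responses: ResponseMatrix


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec_seed, stream)))


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Sample diagnoses, class-shifted standardized text scores, and latent
    traits from the latent regression. Pure function of the spec (seeded)."""
    rng = _rng(spec.seed, 0)
    is_ptsd = rng.uniform(size=spec.n) < spec.prevalence
    shift = np.where(is_ptsd, spec.y_class_gap / 2.0, -spec.y_class_gap / 2.0)
    z = rng.normal(0.0, 1.0, spec.n) + shift
    y = standardize_scores(z)
    eps = rng.normal(0.0, np.sqrt(spec.reg.sigma2), spec.n)
    theta = spec.reg.b0 + spec.reg.b1 * y + eps
    return Cohort(is_ptsd, y, theta)


def gen_item_responses(thetas, bank: ItemBank, seed: int = 0) -> ResponseMatrix:
    """Bernoulli 2PL responses, independent across items given theta."""
    thetas = np.asarray(thetas, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    p = irf_2pl(thetas[:, None], bank.alpha[None, :], bank.beta[None, :])
    values = (rng.uniform(size=p.shape) < p).astype(float)
    person_ids = tuple(f"P{i:04d}" for i in range(thetas.size))
    return ResponseMatrix(person_ids, bank.item_ids, values)


def _class_distributions(text_effect: float) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    vocab = PTSD_MARKERS + NONPTSD_MARKERS + NEUTRAL_STEMS
    k_pos, k_neg = len(PTSD_MARKERS), len(NONPTSD_MARKERS)
    w1 = np.concatenate([
        np.full(k_pos, np.exp(text_effect)),
        np.full(k_neg, np.exp(-text_effect)),
        np.ones(len(NEUTRAL_STEMS)),
    ])
    w2 = np.concatenate([
        np.full(k_pos, np.exp(-text_effect)),
        np.full(k_neg, np.exp(text_effect)),
        np.ones(len(NEUTRAL_STEMS)),
    ])
    return w1 / w1.sum(), w2 / w2.sum(), vocab


def gen_narratives(labels, spec: CohortSpec, seed: int | None = None) -> list[TokenizedDoc]:
    """Class-conditional unigram narratives as bags of stems.

    ``labels`` may be booleans (True = PTSD) or class codes 1/2. Document
    lengths are min_length plus a Poisson excess, echoing the recommendation
    that narratives exceed 150 words.
    """
    labels = np.asarray(labels)
    if labels.dtype == bool:
        classes = np.where(labels, 1, 2)
    else:
        classes = labels.astype(int)
        if not np.all((classes == 1) | (classes == 2)):
            raise ValueError("labels must be booleans or class codes 1/2")
    rng = _rng(spec.seed if seed is None else seed, 2)
    p1, p2, vocab = _class_distributions(spec.text_effect)
    vocab_arr = np.array(vocab)
    docs = []
    for i, cls in enumerate(classes):
        length = spec.min_length + rng.poisson(spec.mean_extra_length)
        probs = p1 if cls == 1 else p2
        tokens = vocab_arr[rng.choice(len(vocab_arr), size=length, p=probs)]
        docs.append(TokenizedDoc(f"P{i:04d}", tuple(tokens), int(cls)))
    return docs


def gen_study(spec: CohortSpec, bank: ItemBank) -> Study:
    """Generate a complete synthetic study.

    Diagnoses are drawn at the spec prevalence; narratives from the
    class-conditional unigram model; a PSM is trained on the cohort's own
    labeled narratives and its standardized log-ratio scores become the text
    covariate y; latent traits follow theta = b0 + b1*y + eps; item responses
    follow the 2PL under the supplied bank. By construction the latent
    regression holds exactly in the generating process, so fitting it to the
    generated data is a parameter-recovery exercise.
    """
    rng = _rng(spec.seed, 3)
    is_ptsd = rng.uniform(size=spec.n) < spec.prevalence
    # degenerate single-class draws cannot train a PSM; force one of each
    if is_ptsd.all():
        is_ptsd[0] = False
    elif not is_ptsd.any():
        is_ptsd[0] = True
    docs = gen_narratives(is_ptsd, spec)
    model = train_psm(docs)
    raw = np.array([psm_score(model, d).raw for d in docs])
    y = standardize_scores(raw)
    eps = rng.normal(0.0, np.sqrt(spec.reg.sigma2), spec.n)
    theta = spec.reg.b0 + spec.reg.b1 * y + eps
    responses = gen_item_responses(theta, bank, seed=spec.seed)
    return Study(
        person_ids=tuple(d.id for d in docs),
        is_ptsd=is_ptsd,
        docs=docs,
        raw_scores=raw,
        y=y,
        theta=theta,
        responses=responses,
    )
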
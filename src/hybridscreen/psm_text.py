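"""Product score model (PSM) for trauma self-narrative classification.

The PSM is a naive-Bayes-style binary classifier over stemmed unigram
keywords. Each class c has a smoothed per-keyword rate (count_w + a) / len(C_c)
estimated from a pooled training corpus; a narrative's class score S_c is the
class prior times the product of those rates over the narrative's scored
keyword occurrences. The classifier thresholds the natural-log ratio
log(S1/S2) at a constant b (default 0); the log-ratio itself is the "text
score" that downstream modules standardize and use as a latent-trait prior
covariate.

Preprocessing: lowercase, expand common English contractions, drop tokens
containing digits, drop stop-list words, Porter-stem the remainder.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from .porter import stem

__all__ = [
    "TokenizedDoc",
    "PsmModel",
    "TextScore",
    "DEFAULT_STOPWORDS",
    "preprocess",
    "train_psm",
    "psm_score",
    "standardize_scores",
]

#: Default stop list: the scikit-learn English list (applied before stemming).
DEFAULT_STOPWORDS = frozenset(ENGLISH_STOP_WORDS)

#: Common contractions expanded before tokenization; the expansions are
#: ordinary stop words and are removed by the stop filter.
CONTRACTIONS: Mapping[str, str] = {
    "i'm": "i am", "i've": "i have", "i'd": "i would", "i'll": "i will",
    "isn't": "is not", "aren't": "are not", "wasn't": "was not",
    "weren't": "were not", "don't": "do not", "doesn't": "does not",
    "didn't": "did not", "can't": "can not", "couldn't": "could not",
    "won't": "will not", "wouldn't": "would not", "shouldn't": "should not",
    "haven't": "have not", "hasn't": "has not", "hadn't": "had not",
    "it's": "it is", "that's": "that is", "there's": "there is",
    "he's": "he is", "she's": "she is", "they're": "they are",
    "we're": "we are", "you're": "you are", "let's": "let us",
}

_WORD_RE = re.compile(r"[a-z0-9']+")
_HAS_DIGIT = re.compile(r"\d")
_CONTRACTION_RE = re.compile(
    r"\b(" + "|".join(re.escape(c) for c in sorted(
        ("i'm", "i've", "i'd", "i'll", "isn't", "aren't", "wasn't", "weren't",
         "don't", "doesn't", "didn't", "can't", "couldn't", "won't",
         "wouldn't", "shouldn't", "haven't", "hasn't", "hadn't", "it's",
         "that's", "there's", "he's", "she's", "they're", "we're", "you're",
         "let's"), key=len, reverse=True)) + r")\b"
)


@dataclass(frozen=True)
class TokenizedDoc:
    """A preprocessed narrative: ordered stem tokens plus an optional class label
    (1 = PTSD, 2 = non-PTSD)."""

    id: str
    tokens: tuple[str, ...]
    label: int | None = None

    def __post_init__(self):
        if self.label is not None and self.label not in (1, 2):
            raise ValueError("label must be 1 (PTSD), 2 (non-PTSD) or None")
        object.__setattr__(self, "tokens", tuple(self.tokens))


def preprocess(text: str, stoplist: Iterable[str] = DEFAULT_STOPWORDS,
               doc_id: str = "", label: int | None = None) -> TokenizedDoc:
    """Normalize a raw narrative into a TokenizedDoc.

    Deterministic: lowercase -> expand contractions -> tokenize on letters ->
    drop tokens with digits (digits never enter the token regex) and stop
    words -> Porter-stem. Empty input yields an empty token list.
    """
    stopset = set(stoplist)
    lowered = _CONTRACTION_RE.sub(lambda m: CONTRACTIONS[m.group(0)], text.lower())
    tokens = []
    for raw in _WORD_RE.findall(lowered):
        word = raw.strip("'")
        if not word or _HAS_DIGIT.search(word) or word in stopset:
            continue
        tokens.append(stem(word))
    return TokenizedDoc(doc_id, tuple(tokens), label)


@dataclass(frozen=True)
class PsmModel:
    """Trained product score model.

    ``u`` and ``v`` map each vocabulary stem to its occurrence count in the
    pooled PTSD (class 1) and non-PTSD (class 2) corpora; ``len1``/``len2``
    are the corresponding corpus lengths (total keyword occurrences), so
    sum(u) == len1 and sum(v) == len2 by construction. ``a`` is the additive
    smoothing constant and ``b`` the decision threshold on log(S1/S2).
    """

    vocab: frozenset[str]
    u: Mapping[str, int]
    v: Mapping[str, int]
    len1: int
    len2: int
    prior1: float
    prior2: float
    a: float = 0.5
    b: float = 0.0

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("smoothing constant a must be positive")
        if not math.isclose(self.prior1 + self.prior2, 1.0, abs_tol=1e-9):
            raise ValueError("class priors must sum to 1")
        if self.len1 <= 0 or self.len2 <= 0:
            raise ValueError("both training corpora must contain keywords")
        if sum(self.u.values()) != self.len1 or sum(self.v.values()) != self.len2:
            raise ValueError("corpus lengths must equal the keyword count totals")

    # -- persistence ---------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "vocab": sorted(self.vocab),
            "u": {w: int(self.u[w]) for w in sorted(self.vocab)},
            "v": {w: int(self.v[w]) for w in sorted(self.vocab)},
            "len1": self.len1, "len2": self.len2,
            "prior1": self.prior1, "prior2": self.prior2,
            "a": self.a, "b": self.b,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PsmModel":
        d = json.loads(Path(path).read_text())
        return cls(frozenset(d["vocab"]), d["u"], d["v"], d["len1"], d["len2"],
                   d["prior1"], d["prior2"], d["a"], d["b"])


@dataclass(frozen=True)
class TextScore:
    """PSM output for one narrative: the log-ratio score, its cohort-standardized
    form (filled in by :func:`standardize_scores`), and the class decision."""

    raw: float
    predicted_class: int
    standardized: float | None = None


def train_psm(
    docs: Sequence[TokenizedDoc],
    vocab: Iterable[str] | None = None,
    a: float = 0.5,
    b: float = 0.0,
    priors: tuple[float, float] | None = None,
) -> PsmModel:
    """Train a PSM from labeled tokenized narratives.

    Keyword counts use token multiplicity (multinomial counting). If ``vocab``
    is omitted the union of observed stems is used. Class priors default to
    the training document proportions; pass ``priors`` to fix them (e.g. to a
    known population prevalence).
    """
    labeled = [d for d in docs if d.label is not None]
    n1 = sum(1 for d in labeled if d.label == 1)
    n2 = sum(1 for d in labeled if d.label == 2)
    if n1 == 0 or n2 == 0:
        raise ValueError("training requires documents from both classes")

    if vocab is None:
        vocab = {t for d in labeled for t in d.tokens}
    vocab = frozenset(vocab)

    c1: Counter[str] = Counter()
    c2: Counter[str] = Counter()
    for d in labeled:
        target = c1 if d.label == 1 else c2
        target.update(t for t in d.tokens if t in vocab)
    len1, len2 = sum(c1.values()), sum(c2.values())
    if len1 == 0 or len2 == 0:
        raise ValueError("a class corpus contains no vocabulary keywords")

    if priors is None:
        prior1 = n1 / (n1 + n2)
        prior2 = n2 / (n1 + n2)
    else:
        prior1, prior2 = priors

    u = {w: c1.get(w, 0) for w in vocab}
    v = {w: c2.get(w, 0) for w in vocab}
    return PsmModel(vocab, u, v, len1, len2, prior1, prior2, a, b)


def psm_score(model: PsmModel, doc: TokenizedDoc) -> TextScore:
    """Score one narrative: raw = log(S1/S2) computed in the log domain.

    Each occurrence of a vocabulary keyword contributes one smoothed-rate
    factor per class; out-of-vocabulary tokens are skipped. The class decision
    is 1 iff raw > b (ties go to class 2).
    """
    raw = math.log(model.prior1 / model.prior2)
    for tok in doc.tokens:
        if tok in model.vocab:
            raw += math.log((model.u[tok] + model.a) / model.len1)
            raw -= math.log((model.v[tok] + model.a) / model.len2)
    return TextScore(raw, 1 if raw > model.b else 2)


def standardize_scores(raws: Sequence[float]) -> np.ndarray:
    """Z-score raw text scores over the analyzed cohort (n-1 SD); order preserved."""
    x = np.asarray(raws, dtype=float)
    if x.size < 2:
        raise ValueError("standardization needs at least 2 scores")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("text scores have zero variance; cannot standardize")
    return (x - x.mean()) / sd
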
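"""Product score model: preprocessing, training, log-ratio scoring,
standardization, and the brute-force product-domain oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridscreen.porter import stem
from hybridscreen.psm_text import (
    PsmModel,
    TokenizedDoc,
    preprocess,
    psm_score,
    standardize_scores,
    train_psm,
)

C1_DOC = TokenizedDoc("c1", ("nightmar", "flashback", "fear", "nightmar"), 1)
C2_DOC = TokenizedDoc("c2", ("happi", "calm", "fear", "sleep"), 2)


class TestPreprocess:
    def test_stems_inflections_drops_digits_and_stopwords(self):
        doc = preprocess("I have nightmares, nightmaring at 3am")
        assert doc.tokens == ("nightmar", "nightmar")

    def test_porter_reference_pairs(self):
        pairs = {
            "caresses": "caress", "ponies": "poni", "relational": "relat",
            "hopping": "hop", "happy": "happi", "terrified": "terrifi",
            "memories": "memori", "nightmare": "nightmar", "sky": "sky",
            "sensibiliti": "sensibl", "triplicate": "triplic",
            "adjustment": "adjust", "dependent": "depend", "rate": "rate",
        }
        assert {w: stem(w) for w in pairs} == pairs

    def test_empty_text_gives_empty_tokens(self):
        assert preprocess("").tokens == ()

    def test_stoplist_closure(self):
        assert preprocess("The the THE", stoplist={"the"}).tokens == ()

    def test_contractions_removed(self):
        doc = preprocess("I'm scared, isn't it awful")
        assert doc.tokens == ("scare", "aw")  # only content words survive


class TestTrainPsm:
    def test_counts_lengths_priors(self):
        m = train_psm([C1_DOC, C2_DOC])
        assert m.u["nightmar"] == 2 and m.v["nightmar"] == 0
        assert m.u["fear"] == 1 and m.v["fear"] == 1
        assert m.len1 == m.len2 == 4
        assert m.prior1 == m.prior2 == 0.5

    def test_identical_docs_symmetric_counts(self):
        a = TokenizedDoc("a", ("x", "y", "x"), 1)
        b = TokenizedDoc("b", ("x", "y", "x"), 2)
        m = train_psm([a, b])
        assert m.u == m.v and m.len1 == m.len2

    def test_single_class_is_untrainable(self):
        with pytest.raises(ValueError, match="both classes"):
            train_psm([C1_DOC])

    def test_vocab_restriction_and_fixed_priors(self):
        m = train_psm([C1_DOC, C2_DOC], vocab={"fear"}, priors=(0.3, 0.7))
        assert m.len1 == m.len2 == 1
        assert (m.prior1, m.prior2) == (0.3, 0.7)

    def test_json_roundtrip(self, tmp_path):
        m = train_psm([C1_DOC, C2_DOC])
        p = tmp_path / "psm.json"
        m.to_json(p)
        m2 = PsmModel.from_json(p)
        assert m2 == PsmModel(m.vocab, dict(m.u), dict(m.v), m.len1, m.len2,
                              m.prior1, m.prior2, m.a, m.b)


class TestPsmScore:
    def test_hand_evaluated_log_ratio(self):
        m = train_psm([C1_DOC, C2_DOC])
        s = psm_score(m, TokenizedDoc("q", ("nightmar", "fear")))
        # S1 = 0.5 * (2.5/4)(1.5/4) = 0.1171875; S2 = 0.5 * (0.5/4)(1.5/4)
        assert s.raw == pytest.approx(math.log(5), abs=1e-12)
        assert s.predicted_class == 1

    def test_symmetric_model_ties_to_class_2(self):
        a = TokenizedDoc("a", ("x", "y"), 1)
        b = TokenizedDoc("b", ("x", "y"), 2)
        m = train_psm([a, b])
        s = psm_score(m, TokenizedDoc("q", ("x", "y", "z")))
        assert s.raw == 0.0 and s.predicted_class == 2

    def test_empty_doc_scores_prior_ratio_only(self):
        m = train_psm([C1_DOC, C2_DOC])
        assert psm_score(m, TokenizedDoc("q", ())).raw == 0.0

    def test_appending_keyword_adds_its_log_weight(self):
        m = train_psm([C1_DOC, C2_DOC])
        base = psm_score(m, TokenizedDoc("q", ("fear",))).raw
        longer = psm_score(m, TokenizedDoc("q", ("fear", "nightmar"))).raw
        expected = math.log((m.u["nightmar"] + m.a) / m.len1) - math.log(
            (m.v["nightmar"] + m.a) / m.len2)
        assert longer - base == pytest.approx(expected, abs=1e-12)


_VOCAB = ["w%d" % i for i in range(6)]
_doc_strategy = st.lists(st.sampled_from(_VOCAB), min_size=0, max_size=10)


@settings(derandomize=True, max_examples=60)
@given(
    d1=st.lists(st.sampled_from(_VOCAB), min_size=1, max_size=10),
    d2=st.lists(st.sampled_from(_VOCAB), min_size=1, max_size=10),
    q=_doc_strategy,
)
def test_log_score_matches_direct_product(d1, d2, q):
    """Log-domain score equals log(S1/S2) with S_c computed by direct
    multiplication of smoothed rates (small vocab, no underflow)."""
    m = train_psm([TokenizedDoc("a", d1, 1), TokenizedDoc("b", d2, 2)])
    s1, s2 = m.prior1, m.prior2
    for tok in q:
        if tok not in m.vocab:
            continue  # out-of-vocabulary tokens are skipped by the scorer
        s1 *= (m.u[tok] + m.a) / m.len1
        s2 *= (m.v[tok] + m.a) / m.len2
    got = psm_score(m, TokenizedDoc("q", q)).raw
    assert got == pytest.approx(math.log(s1 / s2), abs=1e-9)


@settings(derandomize=True, max_examples=60)
@given(
    d1=st.lists(st.sampled_from(_VOCAB), min_size=1, max_size=10),
    d2=st.lists(st.sampled_from(_VOCAB), min_size=1, max_size=10),
    q=_doc_strategy,
)
def test_swapping_training_classes_negates_score(d1, d2, q):
    m = train_psm([TokenizedDoc("a", d1, 1), TokenizedDoc("b", d2, 2)])
    m_swapped = train_psm([TokenizedDoc("a", d1, 2), TokenizedDoc("b", d2, 1)])
    doc = TokenizedDoc("q", q)
    assert psm_score(m, doc).raw == pytest.approx(-psm_score(m_swapped, doc).raw,
                                                  abs=1e-9)


class TestStandardize:
    def test_symmetric_triple(self):
        assert standardize_scores([1, 2, 3]) == pytest.approx([-1, 0, 1])

    def test_moments_and_idempotence(self):
        rng = np.random.default_rng(5)
        x = rng.normal(3, 7, 50)
        z = standardize_scores(x)
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1, abs=1e-12)
        assert standardize_scores(z) == pytest.approx(z)
        assert np.argsort(z).tolist() == np.argsort(x).tolist()

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            standardize_scores([5, 5, 5])
        with pytest.raises(ValueError):
            standardize_scores([1.0])
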
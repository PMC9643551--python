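"""Beam-search behavior: letter floor, whitespace insertion, vocabulary
pruning, finalization rules, and equivalence with exhaustive enumeration."""

import math
from dataclasses import replace

import numpy as np
import pytest

from silentspell.beam_search import (
    BeamCandidate,
    DecoderConfig,
    advance_beam,
    brute_force_decode,
    decode_sequence,
    finalize_sentence,
    recompute_score,
)
from silentspell.classifier import HAND, ClassProbabilities, ProbabilitySequence
from silentspell.language_model import Vocabulary, fit_ngram_lm

LETTERS = [chr(ord("a") + i) for i in range(26)]
CS = LETTERS + [HAND]


def probs_for(weights: dict[str, float], floor=1e-9) -> ClassProbabilities:
    v = np.full(len(CS), floor)
    for k, w in weights.items():
        v[CS.index(k)] = w
    return ClassProbabilities(v / v.sum(), CS)


def seq(*steps) -> ProbabilitySequence:
    return ProbabilitySequence([probs_for(s) for s in steps])


@pytest.fixture
def simple_vocab():
    return Vocabulary(["at", "an", "to", "a", "i"])


@pytest.fixture
def simple_lm(simple_vocab):
    return fit_ngram_lm(["a to an at", "i to at", "at an a"], simple_vocab)


class TestAdvanceBeam:
    def test_single_word_vocab_then_space_extension(self, simple_lm):
        vocab = Vocabulary(["a"])
        cfg = DecoderConfig(beam_width=10)
        beam = advance_beam([], probs_for({"a": 1.0}), simple_lm, vocab, cfg)
        assert beam[0].text == "a"
        beam = advance_beam(beam, probs_for({"a": 1.0}), simple_lm, vocab, cfg)
        # after the space was inserted the next "a" starts a new word
        assert beam[0].text == "a a"

    def test_letter_below_floor_never_appears(self, simple_vocab, simple_lm):
        cfg = DecoderConfig(beam_width=500, letter_floor=0.001)
        weights = {c: 0.99 / 3 for c in "ati"}
        weights["o"] = 0.0005  # below the floor
        beam = advance_beam([], probs_for(weights), simple_lm, simple_vocab, cfg)
        assert beam
        assert all("o" not in c.text for c in beam)

    def test_invalid_prefixes_pruned(self, simple_vocab, simple_lm):
        cfg = DecoderConfig(beam_width=500)
        beam = advance_beam([], probs_for({"a": 0.5, "z": 0.5}), simple_lm,
                            simple_vocab, cfg)
        texts = {c.text for c in beam}
        assert texts == {"a", "a "}  # "z" extends no vocabulary word

    def test_empty_beam_fallback_keeps_neural_ranking(self, simple_lm):
        vocab = Vocabulary(["qqq"])
        cfg = DecoderConfig(beam_width=3)
        beam = advance_beam([], probs_for({"a": 0.7, "b": 0.3}), simple_lm, vocab, cfg)
        assert beam  # never empty
        assert beam[0].text == "a"

    def test_spaces_only_from_extension(self, simple_vocab, simple_lm, decoder_cfg):
        """Every space in any candidate follows a completed vocabulary word."""
        rng = np.random.default_rng(0)
        beam = []
        for _ in range(6):
            w = {c: rng.random() for c in "atoin"}
            beam = advance_beam(beam, probs_for(w), simple_lm, simple_vocab, decoder_cfg)
            for cand in beam:
                for word in cand.text.split(" ")[:-1]:
                    assert simple_vocab.is_word(word)

    def test_wider_beam_never_worse(self, simple_vocab, simple_lm):
        rng = np.random.default_rng(1)
        steps = [{c: rng.random() for c in "atoin"} for _ in range(4)]
        best = []
        for b in (2, 5, 50, 500):
            cfg = DecoderConfig(beam_width=b)
            beam = []
            for s in steps:
                beam = advance_beam(beam, probs_for(s), simple_lm, simple_vocab, cfg)
            # the invariant concerns vocabulary-consistent beams (the
            # empty-beam fallback deliberately bypasses pruning)
            if all(simple_vocab.is_prefix(c.partial) for c in beam):
                best.append(beam[0].combined(cfg))
        assert len(best) >= 2
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(best, best[1:]))


class TestFinalization:
    def test_hand_probability_at_threshold_does_not_finalize(self, simple_lm):
        beam = [BeamCandidate(text="at ", words=("at",), lm_logp=-1.0)]
        cfg = DecoderConfig()
        assert finalize_sentence(beam, 0.79, simple_lm, None, cfg) is None
        assert finalize_sentence(beam, 0.80, simple_lm, None, cfg) is None
        assert finalize_sentence(beam, 0.81, simple_lm, None, cfg) == "at"

    def test_incomplete_candidates_removed_before_rescoring(self, simple_lm):
        complete = BeamCandidate(text="at ", words=("at",), lm_logp=-1.0,
                                 neural_logp=-10.0)
        partial = BeamCandidate(text="at a n x", words=("at",), partial="anx",
                                neural_logp=0.0)
        cfg = DecoderConfig()
        out = finalize_sentence([partial, complete], 0.95, simple_lm, None, cfg)
        assert out == "at"

    def test_zero_rescore_weight_keeps_ranking(self, simple_lm):
        # a rescorer that would invert the ranking has no effect at weight 0
        flip = lambda s: -100.0 if s == "at" else 0.0
        from silentspell.language_model import make_rescorer

        cands = [
            BeamCandidate(text="at ", words=("at",), neural_logp=-1.0),
            BeamCandidate(text="an ", words=("an",), neural_logp=-2.0),
        ]
        cfg = replace(DecoderConfig(), alpha=0.0, alpha_rescore=0.0,
                      use_sentence_end=False)
        assert finalize_sentence(cands, 0.9, simple_lm, make_rescorer(flip), cfg) == "at"
        cfg_on = replace(cfg, alpha_rescore=1.0)
        assert finalize_sentence(cands, 0.9, simple_lm, make_rescorer(flip), cfg_on) == "an"

    def test_incomplete_vs_complete_final_word(self, simple_lm):
        """'hi ther' is removed while 'hi there' survives, even without a
        trailing space."""
        vocab = Vocabulary(["hi", "there"])
        lm = fit_ngram_lm(["hi there"], vocab)
        ther = BeamCandidate(text="hi ther", words=("hi",), partial="ther",
                             neural_logp=0.0)
        there = BeamCandidate(text="hi there", words=("hi",), partial="there",
                              neural_logp=-5.0)
        cfg = DecoderConfig()
        out = finalize_sentence([ther, there], 0.9, lm, None, cfg, vocab=vocab)
        assert out == "hi there"

    def test_all_incomplete_falls_back_with_warning(self, simple_lm):
        cands = [BeamCandidate(text="at a", words=("at",), partial="a")]
        cfg = DecoderConfig()
        with pytest.warns(UserWarning):
            out = finalize_sentence(cands, 0.9, simple_lm, None, cfg)
        assert out == "at"


class TestBruteForce:
    def test_single_cycle_ranking(self, simple_lm):
        vocab = Vocabulary(["a", "i"])
        cfg = DecoderConfig(alpha=0.0, beta=0.0)
        ranking = brute_force_decode(seq({"a": 0.9, "i": 0.1}), simple_lm, vocab, cfg)
        assert ranking[0][0] == "a"

    def test_uniform_lm_ranking_is_probability_product_order(self, simple_vocab, simple_lm):
        cfg = DecoderConfig(alpha=0.0, beta=0.0)
        rng = np.random.default_rng(2)
        steps = [{c: rng.random() for c in "atoi"} for _ in range(3)]
        ranking = brute_force_decode(seq(*steps), simple_lm, simple_vocab, cfg)
        X = seq(*steps)
        for text, score in ranking:
            assert math.isclose(score, recompute_score(text, X, simple_lm, cfg),
                                abs_tol=1e-9)
        scores = [s for _, s in ranking]
        assert scores == sorted(scores, reverse=True)

    def test_guard_refuses_large_instances(self, simple_lm):
        vocab = Vocabulary(["w" * (i + 1) for i in range(60)])
        with pytest.raises(ValueError):
            brute_force_decode(seq({"a": 1.0}), simple_lm, vocab, DecoderConfig(),
                               max_vocab=50)

    def test_beam_matches_enumeration_on_random_instances(self, simple_lm):
        """Oracle equivalence on seeded random small instances."""
        rng = np.random.default_rng(3)
        words = ["at", "an", "to", "a", "i", "it", "tan", "ant", "ton", "tin"]
        for trial in range(25):
            vocab = Vocabulary(rng.choice(words, size=rng.integers(2, 8),
                                          replace=False).tolist())
            lm = simple_lm
            cfg = DecoderConfig(
                alpha=float(rng.uniform(0, 1)), beta=float(rng.uniform(0, 1.5)),
                beam_width=100000,
            )
            n_cycles = int(rng.integers(1, 5))
            steps = [{c: float(rng.random()) for c in "atoin"} for _ in range(n_cycles)]
            ranking = brute_force_decode(seq(*steps), lm, vocab, cfg)
            beam = []
            for s in steps:
                beam = advance_beam(beam, probs_for(s), lm, vocab, cfg)
            if not ranking:
                continue
            assert beam[0].text == ranking[0][0]
            assert math.isclose(beam[0].combined(cfg), ranking[0][1], abs_tol=1e-9)


class TestScoreDecomposition:
    def test_incremental_score_matches_recomputation(self, simple_vocab, simple_lm,
                                                     decoder_cfg):
        rng = np.random.default_rng(4)
        steps = [{c: float(rng.random()) for c in "atoin"} for _ in range(5)]
        X = seq(*steps)
        beam = []
        for s in X:
            beam = advance_beam(beam, s, simple_lm, simple_vocab, decoder_cfg)
        for cand in beam[:20]:
            assert math.isclose(
                cand.combined(decoder_cfg),
                recompute_score(cand.text, X, simple_lm, decoder_cfg),
                abs_tol=1e-9,
            )


class TestDecodeSequence:
    def test_hand_cycle_triggers_finalization(self, simple_vocab, simple_lm,
                                              decoder_cfg):
        X = ProbabilitySequence(
            [probs_for({"a": 0.95}), probs_for({"t": 0.95}),
             probs_for({HAND: 0.95})]
        )
        out = decode_sequence(X, simple_lm, simple_vocab, decoder_cfg)
        assert out["finalized"] and out["final_cycle"] == 2
        assert out["text"] == "at"

    def test_without_hand_cycle_not_finalized(self, simple_vocab, simple_lm,
                                              decoder_cfg):
        X = seq({"a": 0.95}, {"t": 0.95})
        out = decode_sequence(X, simple_lm, simple_vocab, decoder_cfg)
        assert not out["finalized"]
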
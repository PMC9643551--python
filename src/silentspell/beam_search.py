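"""Vocabulary-constrained beam search over per-cycle letter probabilities.

Each 2.5-s cycle yields classifier probabilities over 26 letters (code
words) plus the hand command.  Candidates are extended with each letter c
above a fixed probability floor, and with "c plus whitespace" at the same
probability, so spaces are inserted automatically and never produced by the
classifier.  Candidates whose words or partial final word fall outside the
vocabulary are discarded.  Each surviving candidate s is scored as

    p_nc(s | X_1:tau) * p_lm(s)^alpha * |s|^beta

in log space, where p_lm covers only the words preceding the final
whitespace and |s| is the completed-word count.  When the hand-command
probability exceeds its threshold, candidates with incomplete final words
are removed and the rest rescored with an additional pluggable
language-model term before the arg-max is finalized.

``brute_force_decode`` enumerates every vocabulary-consistent sequence on
small instances and scores it exactly: the beam search with a sufficiently
wide beam must reproduce its ranking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

from .classifier import HAND, ClassProbabilities, ProbabilitySequence, letter_for
from .language_model import NgramLM, RescorerInterface, Vocabulary, uniform_rescorer

__all__ = [
    "DecoderConfig",
    "BeamCandidate",
    "advance_beam",
    "finalize_sentence",
    "brute_force_decode",
    "decode_sequence",
    "recompute_score",
]


@dataclass
class DecoderConfig:
    """Beam-search hyperparameters (clinical values were tuned on held-out
    data and are not published; these are config-exposed defaults)."""

    alpha: float = 0.5           # LM-prior downweighting exponent
    beta: float = 1.0            # word-insertion bonus exponent
    beam_width: int = 200
    letter_floor: float = 0.001  # per-cycle letter probability floor
    alpha_rescore: float = 0.5   # exponent on the finalization rescorer
    hand_threshold: float = 0.80
    renormalize_letters: bool = False  # renormalize after excluding hand mass
    use_sentence_end: bool = True      # include p(</s>|.) at finalization

    def __post_init__(self) -> None:
        if self.beam_width < 1:
            raise ValueError("beam width must be >= 1")
        if not 0.0 <= self.letter_floor < 1.0:
            raise ValueError("letter_floor must lie in [0, 1)")
        if not 0.0 < self.hand_threshold < 1.0:
            raise ValueError("hand_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class BeamCandidate:
    """A partial sentence with its score components (all log-domain)."""

    text: str = ""
    neural_logp: float = 0.0
    lm_logp: float = 0.0               # over completed words only
    words: tuple[str, ...] = ()        # completed words
    partial: str = ""                  # partial final word ("" after a space)

    def combined(self, cfg: DecoderConfig) -> float:
        score = self.neural_logp + cfg.alpha * self.lm_logp
        if self.words:
            score += cfg.beta * math.log(len(self.words))
        return score


def _letter_probs(
    probs: ClassProbabilities, cfg: DecoderConfig
) -> dict[str, float]:
    """Per-letter probabilities from a 26/27-class vector."""
    out: dict[str, float] = {}
    for name, p in zip(probs.class_set, probs.probs):
        if name == HAND:
            continue
        letter = name if len(name) == 1 else letter_for(name)
        out[letter] = float(p)
    if cfg.renormalize_letters:
        total = sum(out.values())
        if total > 0:
            out = {c: p / total for c, p in out.items()}
    return out


def _extensions(
    cand: BeamCandidate,
    letters: dict[str, float],
    lm: NgramLM,
    vocab: Vocabulary,
    cfg: DecoderConfig,
) -> tuple[list[BeamCandidate], list[BeamCandidate]]:
    """(valid, all) extensions of one candidate for one cycle.

    The floor is applied to the raw per-cycle letter probability, once per
    letter; p_nc(c + space) equals p_nc(c).
    """
    valid: list[BeamCandidate] = []
    everything: list[BeamCandidate] = []
    for c, p in letters.items():
        if p <= cfg.letter_floor:
            continue
        logp = math.log(p)
        word = cand.partial + c
        # extension "l + c": partial word continues
        ext = replace(
            cand,
            text=cand.text + c,
            neural_logp=cand.neural_logp + logp,
            partial=word,
        )
        everything.append(ext)
        if vocab.is_prefix(word):
            valid.append(ext)
        # extension "l + c + whitespace": word completes
        ext_sp = BeamCandidate(
            text=cand.text + c + " ",
            neural_logp=cand.neural_logp + logp,
            lm_logp=cand.lm_logp + lm.logp(word, cand.words[-2:]),
            words=cand.words + (word,),
            partial="",
        )
        everything.append(ext_sp)
        if vocab.is_word(word):
            valid.append(ext_sp)
    return valid, everything


def _ranked(cands: list[BeamCandidate], cfg: DecoderConfig) -> list[BeamCandidate]:
    return sorted(cands, key=lambda c: (-c.combined(cfg), c.text))


def advance_beam(
    beam: list[BeamCandidate],
    probs: ClassProbabilities,
    lm: NgramLM,
    vocab: Vocabulary,
    cfg: DecoderConfig,
) -> list[BeamCandidate]:
    """One beam-search iteration; returns the top-B candidates.

    The best candidate (index 0) is the running display sentence.  If
    vocabulary pruning removes every extension, the top-B extensions by
    neural score alone are kept so the beam is never empty.
    """
    if not beam:
        beam = [BeamCandidate()]
    letters = _letter_probs(probs, cfg)
    valid: list[BeamCandidate] = []
    everything: list[BeamCandidate] = []
    for cand in beam:
        v, e = _extensions(cand, letters, lm, vocab, cfg)
        valid.extend(v)
        everything.extend(e)
    if not valid:
        fallback = sorted(everything, key=lambda c: (-c.neural_logp, c.text))
        return fallback[: cfg.beam_width]
    return _ranked(valid, cfg)[: cfg.beam_width]


def finalize_sentence(
    beam: list[BeamCandidate],
    hand_prob: float,
    lm: NgramLM,
    rescorer: RescorerInterface | None,
    cfg: DecoderConfig,
    vocab: Vocabulary | None = None,
) -> str | None:
    """Finalize if the hand-command probability exceeds its threshold.

    Returns None when not finalized.  Candidates whose final token is not a
    complete vocabulary word are dropped (a trailing partial that happens to
    be a complete word counts, with its conditional folded into the prior);
    survivors are rescored with the LM prior plus the rescorer term weighted
    by ``alpha_rescore``.
    """
    if hand_prob <= cfg.hand_threshold:
        return None
    if rescorer is None:
        rescorer = uniform_rescorer()
    complete: list[tuple[BeamCandidate, tuple[str, ...], float]] = []
    for c in beam:
        if c.partial == "":
            complete.append((c, c.words, c.lm_logp))
        elif vocab is not None and vocab.is_word(c.partial):
            complete.append((
                c,
                c.words + (c.partial,),
                c.lm_logp + lm.logp(c.partial, c.words[-2:]),
            ))
    if not complete:
        best = beam[0] if beam else BeamCandidate()
        text = " ".join(best.words)
        warnings.warn(
            "all candidates had incomplete final words at finalization; "
            "returning the best candidate truncated at its last completed word",
            stacklevel=2,
        )
        return text
    scored = {}
    for c, words, lm_logp in complete:
        if cfg.use_sentence_end and words:
            lm_logp += lm.logp("</s>", words[-2:])
        score = c.neural_logp + cfg.alpha * lm_logp
        if words:
            score += cfg.beta * math.log(len(words))
        text = c.text.strip()
        if cfg.alpha_rescore != 0.0:
            score += cfg.alpha_rescore * rescorer(text)
        # space/no-space twins of the same sentence: keep the better score
        if text not in scored or score > scored[text]:
            scored[text] = score
    ranked = sorted(scored.items(), key=lambda st: (-st[1], st[0]))
    return ranked[0][0]


def recompute_score(
    text: str, X: ProbabilitySequence, lm: NgramLM, cfg: DecoderConfig
) -> float:
    """Candidate score recomputed from scratch from its text and X.

    Letters (spaces excluded) are matched one per cycle; used to check that
    the incrementally maintained score decomposes correctly.
    """
    from .language_model import sentence_log_prior

    letters = [c for c in text if c != " "]
    if len(letters) > len(X):
        raise ValueError("text has more letters than cycles")
    neural = 0.0
    for c, probs in zip(letters, X):
        p = _letter_probs(probs, cfg)[c]
        neural += math.log(p)
    lm_logp, n_words = sentence_log_prior(lm, text)
    score = neural + cfg.alpha * lm_logp
    if n_words:
        score += cfg.beta * math.log(n_words)
    return score


def brute_force_decode(
    X: ProbabilitySequence,
    lm: NgramLM,
    vocab: Vocabulary,
    cfg: DecoderConfig,
    max_vocab: int = 50,
    max_cycles: int = 8,
) -> list[tuple[str, float]]:
    """Exhaustively enumerate and score every vocabulary-consistent sequence.

    Tractability guard: refuses instances with more than ``max_vocab`` words
    or ``max_cycles`` cycles.  Returns the full ranking [(text, score), ...]
    sorted by score (ties broken lexicographically).
    """
    if len(vocab) > max_vocab or len(X) > max_cycles:
        raise ValueError("instance too large for exhaustive enumeration")
    beam = [BeamCandidate()]
    for probs in X:
        letters = _letter_probs(probs, cfg)
        nxt: list[BeamCandidate] = []
        for cand in beam:
            v, _ = _extensions(cand, letters, lm, vocab, cfg)
            nxt.extend(v)
        beam = nxt
        if not beam:
            return []
    return [(c.text, c.combined(cfg)) for c in _ranked(beam, cfg)]


def decode_sequence(
    X: ProbabilitySequence,
    lm: NgramLM,
    vocab: Vocabulary,
    cfg: DecoderConfig,
    rescorer: RescorerInterface | None = None,
    collect_dumps: bool = False,
) -> dict:
    """Run the full per-cycle decode of one sentence trial.

    Cycles whose hand-command probability exceeds the threshold trigger
    finalization with the beam from the previous iteration (the terminal
    cycle of a paced trial is the attempted hand squeeze).  If no cycle
    triggers, the best running candidate truncated at its last completed
    word is returned with ``finalized=False``.
    """
    beam: list[BeamCandidate] = [BeamCandidate()]
    dumps = []
    final_text: str | None = None
    final_cycle = None
    for tau, probs in enumerate(X):
        hand_p = probs.get(HAND) if HAND in probs.class_set else 0.0
        final_text = finalize_sentence(beam, hand_p, lm, rescorer, cfg, vocab)
        if final_text is not None:
            final_cycle = tau
            break
        beam = advance_beam(beam, probs, lm, vocab, cfg)
        if collect_dumps:
            dumps.append(
                [
                    {"text": c.text, "neural": c.neural_logp, "lm": c.lm_logp,
                     "score": c.combined(cfg)}
                    for c in beam[:10]
                ]
            )
    finalized = final_text is not None
    if final_text is None:
        best = beam[0] if beam else BeamCandidate()
        final_text = " ".join(best.words)
    return {
        "text": final_text,
        "finalized": finalized,
        "final_cycle": final_cycle,
        "beam": beam,
        "dumps": dumps,
    }
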
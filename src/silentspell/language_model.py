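"""Vocabulary, trigram language model, and the sentence-rescoring interface.

The beam search constrains its character sequences to words from a fixed
vocabulary (a prefix index answers "is this a word?" / "could it become
one?"), weighs candidates by a trigram word model p_lm with backoff
smoothing, and, at finalization, rescores complete sentences through a
pluggable causal-LM interface (a stand-in for large neural language
models, which this package deliberately does not bundle).

Smoothing is absolute-discounting backoff: observed n-grams are discounted
by ``discount`` and the freed mass is spread over the lower-order
distribution, with an add-0.1 floor at the unigram level, so every
in-vocabulary word has positive probability in every context and each
conditional distribution sums to one exactly.  A discount of zero recovers
raw maximum-likelihood count ratios.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable

__all__ = [
    "Vocabulary",
    "build_vocabulary",
    "NgramLM",
    "fit_ngram_lm",
    "sentence_log_prior",
    "RescorerInterface",
    "uniform_rescorer",
    "make_rescorer",
    "score_with_rescorer",
    "ScoringError",
]

START = "<s>"
END = "</s>"


class Vocabulary:
    """A constrained word set with a prefix index."""

    def __init__(self, words: Iterable[str]):
        self.words = frozenset(words)
        if not self.words:
            raise ValueError("vocabulary is empty")
        for w in self.words:
            if not w or not w.isalpha() or w != w.lower():
                raise ValueError(f"invalid vocabulary word {w!r}")
        prefixes = set()
        for w in self.words:
            for i in range(1, len(w) + 1):
                prefixes.add(w[:i])
        self._prefixes = frozenset(prefixes)

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, w: str) -> bool:
        return w in self.words

    def __or__(self, other: "Vocabulary") -> "Vocabulary":
        return Vocabulary(self.words | other.words)

    def union(self, other: "Vocabulary") -> "Vocabulary":
        return self | other

    def is_word(self, s: str) -> bool:
        return s in self.words

    def is_prefix(self, s: str) -> bool:
        """True if ``s`` is a (possibly complete) prefix of some word.

        The empty string is a prefix of every word.
        """
        return s == "" or s in self._prefixes

    def save(self, path: str) -> None:
        with open(path, "w") as f:
            for w in sorted(self.words):
                f.write(w + "\n")

    @classmethod
    def load(cls, path: str) -> "Vocabulary":
        with open(path) as f:
            return cls([line.strip() for line in f if line.strip()])


def _clean(word: str) -> str | None:
    w = word.strip().lower()
    w = "".join(c for c in w if c.isalpha())
    return w or None


def build_vocabulary(
    word_list: Iterable[str],
    reference_list: Iterable[str] | None = None,
    min_len_filter: bool = False,
    supplement: Iterable[str] | None = None,
) -> Vocabulary:
    """Clean, deduplicate, and optionally filter a word list.

    With ``min_len_filter`` on, words of 3 or fewer characters that do not
    appear in ``reference_list`` are dropped (this removes scraped non-words
    like "gp" or "ooo" from frequency-ranked lists).  ``supplement`` words
    are unioned in after filtering.
    """
    words = {w for w in (_clean(x) for x in word_list) if w}
    if min_len_filter:
        ref = {w for w in (_clean(x) for x in (reference_list or [])) if w}
        words = {w for w in words if len(w) > 3 or w in ref}
    if supplement is not None:
        words |= {w for w in (_clean(x) for x in supplement) if w}
    if not words:
        raise ValueError("vocabulary is empty after cleaning/filtering")
    return Vocabulary(words)


@dataclass
class NgramLM:
    """Trigram word model with absolute-discounting backoff.

    ``logp(word, context)`` returns the log conditional probability of
    ``word`` (or the end token) given up to two preceding words; contexts
    shorter than two are start-padded.
    """

    vocab: Vocabulary
    discount: float = 0.4
    unigram_floor: float = 0.1
    uni: Counter = field(default_factory=Counter, repr=False)
    bi: Counter = field(default_factory=Counter, repr=False)
    tri: Counter = field(default_factory=Counter, repr=False)
    bi_ctx: Counter = field(default_factory=Counter, repr=False)
    tri_ctx: Counter = field(default_factory=Counter, repr=False)
    bi_types: Counter = field(default_factory=Counter, repr=False)
    tri_types: Counter = field(default_factory=Counter, repr=False)
    n_tokens: int = 0

    @property
    def support(self) -> frozenset:
        return self.vocab.words | {END}

    def _p_uni(self, w: str) -> float:
        v = len(self.vocab) + 1  # vocabulary plus the end token
        return (self.uni[w] + self.unigram_floor) / (self.n_tokens + self.unigram_floor * v)

    def _p_bi(self, w: str, u: str) -> float:
        tot = self.bi_ctx[u]
        if tot == 0:
            return self._p_uni(w)
        d = self.discount
        disc = max(self.bi[(u, w)] - d, 0.0) / tot
        lam = d * self.bi_types[u] / tot
        return disc + lam * self._p_uni(w)

    def prob(self, w: str, context: tuple[str, ...]) -> float:
        """p(w | context), context = up to two preceding words."""
        if w != END and w not in self.vocab:
            return 0.0
        ctx = (START, START) + tuple(context)
        u, v = ctx[-2], ctx[-1]
        tot = self.tri_ctx[(u, v)]
        if tot == 0:
            return self._p_bi(w, v)
        d = self.discount
        disc = max(self.tri[(u, v, w)] - d, 0.0) / tot
        lam = d * self.tri_types[(u, v)] / tot
        return disc + lam * self._p_bi(w, v)

    def logp(self, w: str, context: tuple[str, ...]) -> float:
        p = self.prob(w, context)
        return math.log(p) if p > 0 else -math.inf

    def save(self, path: str) -> None:
        """Sorted text table: order<TAB>ngram<TAB>count (diffable)."""
        with open(path, "w") as f:
            f.write(f"# discount={self.discount} unigram_floor={self.unigram_floor}\n")
            for w in sorted(self.vocab.words):
                f.write(f"V\t{w}\n")
            for table, name in ((self.uni, "1"), (self.bi, "2"), (self.tri, "3")):
                for key in sorted(table):
                    gram = key if isinstance(key, str) else " ".join(key)
                    f.write(f"{name}\t{gram}\t{table[key]}\n")

    @classmethod
    def load(cls, path: str) -> "NgramLM":
        words, uni, bi, tri = [], Counter(), Counter(), Counter()
        discount, floor = 0.4, 0.1
        with open(path) as f:
            for line in f:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for part in line[1:].split():
                        k, v = part.split("=")
                        if k == "discount":
                            discount = float(v)
                        elif k == "unigram_floor":
                            floor = float(v)
                    continue
                parts = line.split("\t")
                if parts[0] == "V":
                    words.append(parts[1])
                elif parts[0] == "1":
                    uni[parts[1]] = int(parts[2])
                elif parts[0] == "2":
                    bi[tuple(parts[1].split(" "))] = int(parts[2])
                elif parts[0] == "3":
                    tri[tuple(parts[1].split(" "))] = int(parts[2])
        lm = cls(Vocabulary(words), discount=discount, unigram_floor=floor)
        lm.uni, lm.bi, lm.tri = uni, bi, tri
        lm._finalize()
        return lm

    def _finalize(self) -> None:
        self.n_tokens = sum(self.uni.values())
        self.bi_ctx = Counter()
        self.bi_types = Counter()
        for (u, w), c in self.bi.items():
            self.bi_ctx[u] += c
            self.bi_types[u] += 1
        self.tri_ctx = Counter()
        self.tri_types = Counter()
        for (u, v, w), c in self.tri.items():
            self.tri_ctx[(u, v)] += c
            self.tri_types[(u, v)] += 1


def fit_ngram_lm(
    corpus: Iterable[str],
    vocab: Vocabulary,
    discount: float = 0.4,
    unigram_floor: float = 0.1,
) -> NgramLM:
    """Maximum-likelihood trigram counts over a sentence corpus.

    Sentences are lowercased and tokenized on whitespace; out-of-vocabulary
    tokens are dropped so the model's support equals the decoding
    vocabulary.  Refitting with a different vocabulary re-derives the valid
    n-grams from the same corpus.
    """
    lm = NgramLM(vocab, discount=discount, unigram_floor=unigram_floor)
    n_sentences = 0
    for line in corpus:
        tokens = [w for w in (_clean(t) for t in line.split()) if w and w in vocab]
        if not tokens:
            continue
        n_sentences += 1
        padded = [START, START] + tokens + [END]
        for w in tokens + [END]:
            lm.uni[w] += 1
        for u, w in zip(padded[1:], padded[2:]):
            lm.bi[(u, w)] += 1
        for u, v, w in zip(padded, padded[1:], padded[2:]):
            lm.tri[(u, v, w)] += 1
    if n_sentences == 0:
        raise ValueError("corpus contains no in-vocabulary sentences")
    lm._finalize()
    return lm


def sentence_log_prior(
    lm: NgramLM, s: str, include_end: bool = False
) -> tuple[float, int]:
    """Log prior of the completed words of ``s`` and their count |s|.

    Only words preceding the final whitespace character count; a partial
    final word contributes nothing.  An empty completed-word set gives
    (0.0, 0).  With ``include_end`` the end-of-sentence probability is
    added (used at finalization, not during per-cycle advancement).
    """
    if " " in s:
        completed = s[: s.rfind(" ")].split()
    else:
        completed = []
    logp = 0.0
    for i, w in enumerate(completed):
        logp += lm.logp(w, tuple(completed[max(0, i - 2) : i]))
    if include_end and completed:
        logp += lm.logp(END, tuple(completed[-2:]))
    return logp, len(completed)


# ---------------------------------------------------------------------------
# Rescoring interface
# ---------------------------------------------------------------------------


class ScoringError(RuntimeError):
    """A rescorer failed to score a sentence."""


@dataclass
class RescorerInterface:
    """A deterministic map from complete sentence text to log probability."""

    fn: Callable[[str], float]
    name: str = "rescorer"

    def __call__(self, s: str) -> float:
        try:
            return float(self.fn(s))
        except Exception as exc:  # propagate with context
            raise ScoringError(f"{self.name} failed on {s!r}: {exc}") from exc


def uniform_rescorer() -> RescorerInterface:
    """Assigns log probability 0 to every sentence (no-op rescoring)."""
    return RescorerInterface(lambda s: 0.0, name="uniform")


def make_rescorer(fn: Callable[[str], float], name: str = "external") -> RescorerInterface:
    """Adapter for any runtime-supplied causal-LM sentence scorer."""
    return RescorerInterface(fn, name=name)


def score_with_rescorer(rescorer: RescorerInterface, s: str) -> float:
    return rescorer(s)
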
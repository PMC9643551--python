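"""Evaluation metrics: block-pooled CER/WER, typing rates, ablation
conditions, chance-level accuracy, and bootstrap confidence intervals.

Error rates are pooled per block: the sum of edit distances between each
decoded/target pair divided by the total target length across the block's
trials (not the mean of per-trial rates).  Typing rates pool decoded
character/word counts (whitespace included) over trial durations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import HAND, ProbabilitySequence, letter_for

__all__ = [
    "SentenceTrial",
    "BlockMetrics",
    "edit_distance",
    "block_error_rates",
    "typing_rates",
    "evaluate_block",
    "run_ablation",
    "ABLATION_CONDITIONS",
    "bootstrap_median_ci",
    "chance_accuracy",
    "monte_carlo_chance_accuracy",
]


@dataclass
class SentenceTrial:
    """One decoded sentence with its target and duration.

    ``duration_min`` runs from the first go cue to the end of the final
    code-word window (the terminal hand-command window is excluded).
    """

    decoded: str
    target: str
    duration_min: float | None = None

    def __post_init__(self) -> None:
        if self.duration_min is not None and self.duration_min <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_chars(self) -> int:
        return len(self.decoded)  # whitespace included

    @property
    def n_words(self) -> int:
        return len(self.decoded.split())


@dataclass
class BlockMetrics:
    cer: float  # percent
    wer: float  # percent
    cpm: float | None = None
    wpm: float | None = None
    n_trials: int = 0


def _normalize_text(s: str) -> str:
    """Lowercase a-z + single spaces; the speller emits nothing else."""
    s = "".join(c if c.isalpha() or c == " " else " " for c in s.lower())
    return " ".join(s.split())


def edit_distance(a, b, level: str = "character") -> int:
    """Levenshtein distance between two texts at character or word level."""
    if level == "character":
        sa, sb = list(a), list(b)
    elif level == "word":
        sa, sb = a.split(), b.split()
    else:
        raise ValueError("level must be 'character' or 'word'")
    n, m = len(sa), len(sb)
    if n == 0:
        return m
    if m == 0:
        return n
    prev = np.arange(m + 1)
    cur = np.empty(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        cur[0] = i
        sub = prev[:-1] + np.array([sa[i - 1] != x for x in sb], dtype=np.int64)
        ins = prev[1:] + 1
        np.minimum(sub, ins, out=cur[1:])
        for j in range(1, m + 1):  # deletions need the running minimum
            if cur[j - 1] + 1 < cur[j]:
                cur[j] = cur[j - 1] + 1
        prev, cur = cur, prev
    return int(prev[m])


def block_error_rates(trials: list[SentenceTrial], normalize: bool = True) -> BlockMetrics:
    """Pooled CER/WER (percent) across a block's trials."""
    if not trials:
        raise ValueError("empty block")
    cd = wd = cn = wn = 0
    for t in trials:
        dec = _normalize_text(t.decoded) if normalize else t.decoded
        tgt = _normalize_text(t.target) if normalize else t.target
        cd += edit_distance(dec, tgt, "character")
        wd += edit_distance(dec, tgt, "word")
        cn += len(tgt)
        wn += len(tgt.split())
    return BlockMetrics(
        cer=100.0 * cd / cn, wer=100.0 * wd / wn, n_trials=len(trials)
    )


def typing_rates(trials: list[SentenceTrial]) -> BlockMetrics:
    """Pooled characters/words per minute: sum(N_i) / sum(D_i)."""
    if not trials:
        raise ValueError("empty block")
    if any(t.duration_min is None or t.duration_min <= 0 for t in trials):
        raise ValueError("all trials need positive durations")
    total_d = sum(t.duration_min for t in trials)
    return BlockMetrics(
        cer=0.0,
        wer=0.0,
        cpm=sum(t.n_chars for t in trials) / total_d,
        wpm=sum(t.n_words for t in trials) / total_d,
        n_trials=len(trials),
    )


def evaluate_block(trials: list[SentenceTrial]) -> BlockMetrics:
    """Error rates plus typing rates when durations are available."""
    m = block_error_rates(trials)
    if all(t.duration_min for t in trials):
        r = typing_rates(trials)
        m.cpm, m.wpm = r.cpm, r.wpm
    return m


# ---------------------------------------------------------------------------
# Ablation conditions (system-omission simulations)
# ---------------------------------------------------------------------------

ABLATION_CONDITIONS = ("chance", "neural_only", "vocab_constrained", "full")


def run_ablation(
    condition: str,
    sequences: list[ProbabilitySequence],
    lm,
    vocab,
    cfg,
    seed: int = 0,
    rescorer=None,
) -> list[str]:
    """Decode each probability sequence under one omission condition.

    chance: classifier outputs replaced by symmetric-Dirichlet draws, rest
    of the pipeline unchanged.  neural_only: concatenated most likely
    letters, no whitespace.  vocab_constrained: beam search with vocabulary
    constraints but no language model (alpha = beta = 0).  full: the
    complete pipeline.
    """
    from dataclasses import replace as dc_replace

    from .beam_search import decode_sequence

    if condition not in ABLATION_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    decoded = []
    for X in sequences:
        if condition == "chance":
            cs = X.class_set
            arr = rng.dirichlet(np.ones(len(cs)), size=len(X))
            # keep the terminal hand-command cycle so finalization still works
            if HAND in cs and len(X) > 0:
                hi = cs.index(HAND)
                last = np.full(len(cs), 1e-6)
                last[hi] = 1.0
                arr[-1] = last / last.sum()
            Xc = ProbabilitySequence.from_array(arr, cs)
            decoded.append(decode_sequence(Xc, lm, vocab, cfg, rescorer)["text"])
        elif condition == "neural_only":
            letters = []
            for probs in X:
                top = probs.top_class()
                if top == HAND:
                    continue
                letters.append(top if len(top) == 1 else letter_for(top))
            decoded.append("".join(letters))
        elif condition == "vocab_constrained":
            cfg0 = dc_replace(cfg, alpha=0.0, beta=0.0, alpha_rescore=0.0)
            decoded.append(decode_sequence(X, lm, vocab, cfg0, None)["text"])
        else:  # full
            decoded.append(decode_sequence(X, lm, vocab, cfg, rescorer)["text"])
    return decoded


# ---------------------------------------------------------------------------
# Chance levels and bootstrap confidence intervals
# ---------------------------------------------------------------------------


def chance_accuracy(n_classes: int) -> float:
    """Analytic chance accuracy in percent (100 / n_classes)."""
    if n_classes < 1:
        raise ValueError("need at least one class")
    return 100.0 / n_classes


def monte_carlo_chance_accuracy(
    n_classes: int, n_draws: int = 1_000_000, seed: int = 0
) -> float:
    """Accuracy (percent) of arg-max guessing from uniform random
    probability vectors against uniform random labels."""
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 100_000
    done = 0
    while done < n_draws:
        n = min(chunk, n_draws - done)
        probs = rng.standard_exponential((n, n_classes))  # Dirichlet(1) up to scale
        guess = np.argmax(probs, axis=1)
        labels = rng.integers(0, n_classes, size=n)
        hits += int(np.count_nonzero(guess == labels))
        done += n
    return 100.0 * hits / n_draws


def bootstrap_median_ci(
    values,
    level: float = 0.99,
    iterations: int = 2000,
    seed: int = 0,
    statistic=np.median,
) -> tuple[float, float]:
    """Percentile bootstrap interval of the median (or another statistic)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(iterations, values.size))
    stats = statistic(values[idx], axis=1)
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(stats, lo)),
        float(np.quantile(stats, 1.0 - lo)),
    )
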
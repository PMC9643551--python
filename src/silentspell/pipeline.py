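"""End-to-end simulated spelling sessions.

Wires the modules together the way the real-time system runs: a detector
gates session start from a continuous stream; each paced 2.5-s cycle's
feature window is classified by the model ensemble; the beam search
advances per cycle; the hand-command probability finalizes the sentence.
Cycle pacing is logical (indexed) — real-time scheduling is out of scope.
All per-cycle probabilities are stored so any decode can be replayed
bit-for-bit under alternative vocabularies or language models.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .beam_search import DecoderConfig, decode_sequence
from .classifier import (
    ClassifierModel,
    ProbabilitySequence,
    TrialWindow,
    ensemble_predict_many,
)
from .containers import FeatureStream
from .detector import DetectorModel, detect_speech_events
from .language_model import NgramLM, RescorerInterface, Vocabulary
from .metrics import BlockMetrics, SentenceTrial, bootstrap_median_ci, evaluate_block
from .signal_features import decimate_stream
from .synthetic import SyntheticConfig, generate_continuous_session, generate_sentence_trial

__all__ = ["SessionResult", "run_simulated_session", "evaluate_copy_typing",
           "decimate_window"]


@dataclass
class SessionResult:
    """Outcome of one simulated block of sentence-spelling trials."""

    records: list[dict]          # target, decoded, finalized, prob array, dumps
    metrics: BlockMetrics
    seed: int = 0
    engaged: bool | None = None  # detector gating outcome (None: no detector)
    config: dict = field(default_factory=dict)

    def trials(self) -> list[SentenceTrial]:
        return [
            SentenceTrial(r["decoded"], r["target"], duration_min=r["duration_min"])
            for r in self.records
        ]


def decimate_window(window: TrialWindow, factor: int = 6) -> TrialWindow:
    """Decimate a 200 Hz trial window to the classifier rate."""
    stream = FeatureStream(window.features, rate=200.0, normalized=True)
    dec = decimate_stream(stream, factor)
    return TrialWindow(
        dec.values, label=window.label, go_cue_time=window.go_cue_time,
        source=window.source,
    )


def run_simulated_session(
    sentences: list[str],
    models: list[ClassifierModel],
    lm: NgramLM,
    vocab: Vocabulary,
    cfg: DecoderConfig,
    synth: SyntheticConfig,
    seed: int = 0,
    detector: DetectorModel | None = None,
    rescorer: RescorerInterface | None = None,
    decimation_factor: int = 6,
    collect_dumps: bool = False,
) -> SessionResult:
    """Simulate a spelling block: one trial per sentence, deterministic per seed.

    When a detector is supplied, a short continuous lead-in with one speech
    attempt gates engagement first (as in the live system, detection only
    starts the speller; cycles then proceed on the pace).
    """
    rng = np.random.default_rng(seed)
    engaged: bool | None = None
    if detector is not None:
        first_class = synth.class_set[0]
        lead = generate_continuous_session(
            [(first_class, 3.0)], synth, seed=int(rng.integers(2**31))
        )
        events = detect_speech_events(detector, lead.stream)
        engaged = len(events) > 0

    records = []
    for sentence in sentences:
        sub = int(rng.integers(2**31))
        try:
            windows, truth = generate_sentence_trial(sentence, synth, seed=sub)
            dec_windows = [decimate_window(w, decimation_factor) for w in windows]
            probs = ensemble_predict_many(models, dec_windows)
            X = ProbabilitySequence(probs)
            out = decode_sequence(X, lm, vocab, cfg, rescorer, collect_dumps=collect_dumps)
        except Exception as exc:
            raise RuntimeError(f"failed decoding sentence {sentence!r}") from exc
        n_letter_cycles = len(windows) - 1  # terminal window is the hand command
        records.append(
            {
                "target": truth,
                "decoded": out["text"],
                "finalized": out["finalized"],
                "final_cycle": out["final_cycle"],
                "n_cycles": len(windows),
                "probabilities": X.array(),
                "class_set": X.class_set,
                "dumps": out["dumps"],
                # duration: first go cue to end of the final code-word window
                "duration_min": n_letter_cycles * synth.window_s / 60.0,
            }
        )
    metrics = evaluate_block([
        SentenceTrial(r["decoded"], r["target"], r["duration_min"]) for r in records
    ])
    return SessionResult(
        records=records,
        metrics=metrics,
        seed=seed,
        engaged=engaged,
        config={"decoder": asdict(cfg), "decimation_factor": decimation_factor},
    )


def replay_session(
    result: SessionResult,
    lm: NgramLM,
    vocab: Vocabulary,
    cfg: DecoderConfig,
    rescorer: RescorerInterface | None = None,
) -> list[str]:
    """Re-decode a session's stored probability sequences."""
    decoded = []
    for r in result.records:
        if "probabilities" not in r:
            raise ValueError("session has no stored probability dumps")
        X = ProbabilitySequence.from_array(r["probabilities"], r["class_set"])
        decoded.append(decode_sequence(X, lm, vocab, cfg, rescorer)["text"])
    return decoded


def evaluate_copy_typing(
    results: list[SessionResult],
    vocab_variants: list[tuple[str, Vocabulary, NgramLM]],
    cfg: DecoderConfig,
    rescorer: RescorerInterface | None = None,
    ci_seed: int = 0,
) -> pd.DataFrame:
    """Re-decode stored probability sequences under vocabulary/LM variants.

    Returns per-variant block CER/WER with bootstrap confidence intervals
    of the median across blocks.
    """
    rows = []
    for name, vocab, lm in vocab_variants:
        cers, wers = [], []
        for res in results:
            decoded = replay_session(res, lm, vocab, cfg, rescorer)
            trials = [
                SentenceTrial(d, r["target"], r["duration_min"])
                for d, r in zip(decoded, res.records)
            ]
            m = evaluate_block(trials)
            cers.append(m.cer)
            wers.append(m.wer)
        row = {
            "variant": name,
            "vocab_size": len(vocab),
            "median_cer": float(np.median(cers)),
            "median_wer": float(np.median(wers)),
        }
        if len(cers) >= 2:
            row["cer_ci_low"], row["cer_ci_high"] = bootstrap_median_ci(cers, seed=ci_seed)
            row["wer_ci_low"], row["wer_ci_high"] = bootstrap_median_ci(wers, seed=ci_seed)
        rows.append(row)
    return pd.DataFrame(rows)
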
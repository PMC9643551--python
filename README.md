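# silentspell

A silent-speech spelling neuroprosthesis pipeline.  People who have lost
the ability to speak or type can, in principle, spell sentences by
*silently attempting* to say code words — "alpha" for a, "bravo" for b —
while a decoder reads multichannel neural recordings from speech-motor
cortex.  `silentspell` implements that full decoding stack as a tested,
reusable Python package:

* **Feature extraction** — common average referencing, dual-band features
  per electrode (high-gamma analytic amplitude, 70–150 Hz, and
  low-frequency signals, ≤100 Hz) at 200 Hz, streaming 30-s sliding-window
  z-scores with artifact rejection, and ×6 anti-aliased decimation for the
  classifier path.
* **Speech detection** — a stacked-LSTM frame classifier over four
  behavioral states (rest / preparation / motor / speech) whose smoothed
  speech probability engages the speller through hysteresis thresholds.
* **Classification** — every paced 2.5-s cycle, a temporal-convolution +
  bidirectional-GRU network maps the feature window to probabilities over
  26 code words plus an attempted hand squeeze; ensembles average models
  trained from different initializations.  The recurrent layers are NumPy
  with hand-derived, finite-difference-verified backpropagation.
* **Decoding** — a vocabulary-constrained beam search scores candidate
  sentences by classifier evidence, a trigram word prior p_lm weighted by
  α, and a word-insertion bonus |s|^β, inserting spaces automatically.
  When the hand-command probability exceeds 80%, incomplete candidates are
  dropped, survivors are rescored through a pluggable language-model
  interface, and the sentence is finalized.
* **Evaluation & analyses** — pooled block CER/WER and characters/words
  per minute, ablation conditions (chance / neural-only / +vocabulary /
  +LM), bootstrap confidence intervals, gradient-based electrode
  attribution, PCA dimensionality bootstraps, temporal-smoothing sweeps,
  and nearest-class template distances.

Clinical ECoG recordings are restricted-access, so a first-class
**synthetic generator** (`silentspell.synthetic`) emulates 128-channel
dual-band sessions with class-dependent go-cue-aligned templates,
controllable noise, jitter, and channel informativeness; all tests and
the acceptance script run on it.  See `docs/methods.md` for the model
details and design choices.

## Worked example

Train a small ensemble on synthetic isolated-target data, fit the trigram
model on the packaged toy corpus, and decode a spelling session:

```python
import numpy as np
from silentspell import (
    SyntheticConfig, generate_trial_window, train_classifier,
    ClassifierHyperparams, build_vocabulary, fit_ngram_lm, DecoderConfig,
    run_simulated_session,
)
from silentspell.config import packaged_corpus, packaged_vocabulary
from silentspell.pipeline import decimate_window

synth = SyntheticConfig()                      # 128 channels, 27 classes
rng = np.random.default_rng(0)
train = [decimate_window(generate_trial_window(c, synth, seed=int(rng.integers(2**31))))
         for c in synth.class_set for _ in range(10)]
models = [train_classifier(train, ClassifierHyperparams(epochs=30, patience=8),
                           seed=s, class_set=synth.class_set) for s in range(3)]

vocab = build_vocabulary(packaged_vocabulary())
lm = fit_ngram_lm(packaged_corpus(), vocab)
sentences = ["i need water", "please call my family", "i am fine"]
result = run_simulated_session(sentences, models, lm, vocab,
                               DecoderConfig(), synth, seed=42)
for r in result.records:
    print(f"{r['target']!r:30} -> {r['decoded']!r}")
print(f"block CER {result.metrics.cer:.2f}%  CPM {result.metrics.cpm:.1f}")
```

Output:

```
'i need water'                 -> 'i need water'
'please call my family'        -> 'please call my family'
'i am fine'                    -> 'i am fine'
block CER 0.00%  CPM 28.8
```

Every sentence is recovered exactly: individual letter classifications are
imperfect at this training size, but the vocabulary constraints and
trigram prior correct them.  The ~29 characters/minute follows from the
2.5-s letter cycle plus the automatically inserted spaces.

A thin CLI wraps the same library:

```bash
silentspell simulate --run-dir runs/demo --seed 1
silentspell fit-lm --run-dir runs/demo
silentspell train-detector --run-dir runs/demo
```

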
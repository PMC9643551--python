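# Methods

`silentspell` implements a silent-speech spelling neuroprosthesis pipeline:
a user spells a sentence by silently attempting NATO code words (one per
letter) in paced 2.5-s cycles, and finalizes it by attempting a hand
squeeze.  Neural features drive four stages — detection, classification,
beam-search decoding with a language-model prior, and finalization with
rescoring.  Because the clinical ECoG recordings such systems are built on
are restricted-access, the package ships a synthetic data generator that
reproduces the statistical structure the pipeline assumes, and every result
in the test suite and acceptance script is computed on that synthetic data.

## Signal model and feature extraction

Raw input is a 128-channel recording at 1 kHz (microvolts).  Processing:

1. **Common average reference** — per-sample subtraction of the
   across-channel mean; removes shared noise and is causally safe.
2. **Dual-band features.**  Two causal equiripple FIR paths per channel:
   * **HGA** — the analytic amplitude of the 70–150 Hz band.  The band-pass
     filter's coefficients are converted to their analytic (quadrature)
     pair, so the magnitude of one complex FIR filtering gives the
     envelope; this keeps the computation strictly FIR and streamable.
   * **LFS** — the signal low-passed at 100 Hz.
   Filters are designed by the Parks–McClellan (remez) algorithm with 5 Hz
   transition bands and ≥40 dB stopband; the shortest odd length meeting
   that spec is used (estimated by the Kaiser formula), giving an integer
   group delay.  Both paths use equal-length filters so the two feature
   streams stay time-aligned; outputs are reported delay-compensated, and
   `FeatureStream.meta["group_delay_s"]` records the latency a real-time
   consumer would see.  Both streams are subsampled to 200 Hz (every 5th
   sample), yielding 256 features (HGA ch0..127, then LFS ch0..127).
3. **Streaming z-scores.**  Each feature is z-scored against statistics of
   a 30-s sliding window, computed strictly in time order (chunked calls
   are bit-identical to one call).  The z-score of sample *t* uses the
   included samples in the window *before* t; expanding-window statistics
   cover the warm-up, and the first 30 s are flagged.  Degenerate variance
   is floored at `sigma_floor = 1e-6`.  Population (ddof = 0) variance is
   the default; this is a config choice.
4. **Artifact rejection.**  A time point where ≥32 features exceed
   |z| > 10 is replaced by the previous time point's z-values, masked, and
   excluded from statistic updates.  The rule is disabled for the first
   second of statistics (200 samples) so start-up variance cannot trigger
   it spuriously.
5. **Decimation (classifier path only).**  A further anti-alias low-pass at
   5/6 of the post-decimation Nyquist rate (16.67 Hz for factor 6) followed
   by subsampling; output length is `floor(n / factor)`.  The detector
   consumes the undecimated 200 Hz stream.

## Synthetic data generator

The generator emits features directly on the normalized (z-scored) scale —
it emulates the *output* of the feature stage, which is what the models
consume.  Structure:

* **Class templates.**  Each of the 26 code words has a spatiotemporal
  template over the 2.5-s window: smoothed Gaussian-process draws
  (RBF-like, 150 ms length scale, unit RMS) on 12 HGA-informative and 12
  LFS-informative channels; the two channel sets are disjoint, emulating
  the finding that the two bands draw on relatively distinct cortical
  sites.  Letter mode derives each letter's template by truncating the
  code word's to its first 40% and scaling by 0.6, so code words are more
  discriminable by construction.
* **Hand command.**  A separate "hand-knob" channel subset carries the
  hand-squeeze template at higher amplitude (0.8), reflecting how reliably
  distinct that command is from speech attempts.
* **States.**  Continuous sessions have rest background (white noise),
  a preparation offset on a dedicated premotor-like channel subset for 1 s
  before each go cue (200 ms on-ramp, then hold), a shared speech-activity
  offset plus the class template during the 2.5-s response, and the hand
  template for motor events.  Giving preparation its own channels keeps the
  four states spatially separable, which a causal frame classifier needs.
* **Noise and jitter.**  I.i.d. Gaussian noise (SD 1.0) and a Gaussian
  go-cue jitter (SD 50 ms) shift each trial's template.
* **Defaults as study conditions.**  The class-template amplitude (0.25)
  was calibrated once against the generator's own separability oracle — a
  cross-validated linear readout must exceed 90% at 50 trials/class without
  saturating the recurrent classifier — and then frozen.  At these
  settings a single desk-scale classifier reaches roughly 75–90% window
  accuracy depending on training-set size, so decoding errors exist for
  the vocabulary constraints and language model to correct, mirroring the
  structure of the real system's results.
* **What it does not emulate:** 1/f spectra, channel covariance,
  nonstationarity, electrode drift, or any biophysics.  Passing tests show
  the pipeline's machinery is correct and that its components interact as
  designed — not that the models would reach any particular accuracy on
  real recordings.

A `variant(rho, seed)` method produces a paired condition (e.g. overt vs
silent speech attempts) whose templates correlate ρ with the original,
used for cross-condition transfer properties.

## Detector

A 2-layer LSTM (hidden 48/layer) labels every 200 Hz frame as rest /
preparation / motor / speech, trained by truncated backpropagation through
time (chunks of 250 frames, state carried detached) with Adam.  Only the
speech probability is used at run time: it is smoothed by a causal 250-ms
moving average and thresholded with hysteresis — an event is a region above
the offset threshold (0.3) containing a run of ≥500 ms above the onset
threshold (0.5).  This construction makes the event count monotonically
non-increasing in the onset threshold and keeps detection causal.  In the
pipeline the detector only gates session start; cycles then proceed on the
pace.

## Classifier

A 1-D temporal convolution (kernel 5, stride 3, 32 filters) over the
83 × 256 decimated window, two bidirectional GRU layers (hidden 32 per
direction), and a softmax read from the concatenated final forward /
backward states.  Training maximizes the likelihood of the labels
(cross-entropy) with Adam, a stratified 10% validation split, and early
stopping; everything is deterministic given the seed.  These sizes are
deliberately desk-scale — the pipeline trains in seconds to minutes on one
CPU — and all are config-exposed, as are optional augmentation (additive
noise, ±120 ms shifts), an L2 weight penalty, and a mean-pooling readout.

The neural layers themselves (conv1d, GRU, LSTM, dense, dropout, Adam) are
implemented in NumPy with hand-derived backpropagation and are verified
against central finite differences in the test suite; gradients propagate
to the inputs, which the analysis module reuses for attribution.

**Ensembling** averages the probability vectors of models trained from
different random initializations (default 10 in the acceptance run).
**Recalibration selection** keeps sentence-trial windows only from trials
decoded with a character error rate of exactly 0, labeling them from the
truth letters plus the terminal hand command.

## Language model and vocabulary

The decoding vocabulary is a lowercase word set with a prefix index.  The
cleaning rule for scraped frequency lists drops words of ≤3 characters that
are absent from a reference list (removing non-words like "gp", "ooo");
supplements are set unions.

The sentence prior is a trigram word model with absolute-discounting
backoff: observed n-gram counts are discounted by d = 0.4 and the freed
mass goes to the lower order, with an add-0.1 floor at the unigram level
over vocabulary ∪ {end}.  Every conditional distribution sums to one
exactly, every in-vocabulary word has positive probability in every
context, and d = 0 reproduces raw count ratios.  Out-of-vocabulary corpus
tokens are dropped at training so the model's support equals the decoding
vocabulary.  A sentence's prior is the product of each completed word's
conditional given the two preceding words; **words after the final
whitespace contribute nothing** (the partial-word rule), and the
end-of-sentence probability is applied only at finalization.

Rescoring is a pluggable interface mapping sentence text to a log
probability; the package ships a uniform stub and an adapter for any
runtime-supplied causal-LM scorer.  No neural language model is bundled.

## Beam search

Each cycle the classifier emits 27 probabilities.  Every candidate prefix
is extended by each letter c with p(c) > 0.001 (the floor is applied once,
to the raw per-cycle probability) and by "c + space" at the same
probability, so whitespace is only ever inserted by the decoder.
Candidates whose partial final word is not a vocabulary prefix (or, for
space extensions, not a complete word) are discarded; survivors are scored
in log space as

    log p_nc(s | X) + α · log p_lm(s) + β · log |s|

with the LM prior and |s| over completed words only, and the β term
omitted while |s| = 0.  Ties break lexicographically, making the ranking
deterministic.  The top-B candidates survive (α = 0.5, β = 1.0, B = 200 by
default; the clinically tuned values are unpublished).  If pruning ever
empties the beam, the top-B pre-pruning extensions by neural score are kept
— mid-sentence failure is never allowed.

When the hand-command probability exceeds 80% (strictly), candidates with
incomplete final words are removed, each survivor's score is recomputed
with the final word folded into the prior, the end-of-sentence term, and
the rescorer weighted by its own exponent, and the arg-max is finalized.
If every candidate is incomplete, the best one truncated at its last
completed word is returned with a warning.

`brute_force_decode` enumerates every vocabulary-consistent sequence on
guarded small instances (≤50 words, ≤8 cycles) and scores it exactly; the
beam search with a beam at least the enumeration size must reproduce its
ranking, which the acceptance suite checks on 100 random instances.

## Evaluation

CER/WER are **pooled per block**: summed edit distances divided by summed
target lengths (characters include whitespace), in percent — not the mean
of per-trial rates.  Typing rates pool decoded character/word counts over
trial durations, where a trial's duration runs from its first go cue to
the end of its final code-word window (the hand window is excluded).
Texts are compared lowercase over a–z + space.  The ablation conditions
replace classifier outputs with symmetric Dirichlet(1) draws (chance),
concatenate per-cycle arg-max letters without spaces (neural only), run
the beam with α = β = 0 (vocabulary constraints only), or run the full
system.  Confidence intervals are percentile bootstrap over 2000
iterations of the median.

## Analyses

* **Electrode contributions** — the loss gradient w.r.t. the input, L2
  norm over time per (electrode, feature type), averaged over trials;
  non-negative by construction, shape channels × 2.
* **Dimensionality** — bootstrap-resampled trial averages per class are
  arranged features × (time·classes) (spatial) or time ×
  (features·classes) (temporal); columns are mean-centered and the
  smallest PC count explaining strictly >80% variance is recorded per
  bootstrap (with a 1e-9 tolerance so exact eigenvalue ties do not count
  as "strictly more").
* **Smoothing sweep** — Gaussian kernels (SD in seconds, truncated at 4
  SD, reflect padding) apply increasing temporal blur; the probe is a
  cross-validated multinomial logistic regression on the flattened window,
  chosen so the sweep is tractable while remaining sensitive to
  temporal-resolution loss.
* **Nearest-class distance** — bootstrap-averaged class templates,
  pairwise Frobenius distances, per-class minimum over other classes of
  the same utterance type.

## Problem sizes and numerical choices

The test suite and acceptance script size their experiments for a single
CPU: typically 16-channel configurations with 10–40 trials per class for
model-level properties, the full 128-channel default configuration with 10
trials/class and a 10-model ensemble for the end-to-end run, 20 decoded
sentences per block experiment, 50–100 bootstrap iterations for
dimensionality, and 1e6 Monte-Carlo draws for the chance levels.  The
packaged toy corpus (110 assistive-communication-style sentences, 134
words) both trains the trigram model and supplies copy-typing targets;
decoding targets drawn from the LM's own training corpus is the favorable
regime a deployed speller with a user-matched corpus would approximate,
and the ablation conditions quantify how much of the performance comes
from that prior.

Known limitations: the generator's class separability, not any biological
signal, sets attainable accuracies; softmax confidence of small ensembles
is weakly calibrated, so the 80% hand threshold needs adequately trained
models; the trigram serialization stores counts (probabilities are
reconstructed), and the rescoring stage is exercised only through stubs
and adapters.
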
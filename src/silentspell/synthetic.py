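"""Synthetic ECoG-like feature data with the structure the pipeline assumes.

The clinical recordings behind the spelling system are restricted-access,
so every test and demonstration here runs on synthetic 128-channel dual-band
feature streams.  The generator emulates, without any biophysical claim:

* go-cue-aligned, class-dependent spatiotemporal responses over a 2.5-s
  window, built from smoothed Gaussian-process draws per class;
* distinct informative channel subsets for the HGA and LFS bands, plus a
  separate "hand-knob" channel set carrying the hand-motor command;
* four behavioral states for continuous sessions (rest, speech preparation,
  speech, motor) with controllable noise and temporal jitter.

Values are generated on the normalized (z-scored) feature scale, i.e. the
generator emits what `signal_features.normalize_stream` would output.
Everything is reproducible from explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .classifier import CODE_WORDS, HAND, LETTERS, TrialWindow, code_word_for
from .containers import FeatureStream

__all__ = ["SyntheticConfig", "LabeledSession", "STATES",
           "generate_trial_window", "generate_continuous_session",
           "generate_sentence_trial"]

STATES = ["rest", "preparation", "speech", "motor"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic feature-data generator.

    ``class_amplitude`` is the per-channel RMS of each class-specific
    template on the z-scored feature scale; with unit noise SD and a dozen
    informative channels per band this puts a linear readout in the >90%
    accuracy regime without saturating it, so decoding errors exist for the
    language model to correct.
    """

    n_channels: int = 128
    rate: float = 200.0
    window_s: float = 2.5
    mode: str = "code_words"  # or "letters"
    n_informative: int = 12          # per feature band
    n_hand_channels: int = 8
    class_amplitude: float = 0.25
    hand_amplitude: float = 0.8
    activity_amplitude: float = 0.5  # state-dependent offset driving detection
    prep_amplitude: float = 0.4
    noise_sd: float = 1.0
    jitter_sd: float = 0.05          # s, go-cue alignment jitter
    length_scale_s: float = 0.15     # GP smoothness of templates
    template_seed: int = 0
    letter_truncation: float = 0.4   # letters use the first 40% of the code-word template
    letter_scale: float = 0.6

    # filled in __post_init__
    class_set: list[str] = field(default_factory=list)
    templates: dict = field(default_factory=dict, repr=False)
    informative_hga: np.ndarray = field(default=None, repr=False)
    informative_lfs: np.ndarray = field(default=None, repr=False)
    hand_channels: np.ndarray = field(default=None, repr=False)
    prep_channels: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        self.window_n = int(round(self.window_s * self.rate))
        if not self.class_set:
            base = LETTERS if self.mode == "letters" else CODE_WORDS
            self.class_set = list(base) + [HAND]
        rng = np.random.default_rng(self.template_seed)
        n = self.n_channels
        perm = rng.permutation(n)
        self.informative_hga = np.sort(perm[: self.n_informative])
        self.informative_lfs = np.sort(perm[self.n_informative : 2 * self.n_informative])
        self.hand_channels = np.sort(
            perm[2 * self.n_informative : 2 * self.n_informative + self.n_hand_channels]
        )
        # preparatory activity occupies its own (premotor-like) channel set so
        # the four behavioral states have distinct spatial signatures
        p0 = 2 * self.n_informative + self.n_hand_channels
        self.prep_channels = np.sort(perm[p0 : p0 + max(self.n_informative // 2, 2)])
        if not self.templates:
            self.templates = self._build_templates(rng)

    # -- template construction ---------------------------------------------

    def _gp_trace(self, rng: np.random.Generator, t: int) -> np.ndarray:
        sig = self.length_scale_s * self.rate
        x = gaussian_filter1d(rng.standard_normal(t), sig, mode="constant")
        rms = np.sqrt(np.mean(x**2))
        return x / max(rms, 1e-12)

    def _build_templates(self, rng: np.random.Generator) -> dict:
        t = self.window_n
        n = self.n_channels
        templates: dict[str, np.ndarray] = {}
        speech_classes = [c for c in self.class_set if c != HAND]
        base_classes = CODE_WORDS if self.mode == "letters" else speech_classes
        raw: dict[str, np.ndarray] = {}
        for c in base_classes:
            m = np.zeros((t, 2 * n))
            for ch in self.informative_hga:
                m[:, ch] = self._gp_trace(rng, t) * self.class_amplitude
            for ch in self.informative_lfs:
                m[:, n + ch] = self._gp_trace(rng, t) * self.class_amplitude
            raw[c] = m
        if self.mode == "letters":
            # letter responses: truncated, scaled code-word responses, so code
            # words are more discriminable by construction
            cut = int(round(self.letter_truncation * t))
            for letter, cw in zip(LETTERS, CODE_WORDS):
                m = np.zeros((t, 2 * n))
                m[:cut] = raw[cw][:cut] * self.letter_scale
                templates[letter] = m
        else:
            templates.update(raw)
        hand = np.zeros((t, 2 * n))
        for ch in self.hand_channels:
            hand[:, ch] = self._gp_trace(rng, t) * self.hand_amplitude
            hand[:, n + ch] = self._gp_trace(rng, t) * self.hand_amplitude
        templates[HAND] = hand
        return templates

    def activity_profile(self) -> np.ndarray:
        """Shared speech-state offset on informative channels (class-independent)."""
        t = self.window_n
        n = self.n_channels
        m = np.zeros((t, 2 * n))
        env = np.minimum(np.arange(t) / (0.25 * self.rate), 1.0) * self.activity_amplitude
        for ch in self.informative_hga:
            m[:, ch] = env
        for ch in self.informative_lfs:
            m[:, n + ch] = env
        return m

    def template_for(self, class_id: str) -> np.ndarray:
        """Mean window for a class: shared activity plus class template
        (hand trials carry only the hand-channel template)."""
        if class_id not in self.class_set:
            raise ValueError(f"unknown class {class_id!r}")
        if class_id == HAND:
            return self.templates[HAND].copy()
        return self.templates[class_id] + self.activity_profile()

    def variant(self, rho: float, seed: int) -> "SyntheticConfig":
        """A paired condition (e.g. overt vs silent speech attempts) whose
        class templates correlate ``rho`` with this config's templates."""
        other = SyntheticConfig(**{
            k: getattr(self, k)
            for k in ("n_channels", "rate", "window_s", "mode", "n_informative",
                      "n_hand_channels", "class_amplitude", "hand_amplitude",
                      "activity_amplitude", "prep_amplitude", "noise_sd",
                      "jitter_sd", "length_scale_s", "letter_truncation",
                      "letter_scale")
        }, template_seed=seed)
        # mix while preserving per-template scale
        mixed = {}
        for c, m in self.templates.items():
            fresh = other.templates[c]
            mixed[c] = rho * m + np.sqrt(max(1.0 - rho * rho, 0.0)) * fresh
        other.templates = mixed
        other.informative_hga = self.informative_hga
        other.informative_lfs = self.informative_lfs
        other.hand_channels = self.hand_channels
        return other


@dataclass
class LabeledSession:
    """A continuous synthetic session: feature stream plus ground truth."""

    stream: FeatureStream
    events: list[dict]                # onset_s, offset_s, state, label
    frame_states: np.ndarray          # int per frame, index into STATES
    trials: pd.DataFrame              # trial_id, label, go_cue_s

    def __post_init__(self) -> None:
        last = -np.inf
        for ev in self.events:
            if ev["onset_s"] < last:
                raise ValueError("events must be time-ordered and non-overlapping")
            last = ev["offset_s"]


def _jitter_shift(rng: np.random.Generator, config: SyntheticConfig) -> int:
    if config.jitter_sd <= 0:
        return 0
    return int(round(rng.normal(0.0, config.jitter_sd) * config.rate))


def _shifted(template: np.ndarray, shift: int) -> np.ndarray:
    if shift == 0:
        return template
    out = np.zeros_like(template)
    if shift > 0:
        out[shift:] = template[: len(template) - shift]
    else:
        out[:shift] = template[-shift:]
    return out


def generate_trial_window(
    class_id: str, config: SyntheticConfig, seed: int
) -> TrialWindow:
    """One go-cue-aligned window: class template + temporal jitter + noise.

    Emitted at the generator rate (200 Hz); decimate for the classifier.
    """
    rng = np.random.default_rng(seed)
    mean = config.template_for(class_id)  # validates class_id
    shift = _jitter_shift(rng, config)
    values = _shifted(mean, shift)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, values.shape)
    return TrialWindow(values, label=class_id, source="synthetic")


def generate_continuous_session(
    trial_plan: list[tuple[str, float]],
    config: SyntheticConfig,
    seed: int = 0,
    tail_s: float = 2.0,
) -> LabeledSession:
    """Continuous rest-background stream with preparation ramps before each
    go cue and class responses after it.

    ``trial_plan`` lists (class label, go-cue time in seconds); cues must be
    at least ``window_s`` apart.
    """
    rng = np.random.default_rng(seed)
    prep_s = 1.0
    cues = sorted(t for _, t in trial_plan)
    for a, b in zip(cues, cues[1:]):
        if b - a < config.window_s:
            raise ValueError("overlapping trials: go cues closer than the window length")
    dur = (max(cues) + config.window_s + tail_s) if trial_plan else 10.0
    n = int(round(dur * config.rate))
    nf = 2 * config.n_channels
    values = (
        rng.normal(0.0, config.noise_sd, (n, nf)) if config.noise_sd > 0 else np.zeros((n, nf))
    )
    states = np.zeros(n, dtype=int)  # rest
    events: list[dict] = []
    rows = []
    prep = np.zeros((0, nf))
    for trial_id, (label, cue) in enumerate(sorted(trial_plan, key=lambda p: p[1])):
        if label not in config.class_set:
            raise ValueError(f"unknown class {label!r}")
        i0 = int(round(cue * config.rate))
        i1 = min(i0 + config.window_n, n)
        # preparation ramp on informative channels before the cue
        p0 = max(i0 - int(prep_s * config.rate), 0)
        if p0 < i0:
            # fast on-ramp (200 ms) then hold, so the state boundary is sharp
            ramp = np.minimum(np.arange(i0 - p0) / (0.2 * config.rate), 1.0)[:, None]
            prep = np.zeros((i0 - p0, nf))
            cols = np.concatenate(
                [config.prep_channels, config.n_channels + config.prep_channels]
            )
            prep[:, cols] = ramp * config.prep_amplitude
            values[p0:i0] += prep
            states[p0:i0] = STATES.index("preparation")
        shift = _jitter_shift(rng, config)
        mean = _shifted(config.template_for(label), shift)
        values[i0:i1] += mean[: i1 - i0]
        state = "motor" if label == HAND else "speech"
        states[i0:i1] = STATES.index(state)
        events.append(
            {
                "onset_s": p0 / config.rate,
                "offset_s": i1 / config.rate,
                "state": state,
                "label": label,
                "go_cue_s": cue,
            }
        )
        rows.append({"trial_id": trial_id, "label": label, "go_cue_s": cue})
    stream = FeatureStream(values, rate=config.rate, normalized=True)
    trials = pd.DataFrame(rows, columns=["trial_id", "label", "go_cue_s"])
    return LabeledSession(stream=stream, events=events, frame_states=states, trials=trials)


def generate_sentence_trial(
    sentence: str, config: SyntheticConfig, seed: int = 0
) -> tuple[list[TrialWindow], str]:
    """Windows for a paced sentence-spelling trial.

    One window per letter (spaces are skipped; the decoder inserts them)
    plus a terminal hand-command window.  Returns (windows, truth) with the
    truth retaining its spaces.
    """
    if not sentence or any(c not in "abcdefghijklmnopqrstuvwxyz " for c in sentence):
        raise ValueError("sentence must use lowercase a-z and spaces")
    rng = np.random.default_rng(seed)
    labels = [
        (c if config.mode == "letters" else code_word_for(c)) for c in sentence if c != " "
    ] + [HAND]
    windows = []
    for i, lab in enumerate(labels):
        sub = int(rng.integers(2**31))
        windows.append(generate_trial_window(lab, config, seed=sub))
        windows[-1].go_cue_time = i * config.window_s
    return windows, sentence


def save_session(session: LabeledSession, prefix: str) -> None:
    """Serialize a session: HDF5 stream + JSON-lines events + CSV trials."""
    import json

    from .containers import save_stream

    save_stream(prefix + ".h5", session.stream)
    with open(prefix + ".events.jsonl", "w") as f:
        for ev in session.events:
            f.write(json.dumps(ev) + "\n")
    session.trials.to_csv(prefix + ".trials.csv", index=False)
    np.savetxt(prefix + ".states.txt", session.frame_states, fmt="%d")


def load_session(prefix: str) -> LabeledSession:
    import json

    from .containers import load_stream

    stream = load_stream(prefix + ".h5")
    with open(prefix + ".events.jsonl") as f:
        events = [json.loads(line) for line in f if line.strip()]
    trials = pd.read_csv(prefix + ".trials.csv")
    states = np.loadtxt(prefix + ".states.txt", dtype=int)
    return LabeledSession(stream=stream, events=events, frame_states=states, trials=trials)
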
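"""Silent-speech detection from the continuous 200 Hz feature stream.

A stacked-LSTM frame classifier labels every time point as rest, speech
preparation, motor, or speech; only the smoothed speech-state probability
gates engagement of the speller, via thresholding with hysteresis and a
minimum event duration.  Training uses truncated backpropagation through
time over labeled continuous sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import h5py
import numpy as np

from . import nn
from .containers import FeatureStream
from .synthetic import STATES, LabeledSession

__all__ = [
    "DetectorHyperparams",
    "DetectorModel",
    "DetectionEvent",
    "train_detector",
    "detect_speech_events",
]


@dataclass
class DetectorHyperparams:
    hidden: int = 48
    n_layers: int = 2
    lr: float = 3e-3
    epochs: int = 16
    tbptt_len: int = 250          # frames (1.25 s at 200 Hz)
    smoothing_s: float = 0.25     # causal moving average on speech probability
    onset_threshold: float = 0.5
    offset_threshold: float = 0.3
    min_duration_s: float = 0.5


@dataclass
class DetectionEvent:
    """A detected silent-speech attempt."""

    onset_s: float
    offset_s: float | None
    peak_probability: float

    def __post_init__(self) -> None:
        if self.offset_s is not None and self.offset_s <= self.onset_s:
            raise ValueError("offset must follow onset")


class DetectorModel:
    """Stacked-LSTM frame-state classifier with thresholding parameters."""

    state_set = list(STATES)

    def __init__(self, n_features: int, hyperparams: DetectorHyperparams, seed: int):
        hp = hyperparams
        for thr in (hp.onset_threshold, hp.offset_threshold):
            if not 0.0 < thr <= 1.0:
                raise ValueError("thresholds must lie in (0, 1]")
        self.n_features = n_features
        self.hp = hp
        self.seed = seed
        self.meta: dict = {}
        rng = np.random.default_rng(seed)
        self.lstms = []
        d_in = n_features
        for _ in range(hp.n_layers):
            self.lstms.append(nn.LSTM(d_in, hp.hidden, rng))
            d_in = hp.hidden
        self.out = nn.Dense(hp.hidden, len(STATES), rng)

    def params(self) -> list[nn.Param]:
        ps = self.out.params()
        for layer in self.lstms:
            ps += layer.params()
        return ps

    def forward(self, x: np.ndarray, train: bool = False, states=None):
        """x: (batch, time, features) -> frame logits (batch, time, 4).

        ``states`` carries (h, c) per layer across TBPTT chunks.
        """
        new_states = []
        y = x
        for i, layer in enumerate(self.lstms):
            y = layer.forward(y, train=train, state=None if states is None else states[i])
            new_states.append(layer.state)
        logits = self.out.forward(y, train)
        return logits, new_states

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dy = self.out.backward(dlogits)
        for layer in reversed(self.lstms):
            dy = layer.backward(dy)
        return dy

    def frame_probabilities(self, stream: FeatureStream) -> np.ndarray:
        """Per-frame 4-state probabilities for a continuous stream."""
        logits, _ = self.forward(stream.values[None], train=False)
        return nn.softmax(logits[0])

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            for i, p in enumerate(self.params()):
                f.create_dataset(f"param_{i}", data=p.value)
        with open(path + ".json", "w") as f:
            json.dump(
                {"n_features": self.n_features, "hyperparams": asdict(self.hp),
                 "seed": self.seed, "meta": self.meta},
                f, indent=1,
            )

    @classmethod
    def load(cls, path: str) -> "DetectorModel":
        with open(path + ".json") as f:
            side = json.load(f)
        model = cls(side["n_features"], DetectorHyperparams(**side["hyperparams"]), side["seed"])
        model.meta = side["meta"]
        with h5py.File(path, "r") as f:
            for i, p in enumerate(model.params()):
                p.value[...] = f[f"param_{i}"][...]
        return model


def train_detector(
    sessions: list[LabeledSession],
    hyperparams: DetectorHyperparams | None = None,
    seed: int = 0,
    verbose: bool = False,
) -> DetectorModel:
    """Supervised frame labeling with truncated backpropagation through time.

    Sessions are truncated to a common length and batched; LSTM state is
    carried (detached) across TBPTT chunks.  Deterministic given seed.
    """
    if not sessions:
        raise ValueError("no training sessions")
    hp = hyperparams or DetectorHyperparams()
    present = set()
    for s in sessions:
        present.update(np.unique(s.frame_states).tolist())
    if present != set(range(len(STATES))):
        missing = [STATES[i] for i in range(len(STATES)) if i not in present]
        raise ValueError(f"training sessions missing frame states: {missing}")

    n_feat = sessions[0].stream.n_features
    t_min = min(s.stream.n_samples for s in sessions)
    x = np.stack([s.stream.values[:t_min] for s in sessions])
    y = np.stack([s.frame_states[:t_min] for s in sessions])
    model = DetectorModel(n_feat, hp, seed)
    opt = nn.Adam(model.params(), lr=hp.lr)
    for epoch in range(hp.epochs):
        states = None
        total, count = 0.0, 0
        for i0 in range(0, t_min, hp.tbptt_len):
            xb = x[:, i0 : i0 + hp.tbptt_len]
            yb = y[:, i0 : i0 + hp.tbptt_len]
            logits, states = model.forward(xb, train=True, states=states)
            loss, dlogits, _ = nn.softmax_xent(logits, yb)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            total += loss
            count += 1
        if verbose:
            print(f"epoch {epoch}: loss {total / count:.4f}")
    model.meta = {"seed": seed, "epochs": hp.epochs, "n_sessions": len(sessions)}
    return model


def _causal_moving_average(p: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return p
    c = np.cumsum(np.concatenate([[0.0], p]))
    idx = np.arange(len(p))
    lo = np.maximum(idx - width + 1, 0)
    return (c[idx + 1] - c[lo]) / (idx + 1 - lo)


def detect_speech_events(
    model: DetectorModel, stream: FeatureStream
) -> list[DetectionEvent]:
    """Threshold the smoothed speech probability into detection events.

    An event is a contiguous region above the offset threshold that contains
    a run of at least ``min_duration_s`` above the onset threshold
    (hysteresis debouncing); only the speech-state probability is used.
    Raising the onset threshold can only remove events, never add them, and
    detection is causal (trailing moving-average smoothing).
    """
    hp = model.hp
    probs = model.frame_probabilities(stream)
    speech = probs[:, STATES.index("speech")]
    width = max(1, int(round(hp.smoothing_s * stream.rate)))
    smoothed = _causal_moving_average(speech, width)
    min_frames = int(round(hp.min_duration_s * stream.rate))

    events: list[DetectionEvent] = []
    above_off = smoothed >= hp.offset_threshold
    t = 0
    n = len(smoothed)
    while t < n:
        if not above_off[t]:
            t += 1
            continue
        start = t
        while t < n and above_off[t]:
            t += 1
        end = t  # region [start, end)
        seg = smoothed[start:end] >= hp.onset_threshold
        # longest run above the onset threshold, and its start
        run, best, onset_i = 0, 0, None
        cur_start = None
        for i, flag in enumerate(seg):
            if flag:
                if run == 0:
                    cur_start = i
                run += 1
                if run > best:
                    best = run
                    if best >= min_frames and onset_i is None:
                        onset_i = cur_start
            else:
                run = 0
        if best >= min_frames and onset_i is not None:
            events.append(
                DetectionEvent(
                    onset_s=(start + onset_i) / stream.rate,
                    offset_s=end / stream.rate,
                    peak_probability=float(smoothed[start:end].max()),
                )
            )
    return events
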
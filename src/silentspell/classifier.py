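"""27-class code-word / hand-command classification of 2.5-s feature windows.

Each letter-decoding cycle yields a window ``x_i`` of decimated, normalized
HGA+LFS features; the classifier estimates ``p(y_i | x_i)`` over the 26 NATO
code words plus the attempted hand squeeze that finalizes a sentence.
Training minimizes cross-entropy (maximum likelihood over the training
labels) with Adam.  The architecture is a 1-D temporal convolution followed
by bidirectional GRU layers and a softmax output read from the final
recurrent states.  Ensembling averages the probability outputs of several
models trained from different random initializations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import h5py
import numpy as np

from . import nn

__all__ = [
    "CODE_WORDS",
    "HAND",
    "LETTERS",
    "class_set_27",
    "class_set_26",
    "letter_for",
    "code_word_for",
    "TrialWindow",
    "ClassifierHyperparams",
    "ClassifierModel",
    "ClassProbabilities",
    "ProbabilitySequence",
    "train_classifier",
    "ensemble_predict",
    "ensemble_predict_many",
    "select_recalibration_trials",
    "stratified_folds",
]

CODE_WORDS = [
    "alpha", "bravo", "charlie", "delta", "echo", "foxtrot", "golf", "hotel",
    "india", "juliett", "kilo", "lima", "mike", "november", "oscar", "papa",
    "quebec", "romeo", "sierra", "tango", "uniform", "victor", "whiskey",
    "xray", "yankee", "zulu",
]
HAND = "hand"
LETTERS = [chr(ord("a") + i) for i in range(26)]
_LETTER_TO_CODE = dict(zip(LETTERS, CODE_WORDS))
_CODE_TO_LETTER = dict(zip(CODE_WORDS, LETTERS))


def class_set_27() -> list[str]:
    """26 NATO code words plus the hand-motor finalization command."""
    return CODE_WORDS + [HAND]


def class_set_26() -> list[str]:
    return list(CODE_WORDS)


def code_word_for(letter: str) -> str:
    return _LETTER_TO_CODE[letter]


def letter_for(code_word: str) -> str:
    return _CODE_TO_LETTER[code_word]


@dataclass
class TrialWindow:
    """One go-cue-aligned 2.5-s feature window with its class label."""

    features: np.ndarray  # time x feature, decimated rate
    label: str | None = None
    go_cue_time: float = 0.0
    source: str = "synthetic"  # isolated-target | sentence | synthetic

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("features must be time x feature")


@dataclass
class ClassProbabilities:
    """Normalized per-class probability vector for one window."""

    probs: np.ndarray
    class_set: list[str]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (len(self.class_set),):
            raise ValueError("probability vector length must match class set")
        if not np.all(self.probs >= -1e-12) or abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be nonnegative and sum to 1")

    def top_class(self) -> str:
        return self.class_set[int(np.argmax(self.probs))]

    def get(self, name: str) -> float:
        return float(self.probs[self.class_set.index(name)])


@dataclass
class ProbabilitySequence:
    """Ordered per-cycle class probabilities X_{1:T} feeding the beam search."""

    steps: list[ClassProbabilities]

    def __post_init__(self) -> None:
        if self.steps:
            cs = self.steps[0].class_set
            if any(s.class_set != cs for s in self.steps):
                raise ValueError("all steps must share one class set")

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)

    def __getitem__(self, i):
        return self.steps[i]

    @property
    def class_set(self) -> list[str]:
        return self.steps[0].class_set

    def array(self) -> np.ndarray:
        return np.stack([s.probs for s in self.steps])

    @classmethod
    def from_array(cls, arr: np.ndarray, class_set: list[str]) -> "ProbabilitySequence":
        return cls([ClassProbabilities(row, class_set) for row in arr])


@dataclass
class ClassifierHyperparams:
    """Desk-scale defaults; the clinical sizes are not published and all of
    these are exposed in configuration."""

    conv_kernel: int = 5
    conv_stride: int = 3
    conv_filters: int = 32
    hidden: int = 32
    n_gru_layers: int = 2
    dropout: float = 0.2
    lr: float = 2e-3
    epochs: int = 50
    batch_size: int = 64
    patience: int = 7
    val_fraction: float = 0.1
    augment: bool = False
    noise_aug_sd: float = 0.1
    shift_aug_s: float = 0.12
    readout: str = "final"  # "final" uses end states; "mean" pools GRU outputs over time
    weight_decay: float = 0.0


class ClassifierModel:
    """Conv + bidirectional-GRU window classifier."""

    def __init__(
        self,
        n_features: int,
        n_time: int,
        class_set: list[str],
        hyperparams: ClassifierHyperparams,
        seed: int,
    ):
        self.n_features = n_features
        self.n_time = n_time
        self.class_set = list(class_set)
        self.hp = hyperparams
        self.seed = seed
        self.meta: dict = {}
        rng = np.random.default_rng(seed)
        hp = hyperparams
        self.conv = nn.Conv1D(n_features, hp.conv_filters, hp.conv_kernel, hp.conv_stride, rng)
        self.relu = nn.ReLU()
        self.drop = nn.Dropout(hp.dropout, np.random.default_rng(rng.integers(2**31)))
        self.grus = []
        d_in = hp.conv_filters
        for _ in range(hp.n_gru_layers):
            self.grus.append(nn.BiGRU(d_in, hp.hidden, rng))
            d_in = 2 * hp.hidden
        self.out = nn.Dense(2 * hp.hidden, len(class_set), rng)

    # -- forward / backward -------------------------------------------------

    def params(self) -> list[nn.Param]:
        ps = self.conv.params() + self.out.params()
        for g in self.grus:
            ps += g.params()
        return ps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (batch, time, features) -> logits (batch, classes)."""
        y = self.conv.forward(x, train)
        y = self.relu.forward(y, train)
        y = self.drop.forward(y, train)
        for g in self.grus:
            y = g.forward(y, train)
        h = self.hp.hidden
        self._seq_shape = y.shape
        if self.hp.readout == "mean":
            self._feat = y.mean(axis=1)
        else:  # final forward state and final (t=0) backward state
            self._feat = np.concatenate([y[:, -1, :h], y[:, 0, h:]], axis=1)
        return self.out.forward(self._feat, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dfeat = self.out.backward(dlogits)
        h = self.hp.hidden
        dseq = np.zeros(self._seq_shape)
        if self.hp.readout == "mean":
            dseq += dfeat[:, None, :] / self._seq_shape[1]
        else:
            dseq[:, -1, :h] = dfeat[:, :h]
            dseq[:, 0, h:] = dfeat[:, h:]
        dy = dseq
        for g in reversed(self.grus):
            dy = g.backward(dy)
        dy = self.drop.backward(dy)
        dy = self.relu.backward(dy)
        return self.conv.backward(dy)

    # -- inference ----------------------------------------------------------

    def predict_proba(self, windows: list[TrialWindow] | np.ndarray) -> np.ndarray:
        x = _stack(windows)
        out = np.empty((x.shape[0], len(self.class_set)))
        bs = 256
        for i in range(0, x.shape[0], bs):
            out[i : i + bs] = nn.softmax(self.forward(x[i : i + bs], train=False))
        return out

    def predict(self, windows: list[TrialWindow] | np.ndarray) -> list[str]:
        p = self.predict_proba(windows)
        return [self.class_set[i] for i in np.argmax(p, axis=1)]

    def input_gradients(self, windows: list[TrialWindow]) -> np.ndarray:
        """d(loss)/d(input) per trial (batch, time, features); labels required."""
        x = _stack(windows)
        labels = np.array([self.class_set.index(w.label) for w in windows])
        logits = self.forward(x, train=False)
        _, dlogits, _ = nn.softmax_xent(logits, labels)
        return self.backward(dlogits * len(labels))  # per-trial, not mean-scaled

    # -- serialization ------------------------------------------------------

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            for i, p in enumerate(self.params()):
                f.create_dataset(f"param_{i}", data=p.value)
        side = {
            "n_features": self.n_features,
            "n_time": self.n_time,
            "class_set": self.class_set,
            "hyperparams": asdict(self.hp),
            "seed": self.seed,
            "meta": self.meta,
        }
        with open(path + ".json", "w") as f:
            json.dump(side, f, indent=1)

    @classmethod
    def load(cls, path: str) -> "ClassifierModel":
        with open(path + ".json") as f:
            side = json.load(f)
        model = cls(
            side["n_features"],
            side["n_time"],
            side["class_set"],
            ClassifierHyperparams(**side["hyperparams"]),
            side["seed"],
        )
        model.meta = side["meta"]
        with h5py.File(path, "r") as f:
            for i, p in enumerate(model.params()):
                p.value[...] = f[f"param_{i}"][...]
        return model


def _stack(windows) -> np.ndarray:
    if isinstance(windows, np.ndarray):
        return windows if windows.ndim == 3 else windows[None]
    return np.stack([w.features for w in windows])


def _stratified_split(labels: np.ndarray, fraction: float, rng: np.random.Generator):
    """Return (train_idx, val_idx) with per-class proportional allocation."""
    val = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        k = max(1, int(round(len(idx) * fraction)))
        val.extend(idx[:k])
    val = np.sort(np.array(val))
    train = np.setdiff1d(np.arange(len(labels)), val)
    return train, val


def stratified_folds(labels: list[str], n_folds: int, seed: int) -> list[np.ndarray]:
    """Stratified fold assignment: per-fold class counts differ by at most 1."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(n_folds)]
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        for j, i in enumerate(idx):
            folds[j % n_folds].append(i)
    return [np.sort(np.array(f)) for f in folds]


def train_classifier(
    train: list[TrialWindow],
    hyperparams: ClassifierHyperparams | None = None,
    seed: int = 0,
    init_from: ClassifierModel | None = None,
    class_set: list[str] | None = None,
    verbose: bool = False,
) -> ClassifierModel:
    """Fit the window classifier by cross-entropy minimization.

    Deterministic given (data, seed).  A stratified 10% validation split of
    the training set drives early stopping.  ``init_from`` warm-starts the
    parameters (pretrain/fine-tune scheme across speech types).
    """
    if not train:
        raise ValueError("empty training set")
    hp = hyperparams or ClassifierHyperparams()
    if class_set is None:
        class_set = init_from.class_set if init_from is not None else class_set_27()
    for w in train:
        if w.label not in class_set:
            raise ValueError(f"label {w.label!r} outside class set")
    if init_from is not None and init_from.class_set != class_set:
        raise ValueError("init_from class set does not match")

    x = _stack(train)
    y = np.array([class_set.index(w.label) for w in train])
    model = ClassifierModel(x.shape[2], x.shape[1], class_set, hp, seed)
    if init_from is not None:
        for p, q in zip(model.params(), init_from.params()):
            p.value[...] = q.value
    rng = np.random.default_rng(seed + 1)
    tr_idx, val_idx = _stratified_split(y, hp.val_fraction, rng)
    if len(tr_idx) == 0:
        tr_idx = val_idx
    xv, yv = x[val_idx], y[val_idx]
    opt = nn.Adam(model.params(), lr=hp.lr, weight_decay=hp.weight_decay)

    best_val, best_params, best_epoch, since = -1.0, None, 0, 0
    shift_max = 0
    if hp.augment:
        # shift in samples at the (decimated) window rate
        shift_max = max(1, int(round(hp.shift_aug_s * x.shape[1] / 2.5)))
    for epoch in range(hp.epochs):
        order = rng.permutation(tr_idx)
        for i in range(0, len(order), hp.batch_size):
            idx = order[i : i + hp.batch_size]
            xb = x[idx]
            if hp.augment:
                xb = xb + rng.normal(0, hp.noise_aug_sd, xb.shape)
                s = int(rng.integers(-shift_max, shift_max + 1))
                xb = np.roll(xb, s, axis=1)
            logits = model.forward(xb, train=True)
            _, dlogits, _ = nn.softmax_xent(logits, y[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
        val_acc = float(np.mean(np.argmax(model.predict_proba(xv), axis=1) == yv))
        if verbose:
            print(f"epoch {epoch}: val acc {val_acc:.3f}")
        if val_acc > best_val + 1e-12:
            best_val, best_epoch, since = val_acc, epoch, 0
            best_params = [p.value.copy() for p in model.params()]
        else:
            since += 1
            if since >= hp.patience:
                break
    if best_params is not None:
        for p, v in zip(model.params(), best_params):
            p.value[...] = v
    model.meta = {"val_accuracy": best_val, "best_epoch": best_epoch, "seed": seed}
    return model


def ensemble_predict(models: list[ClassifierModel], window: TrialWindow) -> ClassProbabilities:
    """Arithmetic mean of the per-model probability vectors for one window."""
    return ensemble_predict_many(models, [window])[0]


def ensemble_predict_many(
    models: list[ClassifierModel], windows: list[TrialWindow]
) -> list[ClassProbabilities]:
    if not models:
        raise ValueError("need at least one model")
    cs = models[0].class_set
    if any(m.class_set != cs for m in models):
        raise ValueError("all ensemble members must share one class set")
    x = _stack(windows)
    mean = np.zeros((x.shape[0], len(cs)))
    for m in models:
        mean += m.predict_proba(x)
    mean /= len(models)
    mean /= mean.sum(axis=1, keepdims=True)
    return [ClassProbabilities(row, cs) for row in mean]


def select_recalibration_trials(
    sentence_trials: list[tuple[str, str, list[TrialWindow]]],
) -> list[TrialWindow]:
    """Keep windows only from sentence trials decoded with zero character
    error; label them from the truth letter sequence plus the terminal hand
    command."""
    from .metrics import edit_distance

    selected: list[TrialWindow] = []
    for decoded, truth, windows in sentence_trials:
        if edit_distance(decoded, truth, level="character") != 0:
            continue
        letters = [c for c in truth if c != " "]
        labels = [code_word_for(c) for c in letters] + [HAND]
        if len(labels) != len(windows):
            raise ValueError("window count does not match truth letter count")
        for w, lab in zip(windows, labels):
            selected.append(
                TrialWindow(w.features, label=lab, go_cue_time=w.go_cue_time, source="sentence")
            )
    return selected
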
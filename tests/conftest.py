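"""Shared fixtures: small synthetic configurations and toy language models.

All fixtures are generated programmatically and seeded, so the suite is
deterministic and ships no data files.
"""

import numpy as np
import pytest

from silentspell.beam_search import DecoderConfig
from silentspell.language_model import build_vocabulary, fit_ngram_lm
from silentspell.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def small_synth():
    """A reduced-channel generator configuration for fast model training."""
    return SyntheticConfig(
        n_channels=16, n_informative=4, n_hand_channels=3, class_amplitude=0.4,
        hand_amplitude=3.5, template_seed=7,
    )


@pytest.fixture(scope="session")
def default_synth():
    """The generator at its default (study) conditions."""
    return SyntheticConfig()


@pytest.fixture(scope="session")
def toy_vocab():
    return build_vocabulary(["at", "an", "to", "a", "i", "it", "tan", "ant"])


@pytest.fixture(scope="session")
def toy_lm(toy_vocab):
    corpus = [
        "a tan ant", "an ant", "to a tan ant", "i tan", "it is a tan ant",
        "at it", "a tan tan ant", "i to it", "an an an",
    ]
    return fit_ngram_lm(corpus, toy_vocab)


@pytest.fixture
def decoder_cfg():
    return DecoderConfig(alpha=0.5, beta=1.0, beam_width=100)


def make_windows(config, n_per_class, seed, classes=None, decimate=True):
    """Labeled decimated trial windows for each class."""
    from silentspell.pipeline import decimate_window
    from silentspell.synthetic import generate_trial_window

    rng = np.random.default_rng(seed)
    out = []
    for c in classes or config.class_set:
        for _ in range(n_per_class):
            w = generate_trial_window(c, config, seed=int(rng.integers(2**31)))
            out.append(decimate_window(w) if decimate else w)
    return out


def uniform_over(class_set, peaked=None, p=0.9):
    """A probability vector: uniform, or peaked on one class."""
    n = len(class_set)
    if peaked is None:
        return np.full(n, 1.0 / n)
    v = np.full(n, (1.0 - p) / (n - 1))
    v[class_set.index(peaked)] = p
    return v
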
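"""Global configuration: one YAML file mapping to the per-module dataclasses.

Section names and keys mirror the dataclass fields, e.g.::

    features:   {hga_band: [70, 150], lfs_cutoff: 100, stream_rate: 200,
                 zscore_window_s: 30, artifact_feature_count: 32,
                 artifact_z: 10, decimation_factor: 6}
    synthetic:  {n_channels: 128, noise_sd: 1.0, class_amplitude: 0.1}
    classifier: {hidden: 32, conv_filters: 32, epochs: 50}
    detector:   {hidden: 32, onset_threshold: 0.5, offset_threshold: 0.3}
    decoder:    {alpha: 0.5, beta: 1.0, beam_width: 200, letter_floor: 0.001,
                 alpha_rescore: 0.5, hand_threshold: 0.8}

Omitted sections and keys fall back to the dataclass defaults.
"""

from __future__ import annotations

from dataclasses import asdict
from importlib import resources

import yaml

from .beam_search import DecoderConfig
from .classifier import ClassifierHyperparams
from .detector import DetectorHyperparams
from .signal_features import FeatureConfig
from .synthetic import SyntheticConfig

__all__ = ["load_config", "default_config", "dump_config",
           "packaged_corpus", "packaged_vocabulary"]

_SECTIONS = {
    "features": FeatureConfig,
    "synthetic": SyntheticConfig,
    "classifier": ClassifierHyperparams,
    "detector": DetectorHyperparams,
    "decoder": DecoderConfig,
}

_SYNTH_KEYS = (
    "n_channels", "rate", "window_s", "mode", "n_informative", "n_hand_channels",
    "class_amplitude", "hand_amplitude", "activity_amplitude", "prep_amplitude",
    "noise_sd", "jitter_sd", "length_scale_s", "template_seed",
    "letter_truncation", "letter_scale",
)


def default_config() -> dict:
    return {name: cls() for name, cls in _SECTIONS.items()}


def load_config(path: str | None) -> dict:
    """Build the per-module config objects from a YAML file (or defaults)."""
    raw = {}
    if path is not None:
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
    out = {}
    for name, cls in _SECTIONS.items():
        kwargs = dict(raw.get(name, {}))
        if name == "features" and "hga_band" in kwargs:
            kwargs["hga_band"] = tuple(kwargs["hga_band"])
        out[name] = cls(**kwargs)
    return out


def dump_config(config: dict, path: str) -> None:
    """Snapshot the active configuration (scalar fields only) to YAML."""
    raw = {}
    for name, obj in config.items():
        d = asdict(obj)
        if name == "synthetic":
            d = {k: d[k] for k in _SYNTH_KEYS}
        raw[name] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in d.items()
            if isinstance(v, (int, float, str, bool, tuple, list))
        }
    with open(path, "w") as f:
        yaml.safe_dump(raw, f, sort_keys=True)


def packaged_corpus() -> list[str]:
    """The packaged toy sentence corpus (assistive-communication style)."""
    text = resources.files("silentspell").joinpath("data/toy_corpus.txt").read_text()
    return [line for line in text.splitlines() if line.strip()]


def packaged_vocabulary() -> list[str]:
    text = resources.files("silentspell").joinpath("data/toy_vocab.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]
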
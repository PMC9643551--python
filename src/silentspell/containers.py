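"""In-memory containers for recordings and feature streams, with HDF5 I/O.

A :class:`RawRecording` holds a channels x time voltage matrix at the
acquisition rate (nominally 1 kHz).  A :class:`FeatureStream` holds a
time x feature matrix of neural features: high-gamma analytic amplitude
(HGA) for every channel followed by low-frequency signals (LFS) for every
channel, so the feature count is always twice the channel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["RawRecording", "FeatureStream", "feature_order", "save_stream", "load_stream"]


def feature_order(n_channels: int) -> list[str]:
    """Canonical feature naming: hga0..hgaN-1 then lfs0..lfsN-1."""
    return [f"hga{i}" for i in range(n_channels)] + [f"lfs{i}" for i in range(n_channels)]


@dataclass
class RawRecording:
    """Multichannel voltage recording (channels x time, microvolts)."""

    samples: np.ndarray
    rate: float = 1000.0
    channel_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time matrix")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.samples.shape[0])
        self.channel_ids = np.asarray(self.channel_ids)
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError("channel_ids length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass
class FeatureStream:
    """Time x feature matrix of dual-band neural features.

    ``values[t, f]`` with features ordered HGA ch0..N-1 then LFS ch0..N-1.
    ``artifact_mask[t]`` is True where the artifact-rejection rule fired;
    ``warmup_mask[t]`` is True where filters or running statistics had not
    yet settled and values should not be trusted.
    """

    values: np.ndarray
    rate: float
    normalized: bool = False
    artifact_mask: np.ndarray | None = None
    warmup_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D time x feature matrix")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        n = self.values.shape[0]
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(n, dtype=bool)
        if self.warmup_mask is None:
            self.warmup_mask = np.zeros(n, dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        self.warmup_mask = np.asarray(self.warmup_mask, dtype=bool)
        if len(self.artifact_mask) != n or len(self.warmup_mask) != n:
            raise ValueError("masks must match the time dimension")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        if self.n_features % 2:
            raise ValueError("feature count is not 2 x channel count")
        return self.n_features // 2

    def hga(self) -> np.ndarray:
        """HGA half of the feature matrix (time x channels)."""
        return self.values[:, : self.n_channels]

    def lfs(self) -> np.ndarray:
        """LFS half of the feature matrix (time x channels)."""
        return self.values[:, self.n_channels :]

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate


def save_stream(path: str, stream: FeatureStream) -> None:
    """Write a feature stream to an HDF5 container with rate/order attributes."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=stream.values)
        d.attrs["rate"] = stream.rate
        d.attrs["normalized"] = stream.normalized
        d.attrs["feature_order"] = ",".join(feature_order(stream.n_channels))
        f.create_dataset("artifact_mask", data=stream.artifact_mask)
        f.create_dataset("warmup_mask", data=stream.warmup_mask)


def load_stream(path: str) -> FeatureStream:
    with h5py.File(path, "r") as f:
        d = f["values"]
        return FeatureStream(
            values=d[...],
            rate=float(d.attrs["rate"]),
            normalized=bool(d.attrs["normalized"]),
            artifact_mask=f["artifact_mask"][...],
            warmup_mask=f["warmup_mask"][...],
        )
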
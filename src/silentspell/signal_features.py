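"""Dual-band ECoG feature extraction and streaming normalization.

The pipeline converts a common-average-referenced 1 kHz recording into a
single 200 Hz feature stream holding, per channel, the high-gamma analytic
amplitude (HGA, 70-150 Hz band) and the anti-aliased low-frequency signal
(LFS, low-passed at 100 Hz).  The stream is z-scored per feature against a
30-s sliding window with an artifact-rejection rule, and the classifier path
is further decimated by a factor of 6 behind an anti-aliasing filter with a
16.67 Hz cutoff.

All filters are causal equiripple FIRs; outputs are reported delay-
compensated (shifted back by the group delay), so a real-time consumer would
see each value ``group_delay_s`` seconds after the sample it is aligned to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .containers import FeatureStream, RawRecording

__all__ = [
    "FeatureConfig",
    "NormalizerState",
    "common_average_reference",
    "extract_feature_stream",
    "normalize_stream",
    "decimate_stream",
]


@dataclass
class FeatureConfig:
    """Feature-extraction parameters (units: Hz unless noted)."""

    hga_band: tuple[float, float] = (70.0, 150.0)
    lfs_cutoff: float = 100.0
    stream_rate: float = 200.0
    transition_hz: float = 5.0          # FIR transition-band half width
    stopband_db: float = 40.0
    zscore_window_s: float = 30.0
    artifact_feature_count: int = 32
    artifact_z: float = 10.0
    artifact_min_samples: int = 200     # disable artifact rule before this many stats samples
    sigma_floor: float = 1e-6
    decimation_factor: int = 6


DEFAULT_CONFIG = FeatureConfig()


def common_average_reference(raw: RawRecording) -> RawRecording:
    """Subtract the across-channel mean from every time sample.

    Per-sample and causally safe; removes noise shared by all electrodes.
    """
    if raw.n_channels < 2:
        raise ValueError("common average reference requires at least 2 channels")
    ref = raw.samples.mean(axis=0, keepdims=True)
    return RawRecording(raw.samples - ref, rate=raw.rate, channel_ids=raw.channel_ids)


def _n_taps(fs: float, transition_hz: float, atten_db: float) -> int:
    n, _ = sps.kaiserord(atten_db + 5.0, 2.0 * transition_hz / fs)
    return n | 1  # odd length -> integer group delay


@lru_cache(maxsize=8)
def _hga_filter(fs: float, lo: float, hi: float, trans: float, atten: float) -> tuple[np.ndarray, int]:
    """Complex analytic band-pass FIR: real part band-passes 70-150 Hz, the
    imaginary part is its quadrature pair, so |x * h| is the analytic
    amplitude of the band."""
    numtaps = _n_taps(fs, trans, atten)
    h = sps.remez(
        numtaps,
        [0, lo - trans, lo, hi, hi + trans, fs / 2],
        [0, 1, 0],
        fs=fs,
    )
    h_analytic = sps.hilbert(h)  # analytic pair of the coefficient sequence
    return h_analytic, (numtaps - 1) // 2


@lru_cache(maxsize=8)
def _lowpass_filter(fs: float, cutoff: float, trans: float, atten: float) -> tuple[np.ndarray, int]:
    numtaps = _n_taps(fs, trans, atten)
    h = sps.remez(
        numtaps,
        [0, cutoff - trans / 2, cutoff + trans / 2, fs / 2],
        [1, 0],
        fs=fs,
    )
    return h, (numtaps - 1) // 2


def _filter_aligned(h: np.ndarray, x: np.ndarray, gd: int) -> np.ndarray:
    """FIR along axis 0 with group-delay compensation.

    The filter itself is causal with delay ``gd``; for offline alignment the
    output is shifted back by ``gd`` samples, with reflected padding at both
    ends so output length equals input length.  The first samples are
    warm-up; the last ``gd`` samples lean on reflected padding.
    """
    if gd == 0:
        return sps.lfilter(h, 1.0, x, axis=0)
    if x.shape[0] > gd:
        head = x[1 : gd + 1][::-1]
        tail = x[-gd - 1 : -1][::-1]
    else:  # recording shorter than the filter: zero padding, all warm-up
        head = np.zeros((gd,) + x.shape[1:], dtype=x.dtype)
        tail = head
    xp = np.concatenate([head, x, tail], axis=0)
    y = sps.lfilter(h, 1.0, xp, axis=0)
    return y[2 * gd :]


def extract_feature_stream(
    raw: RawRecording, config: FeatureConfig = DEFAULT_CONFIG
) -> FeatureStream:
    """Extract the combined HGA+LFS feature stream at 200 Hz.

    HGA features are the analytic amplitude of the 70-150 Hz band; LFS
    features are the signal low-passed at 100 Hz.  Both are computed at the
    acquisition rate with time-aligned FIRs of equal length, then subsampled
    to ``config.stream_rate``.
    """
    fs = raw.rate
    step = fs / config.stream_rate
    if abs(step - round(step)) > 1e-9:
        raise ValueError("acquisition rate must be an integer multiple of stream_rate")
    step = int(round(step))

    h_hga, gd1 = _hga_filter(fs, *config.hga_band, config.transition_hz, config.stopband_db)
    h_lfs, gd2 = _lowpass_filter(fs, config.lfs_cutoff, config.transition_hz, config.stopband_db)
    gd = max(gd1, gd2)
    x = raw.samples.T  # time x channels

    warmup_n = max(len(h_hga), len(h_lfs))
    if raw.n_samples < warmup_n:
        import warnings

        warnings.warn(
            "recording shorter than filter warm-up; all samples flagged as warm-up",
            stacklevel=2,
        )

    hga = np.abs(_filter_aligned(h_hga, x.astype(complex), gd1))
    lfs = _filter_aligned(h_lfs, x, gd2)

    values = np.concatenate([hga[::step], lfs[::step]], axis=1)
    warmup = np.zeros(values.shape[0], dtype=bool)
    warmup[: int(np.ceil(warmup_n / step))] = True
    return FeatureStream(
        values,
        rate=config.stream_rate,
        normalized=False,
        warmup_mask=warmup,
        meta={"group_delay_s": gd / fs},
    )


# ---------------------------------------------------------------------------
# Streaming z-score normalization with artifact rejection
# ---------------------------------------------------------------------------


@dataclass
class NormalizerState:
    """Running per-feature statistics over a sliding window.

    The z-score of sample ``t`` is computed against the unmasked samples in
    the preceding ``window_span`` seconds (expanding window during warm-up).
    A sample where at least ``artifact_feature_count`` features exceed
    ``|z| > artifact_z`` is masked: its z-values are copied from the previous
    time point and it never enters the statistics.
    """

    n_features: int
    rate: float
    window_span: float = 30.0
    sigma_floor: float = 1e-6
    artifact_feature_count: int = 32
    artifact_z: float = 10.0
    artifact_min_samples: int = 200
    ddof: int = 0  # population variance by default; config choice

    _buf: np.ndarray = field(init=False, repr=False)
    _included: np.ndarray = field(init=False, repr=False)
    _sum: np.ndarray = field(init=False, repr=False)
    _sumsq: np.ndarray = field(init=False, repr=False)
    _count: int = field(init=False, default=0)
    _pos: int = field(init=False, default=0)
    _filled: int = field(init=False, default=0)
    _last_z: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.window_n = int(round(self.window_span * self.rate))
        self._buf = np.zeros((self.window_n, self.n_features))
        self._included = np.zeros(self.window_n, dtype=bool)
        self._sum = np.zeros(self.n_features)
        self._sumsq = np.zeros(self.n_features)
        self._last_z = np.zeros(self.n_features)

    @property
    def n_stat_samples(self) -> int:
        return self._count

    def _evict(self) -> None:
        if self._filled == self.window_n and self._included[self._pos]:
            old = self._buf[self._pos]
            self._sum -= old
            self._sumsq -= old * old
            self._count -= 1
            self._included[self._pos] = False

    def _admit(self, x: np.ndarray, include: bool) -> None:
        self._buf[self._pos] = x
        self._included[self._pos] = include
        if include:
            self._sum += x
            self._sumsq += x * x
            self._count += 1
        self._pos = (self._pos + 1) % self.window_n
        self._filled = min(self._filled + 1, self.window_n)

    def process(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Normalize a chunk strictly in time order.

        Returns (z-scores, artifact mask).  Calling this repeatedly on
        consecutive chunks is bit-identical to a single call on their
        concatenation.
        """
        values = np.asarray(values, dtype=np.float64)
        out = np.empty_like(values)
        mask = np.zeros(values.shape[0], dtype=bool)
        for t in range(values.shape[0]):
            x = values[t]
            if self._count >= 2:
                mean = self._sum / self._count
                var = self._sumsq / self._count - mean * mean
                if self.ddof:
                    var = var * self._count / max(self._count - self.ddof, 1)
                std = np.sqrt(np.maximum(var, 0.0))
                std = np.maximum(std, self.sigma_floor)
                z = (x - mean) / std
            else:
                z = np.zeros(self.n_features)
            artifact = (
                self._count >= self.artifact_min_samples
                and int(np.count_nonzero(np.abs(z) > self.artifact_z))
                >= self.artifact_feature_count
            )
            self._evict()
            if artifact:
                out[t] = self._last_z
                mask[t] = True
                self._admit(x, include=False)
            else:
                out[t] = z
                self._last_z = z
                self._admit(x, include=True)
        return out, mask


def normalize_stream(
    stream: FeatureStream,
    state: NormalizerState | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> FeatureStream:
    """Z-score a feature stream against 30-s sliding statistics (streamable)."""
    if stream.normalized:
        raise ValueError("stream is already normalized")
    if state is None:
        state = NormalizerState(
            n_features=stream.n_features,
            rate=stream.rate,
            window_span=config.zscore_window_s,
            sigma_floor=config.sigma_floor,
            artifact_feature_count=config.artifact_feature_count,
            artifact_z=config.artifact_z,
            artifact_min_samples=config.artifact_min_samples,
        )
    z, artifact = state.process(stream.values)
    warmup = stream.warmup_mask.copy()
    warmup[: min(state.window_n, len(warmup))] = True
    return FeatureStream(
        z,
        rate=stream.rate,
        normalized=True,
        artifact_mask=artifact | stream.artifact_mask,
        warmup_mask=warmup,
        meta=dict(stream.meta),
    )


def decimate_stream(
    stream: FeatureStream, factor: int | None = None, config: FeatureConfig = DEFAULT_CONFIG
) -> FeatureStream:
    """Anti-alias low-pass then subsample the stream by ``factor``.

    The cutoff is 5/6 of the post-decimation Nyquist rate (16.67 Hz for
    200 Hz / 6), matching the classifier's input rate.
    """
    if factor is None:
        factor = config.decimation_factor
    if not isinstance(factor, (int, np.integer)) or factor <= 0:
        raise ValueError("decimation factor must be a positive integer")
    if factor == 1:
        return stream
    cutoff = (stream.rate / factor) / 2.0 * (5.0 / 6.0)
    h, gd = _lowpass_filter(stream.rate, cutoff, config.transition_hz, config.stopband_db)
    y = _filter_aligned(h, stream.values, gd)
    n_out = stream.n_samples // factor
    idx = np.arange(n_out) * factor
    return FeatureStream(
        y[idx],
        rate=stream.rate / factor,
        normalized=stream.normalized,
        artifact_mask=stream.artifact_mask[idx],
        warmup_mask=stream.warmup_mask[idx],
        meta=dict(stream.meta),
    )
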
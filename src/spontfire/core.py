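"""Core data containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["RawRecording", "SpikeTrain", "RateSeries"]


@dataclass
class RawRecording:
    """A single-channel extracellular voltage trace in microvolts.

    ``metadata`` carries animal / group / phase / preset / seed labels and is
    propagated unchanged through filtering.
    """

    samples: np.ndarray  # µV
    fs: float  # Hz
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1:
            raise ValueError("RawRecording expects a 1-D trace")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_samples / self.fs


@dataclass
class SpikeTrain:
    """Detected (or ground-truth) spike times plus their binary-train form.

    The binary train is materialised lazily: ``binary_train`` places a single
    1 at ``round(t * fs)`` for each spike time, which is well defined as long
    as successive spikes are more than one sample apart.
    """

    spike_times: np.ndarray  # s, strictly increasing
    fs: float  # Hz of the binary representation
    duration: float  # s
    source_id: str = ""

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if self.spike_times.size and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike_times must be strictly increasing")
        if self.spike_times.size and (
            self.spike_times[0] < 0 or self.spike_times[-1] > self.duration
        ):
            raise ValueError("spike_times must lie within [0, duration]")
        self._binary: np.ndarray | None = None

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def binary_train(self) -> np.ndarray:
        if self._binary is None:
            from .detection import to_binary_train  # local import, no cycle at load

            self._binary = to_binary_train(
                self.spike_times, self.fs, self.duration, source_id=self.source_id
            )._binary
        return self._binary


@dataclass
class RateSeries:
    """Instantaneous firing rate (Hz) on the binary-train time grid."""

    t: np.ndarray  # s, sample times
    rate: np.ndarray  # Hz
    window: float  # s, boxcar width
    fs: float  # Hz of the grid
    epoch: str = ""  # e.g. "before" / "after"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.t.shape != self.rate.shape:
            raise ValueError("t and rate must have matching shapes")
        if self.rate.size and self.rate.min() < 0:
            raise ValueError("rates must be non-negative")

    @property
    def duration(self) -> float:
        return self.t.size / self.fs
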
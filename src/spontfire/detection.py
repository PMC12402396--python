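"""Threshold spike detection on filtered traces via the MAD noise estimate.

The noise level is the median absolute deviation about the median (MAD),
optionally rescaled by 1.4826 so it estimates the Gaussian SD (the default:
a multiplier of k then corresponds to a k-sigma threshold, the conventional
reading of "k x noise").  A spike is recorded at the local extremum within
the alignment window after each threshold crossing, crossings within the
dead time of an accepted spike are ignored, and the resulting spike train
can be binarised at the acquisition rate and OR-pooled down to 5 kHz
without losing events.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import RawRecording, SpikeTrain

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionParams",
    "DegenerateNoiseError",
    "mad",
    "detect_spikes",
    "to_binary_train",
    "downsample_train",
]

#: Scale factor that makes the median absolute deviation a consistent
#: estimator of the standard deviation under Gaussian noise (1/Phi^-1(3/4)).
NORMAL_MAD_SCALE = 1.4826022185056018


class DegenerateNoiseError(ValueError):
    """Raised when the trace has no dispersion to estimate noise from."""


@dataclass(frozen=True)
class DetectionParams:
    mad_multiplier: float = 5.0  # k
    polarity: str = "negative"  # {"negative", "positive", "both"}
    dead_time_ms: float = 1.0
    alignment_window_ms: float = 1.0
    mad_scaling: str = "normal"  # {"raw", "normal"}
    mad_center: str = "median"  # {"median", "mean"}

    def __post_init__(self) -> None:
        if self.mad_multiplier <= 0:
            raise ValueError("mad_multiplier must be > 0")
        if self.polarity not in ("negative", "positive", "both"):
            raise ValueError("polarity must be negative, positive or both")
        if self.mad_scaling not in ("raw", "normal"):
            raise ValueError("mad_scaling must be raw or normal")
        if self.mad_center not in ("median", "mean"):
            raise ValueError("mad_center must be median or mean")
        if self.dead_time_ms <= 0 or self.alignment_window_ms <= 0:
            raise ValueError("dead_time_ms and alignment_window_ms must be > 0")
        if self.dead_time_ms < self.alignment_window_ms:
            raise ValueError("dead_time_ms must be >= alignment_window_ms")


def mad(x: np.ndarray, center: str = "median", scaling: str = "raw") -> float:
    """Absolute deviation about the median (or mean) of ``x``.

    ``scaling="normal"`` multiplies the median-absolute-deviation by 1.4826
    so that it estimates sigma for Gaussian data.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("mad of an empty sequence is undefined")
    if center == "median":
        dev = np.abs(x - np.median(x))
    elif center == "mean":
        dev = np.abs(x - x.mean())
    else:
        raise ValueError("center must be median or mean")
    value = float(np.median(dev)) if center == "median" else float(dev.mean())
    if scaling == "normal":
        value *= NORMAL_MAD_SCALE
    elif scaling != "raw":
        raise ValueError("scaling must be raw or normal")
    return value


def detect_spikes(
    filtered: RawRecording, params: DetectionParams | None = None
) -> SpikeTrain:
    """Extract spike times from a band-passed trace by MAD thresholding.

    Negative polarity (the default, extracellular spikes being
    negative-dominant) thresholds at ``-k * MAD``; each downward crossing is
    aligned to the trace minimum within the alignment window, and further
    crossings within the dead time are suppressed.
    """
    if params is None:
        params = DetectionParams()
    x = np.asarray(filtered.samples, dtype=np.float32)
    noise = mad(x, center=params.mad_center, scaling=params.mad_scaling)
    if noise == 0:
        raise DegenerateNoiseError("degenerate noise estimate: MAD of trace is 0")
    fs = filtered.fs
    if params.polarity == "negative":
        sig = x
    elif params.polarity == "positive":
        sig = -x
    else:  # both: detect on the negative envelope of |x|
        sig = -np.abs(x)
    thr = -params.mad_multiplier * noise

    below = sig < thr
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if below[0]:
        crossings = np.concatenate(([0], crossings))
    win = max(1, int(round(params.alignment_window_ms * fs / 1000.0)))
    dead = int(round(params.dead_time_ms * fs / 1000.0))
    peaks: list[int] = []
    last = -dead - 1
    for c in crossings:
        if c <= last + dead:
            continue
        seg = sig[c : c + win]
        peak = c + int(np.argmin(seg))
        if peaks and peak - peaks[-1] < dead:
            continue
        peaks.append(peak)
        last = peak
    times = np.asarray(peaks, dtype=float) / fs
    if times.size == 0:
        warnings.warn("no spikes detected", stacklevel=2)
    return SpikeTrain(
        spike_times=times,
        fs=fs,
        duration=filtered.duration,
        source_id=str(filtered.metadata.get("animal", "")),
    )


def to_binary_train(
    times: np.ndarray, fs: float, duration: float, source_id: str = ""
) -> SpikeTrain:
    """Binary spike train with ``train[round(t * fs)] = 1`` for each time."""
    times = np.asarray(times, dtype=float)
    n = int(round(duration * fs))
    if times.size and (times.min() < 0 or times.max() > duration):
        raise ValueError("spike times must lie within [0, duration]")
    idx = np.minimum(np.round(times * fs).astype(np.int64), n - 1)
    if idx.size and np.any(np.diff(idx) == 0):
        raise ValueError("two spikes map to the same sample at this rate")
    train = np.zeros(n, dtype=np.uint8)
    train[idx] = 1
    st = SpikeTrain(spike_times=times, fs=fs, duration=duration, source_id=source_id)
    st._binary = train
    return st


def downsample_train(train: SpikeTrain, target_fs: float = 5000.0) -> SpikeTrain:
    """OR-pool a binary train down to ``target_fs`` (event-count preserving).

    Each target bin is 1 if any of its source samples is 1, so spikes are
    never dropped by decimation; two spikes falling into the same target bin
    collide into one (logged), which cannot happen while the dead time
    exceeds the target bin width.
    """
    factor = train.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"source rate {train.fs} Hz is not an integer multiple of {target_fs} Hz"
        )
    factor = int(round(factor))
    src = train.binary_train
    n_out = -(-src.size // factor)  # ceil
    padded = np.zeros(n_out * factor, dtype=src.dtype)
    padded[: src.size] = src
    pooled = padded.reshape(n_out, factor).max(axis=1)
    n_collisions = int(src.sum() - pooled.sum())
    if n_collisions:
        logger.info("OR-pooling merged %d spike pairs into shared bins", n_collisions)
    idx = np.flatnonzero(pooled)
    out = SpikeTrain(
        spike_times=idx / target_fs,
        fs=target_fs,
        duration=n_out / target_fs,
        source_id=train.source_id,
    )
    out._binary = pooled
    return out
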
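"""Spontaneous firing-rate series and inter-spike-interval statistics.

The rate series is a centred 1-s boxcar count over the 5 kHz binary train,
divided at each sample by the window's actual in-bounds coverage (so the
first/last half-window is normalised by the shorter effective duration
rather than drooping).  A centred kernel introduces no time shift, the
discrete analogue of zero-phase filtering.  ISI statistics use 5-ms
half-open histogram bins and the strict fraction of intervals below 5 ms,
the standard burst-propensity summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import RateSeries, SpikeTrain

__all__ = [
    "sfr",
    "mean_sfr",
    "isis",
    "isi_hist",
    "IsiHistogram",
    "IsiSummary",
    "short_isi_fraction",
    "isi_summary",
]


def sfr(train: SpikeTrain, window: float = 1.0, epoch: str = "") -> RateSeries:
    """Boxcar-smoothed instantaneous rate (Hz), one value per train sample.

    ``rate[i]`` counts spikes in the centred ``window``-second boxcar around
    sample ``i`` and divides by the in-bounds window duration at ``i``.
    """
    n = train.n_samples
    win = int(round(window * train.fs))
    if win < 1:
        raise ValueError("window shorter than one sample")
    if win > n:
        raise ValueError("window longer than the recording")
    b = train.binary_train.astype(np.float32)
    # mode="constant" zero-pads, so mean*win = in-window count near edges too.
    counts = uniform_filter1d(b, size=win, mode="constant", cval=0.0) * win
    coverage = (
        uniform_filter1d(np.ones(n, dtype=np.float32), size=win, mode="constant")
        * win
    )
    rate = counts / (coverage / train.fs)
    rate = np.maximum(rate, 0.0)  # clip float round-off
    t = np.arange(n) / train.fs
    return RateSeries(
        t=t, rate=rate, window=window, fs=train.fs, epoch=epoch,
        source_id=train.source_id,
    )


def mean_sfr(series: RateSeries, interval: tuple[float, float] | None = None) -> float:
    """Arithmetic mean rate over ``interval = (t0, t1)`` seconds."""
    if interval is None:
        interval = (float(series.t[0]), float(series.t[-1]) + 1.0 / series.fs)
    t0, t1 = interval
    if not (0.0 <= t0 < t1 <= series.duration + 1e-9):
        raise ValueError(f"interval {interval} is empty or outside the recording")
    lo = int(np.ceil(t0 * series.fs - 1e-9))
    hi = int(np.floor(t1 * series.fs + 1e-9))
    hi = min(hi, series.rate.size)
    if hi <= lo:
        raise ValueError(f"interval {interval} contains no rate samples")
    return float(series.rate[lo:hi].mean())


def isis(spike_times: np.ndarray) -> np.ndarray:
    """Inter-spike intervals in ms; empty for fewer than two spikes."""
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size < 2:
        return np.empty(0)
    out = np.diff(spike_times) * 1000.0
    if np.any(out <= 0):
        raise ValueError("spike times must be strictly increasing")
    return out


@dataclass(frozen=True)
class IsiHistogram:
    """ISI histogram with uniform half-open bins and an overflow count."""

    bin_edges: np.ndarray  # ms, length n_bins + 1, starting at 0
    counts: np.ndarray  # int, length n_bins
    n_isis_total: int
    n_overflow: int

    def __post_init__(self) -> None:
        if int(self.counts.sum()) + self.n_overflow != self.n_isis_total:
            raise ValueError("histogram counts do not conserve the ISI total")


@dataclass(frozen=True)
class IsiSummary:
    short_fraction: float  # P(ISI < 5 ms), strict
    total_spike_count: int
    n_isis: int


def isi_hist(
    isi_ms: np.ndarray, bin_width: float = 5.0, max_isi: float = 500.0
) -> IsiHistogram:
    """Histogram of ISIs with half-open ``[lo, hi)`` bins of ``bin_width`` ms.

    Intervals at or beyond ``max_isi`` go to the overflow count, so totals
    are always conserved.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    isi_ms = np.asarray(isi_ms, dtype=float)
    if isi_ms.size and isi_ms.min() < 0:
        raise ValueError("negative ISI: corrupt spike ordering")
    n_bins = int(np.ceil(max_isi / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    # np.histogram closes the last bin; route >= max_isi to overflow instead.
    in_range = isi_ms[isi_ms < edges[-1]]
    counts, _ = np.histogram(in_range, bins=edges)
    return IsiHistogram(
        bin_edges=edges,
        counts=counts.astype(np.int64),
        n_isis_total=int(isi_ms.size),
        n_overflow=int(isi_ms.size - in_range.size),
    )


def short_isi_fraction(isi_ms: np.ndarray, threshold: float = 5.0) -> float:
    """Fraction of ISIs strictly below ``threshold`` ms."""
    isi_ms = np.asarray(isi_ms, dtype=float)
    if isi_ms.size == 0:
        raise ValueError("short-ISI fraction of an empty ISI list is undefined")
    return float(np.count_nonzero(isi_ms < threshold) / isi_ms.size)


def isi_summary(spike_times: np.ndarray, threshold: float = 5.0) -> IsiSummary:
    """Short-ISI fraction plus totals for one spike train."""
    intervals = isis(spike_times)
    return IsiSummary(
        short_fraction=short_isi_fraction(intervals, threshold),
        total_spike_count=int(np.asarray(spike_times).size),
        n_isis=int(intervals.size),
    )
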
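"""Zero-phase Butterworth band-pass filtering of raw voltage traces.

The filter is a 4th-order Butterworth band-pass (300-6000 Hz by default)
applied forward and backward in second-order sections, so the net phase is
zero and the effective magnitude response is the squared (8th-order)
prototype.  Edges are handled by reflect padding three settling lengths
long, which keeps startup transients out of the first second of the trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import RawRecording

__all__ = ["FilterSpec", "bandpass"]


@dataclass(frozen=True)
class FilterSpec:
    low_cutoff: float = 300.0  # Hz
    high_cutoff: float = 6000.0  # Hz
    order: int = 4  # one-pass prototype order

    def __post_init__(self) -> None:
        if not 0 < self.low_cutoff < self.high_cutoff:
            raise ValueError("require 0 < low_cutoff < high_cutoff")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def settling_samples(self, fs: float) -> int:
        # Heuristic settling length: one low-cutoff period per filter order.
        return self.order * int(round(fs / self.low_cutoff))


def bandpass(rec: RawRecording, spec: FilterSpec | None = None) -> RawRecording:
    """Zero-phase band-pass filter a recording; length and fs are preserved.

    Raises a ``ValueError`` if the high cutoff reaches the Nyquist frequency
    or the trace is shorter than three reflect-padding lengths.
    """
    if spec is None:
        spec = FilterSpec()
    if spec.high_cutoff >= rec.fs / 2:
        raise ValueError(
            f"high cutoff {spec.high_cutoff} Hz must be below Nyquist "
            f"({rec.fs / 2} Hz)"
        )
    padlen = 3 * spec.settling_samples(rec.fs)
    if rec.n_samples <= padlen:
        raise ValueError(
            f"trace of {rec.n_samples} samples is too short to filter "
            f"(needs more than {padlen})"
        )
    sos = signal.butter(
        spec.order,
        [spec.low_cutoff, spec.high_cutoff],
        btype="bandpass",
        fs=rec.fs,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, np.asarray(rec.samples, dtype=np.float64),
                                  padtype="even", padlen=padlen)
    if rec.samples.dtype == np.float32:
        filtered = filtered.astype(np.float32)
    meta = dict(rec.metadata)
    meta["filter"] = {
        "low_hz": spec.low_cutoff,
        "high_hz": spec.high_cutoff,
        "order": spec.order,
        "zero_phase": True,
    }
    return RawRecording(samples=filtered, fs=rec.fs, metadata=meta)
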
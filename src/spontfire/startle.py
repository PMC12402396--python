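"""Acoustic-startle session containers and GPIAS / PPI indices.

A GPIAS (gap prepulse inhibition of the acoustic startle) block holds gap
and no-gap trials; a PPI block holds pulse, prepulse and no-stimulus trials.
Both indices are ratios of mean startle amplitudes expressed as percent
inhibition:

    GPIAS = (1 - avg_gap / avg_nogap) * 100
    PPI   = (1 - avg_prepulse / avg_startle) * 100

A tinnitus-like percept "fills in" the silent gap, weakening gap-induced
inhibition, so a GPIAS drop with intact PPI is the behavioral readout of
tinnitus.  Both are ratios of *means* over trials, not means of per-trial
ratios, and no-stimulus trials enter neither formula (they only quantify
baseline platform motion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "TRIAL_TYPES",
    "StartleTrial",
    "StartleSession",
    "BehaviorIndex",
    "peak_to_peak",
    "gpias_index",
    "ppi_index",
    "summarize_session",
]

TRIAL_TYPES = ("gap", "no_gap", "pulse", "prepulse", "no_stim")

#: Default trial counts per session block (gap/no-gap GPIAS block; pulse,
#: prepulse and no-stimulus PPI block).
DEFAULT_TRIAL_COUNTS = {
    "gap": 16,
    "no_gap": 16,
    "pulse": 15,
    "prepulse": 10,
    "no_stim": 8,
}


@dataclass
class StartleTrial:
    trial_type: str
    amplitude: float  # peak-to-peak platform force, arbitrary units
    waveform: np.ndarray | None = None  # optional platform force samples
    waveform_fs: float | None = None  # Hz
    response_window_ms: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class StartleSession:
    trials: list[StartleTrial]
    metadata: dict[str, Any] = field(default_factory=dict)
    expected_counts: dict[str, int] | None = None

    def __post_init__(self) -> None:
        expected = self.expected_counts
        if expected is not None:
            counts = {k: 0 for k in expected}
            for tr in self.trials:
                if tr.trial_type in counts:
                    counts[tr.trial_type] += 1
            if counts != expected:
                raise ValueError(
                    f"trial counts {counts} do not match expected {expected}"
                )

    def amplitudes(self, trial_type: str) -> np.ndarray:
        return np.array(
            [tr.amplitude for tr in self.trials if tr.trial_type == trial_type],
            dtype=float,
        )


@dataclass(frozen=True)
class BehaviorIndex:
    """Per-session summary: both indices and the underlying mean amplitudes."""

    gpias: float | None  # percent; None if the session has no GPIAS block
    ppi: float | None  # percent; None if the session has no PPI block
    avg_gap: float | None = None
    avg_nogap: float | None = None
    avg_prepulse: float | None = None
    avg_startle: float | None = None
    avg_no_stim: float | None = None


def peak_to_peak(
    waveform: np.ndarray, fs: float, window_ms: tuple[float, float] = (0.0, 100.0)
) -> float:
    """Max-minus-min of the platform force inside the response window.

    The window is given in ms relative to the start of the stored waveform
    (i.e. startle-pulse onset); it must overlap the waveform.
    """
    waveform = np.asarray(waveform, dtype=float)
    lo = int(round(window_ms[0] * fs / 1000.0))
    hi = int(round(window_ms[1] * fs / 1000.0))
    lo = max(lo, 0)
    hi = min(hi, waveform.size)
    if hi <= lo:
        raise ValueError("response window does not overlap the waveform")
    seg = waveform[lo:hi]
    return float(seg.max() - seg.min())


def _mean_amp(session: StartleSession, trial_type: str, needed_for: str) -> float:
    amps = session.amplitudes(trial_type)
    if amps.size == 0:
        raise ValueError(f"{needed_for} requires at least one {trial_type} trial")
    return float(amps.mean())


def gpias_index(session: StartleSession) -> float:
    """Gap inhibition percent, ``(1 - avg_gap/avg_nogap) * 100``.

    Can be negative when gap trials startle *more* than no-gap trials
    (facilitation); never exceeds 100.
    """
    avg_gap = _mean_amp(session, "gap", "GPIAS")
    avg_nogap = _mean_amp(session, "no_gap", "GPIAS")
    if avg_nogap == 0:
        raise ValueError("GPIAS undefined: mean no-gap amplitude is zero")
    return (1.0 - avg_gap / avg_nogap) * 100.0


def ppi_index(session: StartleSession) -> float:
    """Prepulse inhibition percent, ``(1 - avg_prepulse/avg_startle) * 100``."""
    avg_pre = _mean_amp(session, "prepulse", "PPI")
    avg_startle = _mean_amp(session, "pulse", "PPI")
    if avg_startle == 0:
        raise ValueError("PPI undefined: mean startle amplitude is zero")
    return (1.0 - avg_pre / avg_startle) * 100.0


def summarize_session(session: StartleSession) -> BehaviorIndex:
    """Compute whichever of GPIAS / PPI the session's trial mix supports."""

    def opt_mean(tt: str) -> float | None:
        a = session.amplitudes(tt)
        return float(a.mean()) if a.size else None

    avg_gap, avg_nogap = opt_mean("gap"), opt_mean("no_gap")
    avg_pre, avg_startle = opt_mean("prepulse"), opt_mean("pulse")
    gpias = ppi = None
    if avg_gap is not None and avg_nogap:
        gpias = (1.0 - avg_gap / avg_nogap) * 100.0
    if avg_pre is not None and avg_startle:
        ppi = (1.0 - avg_pre / avg_startle) * 100.0
    if gpias is None and ppi is None:
        warnings.warn("session supports neither GPIAS nor PPI", stacklevel=2)
    return BehaviorIndex(
        gpias=gpias,
        ppi=ppi,
        avg_gap=avg_gap,
        avg_nogap=avg_nogap,
        avg_prepulse=avg_pre,
        avg_startle=avg_startle,
        avg_no_stim=opt_mean("no_stim"),
    )
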
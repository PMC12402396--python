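"""Plain-format artifact I/O: WAV traces with JSON sidecars, CSV tables.

Every artifact is independently inspectable: recordings are single-channel
float32 WAV (sample values in µV, sampling rate in the header) with a JSON
sidecar carrying the metadata; spike times, rate series, startle sessions
and histograms are small CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .core import RateSeries, RawRecording, SpikeTrain
from .rates import IsiHistogram
from .startle import StartleSession, StartleTrial

__all__ = [
    "save_recording",
    "load_recording",
    "save_spike_times",
    "load_spike_times",
    "save_rate_series",
    "save_isi_hist",
    "save_session",
    "load_session",
    "write_json",
]


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def save_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a float32 WAV plus a ``.json`` metadata sidecar."""
    path = Path(path)
    wavfile.write(path, int(round(rec.fs)), np.asarray(rec.samples, dtype=np.float32))
    sidecar = dict(rec.metadata)
    sidecar.update({"fs_hz": rec.fs, "n_samples": rec.n_samples, "unit": "uV"})
    write_json(sidecar, path.with_suffix(".json"))


def load_recording(path: str | Path) -> RawRecording:
    path = Path(path)
    fs, samples = wavfile.read(path)
    meta_path = path.with_suffix(".json")
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    fs = float(metadata.get("fs_hz", fs))
    return RawRecording(samples=samples, fs=fs, metadata=metadata)


def save_spike_times(train: SpikeTrain, path: str | Path) -> None:
    pd.DataFrame(
        {"recording_id": train.source_id, "spike_time_s": train.spike_times}
    ).to_csv(path, index=False)


def load_spike_times(
    path: str | Path, fs: float, duration: float
) -> SpikeTrain:
    df = pd.read_csv(path)
    source = str(df["recording_id"].iloc[0]) if len(df) else ""
    return SpikeTrain(
        spike_times=df["spike_time_s"].to_numpy(),
        fs=fs,
        duration=duration,
        source_id=source,
    )


def save_rate_series(series: RateSeries, path: str | Path, stride: int = 1) -> None:
    """Rate series CSV (optionally strided to keep files small)."""
    pd.DataFrame(
        {"t_s": series.t[::stride], "rate_hz": series.rate[::stride]}
    ).to_csv(path, index=False)


def save_isi_hist(hist: IsiHistogram, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin_lo_ms": hist.bin_edges[:-1],
            "bin_hi_ms": hist.bin_edges[1:],
            "count": hist.counts,
        }
    ).to_csv(path, index=False)


def save_session(session: StartleSession, path: str | Path) -> None:
    pd.DataFrame(
        {
            "trial_index": range(len(session.trials)),
            "trial_type": [t.trial_type for t in session.trials],
            "amplitude": [t.amplitude for t in session.trials],
        }
    ).to_csv(path, index=False)
    write_json(session.metadata, Path(path).with_suffix(".json"))


def load_session(path: str | Path, validate_counts: bool = False) -> StartleSession:
    df = pd.read_csv(path)
    meta_path = Path(path).with_suffix(".json")
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    trials = [
        StartleTrial(trial_type=row.trial_type, amplitude=float(row.amplitude))
        for row in df.itertuples()
    ]
    expected = None
    if validate_counts:
        from .startle import DEFAULT_TRIAL_COUNTS

        expected = dict(DEFAULT_TRIAL_COUNTS)
    return StartleSession(trials=trials, metadata=metadata, expected_counts=expected)
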
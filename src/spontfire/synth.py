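"""Ground-truth generators for extracellular recordings and startle sessions.

The spiking model is a refractory-offset renewal process: each inter-spike
interval is ``refractory + X`` where ``X`` is drawn from a two-component
mixture — a gamma "burst" component with a short mean and an exponential
"tonic" component.  The two free parameters (burst weight ``w`` and tonic
mean) are solved so that the process hits a target mean firing rate *and* a
target fraction of ISIs shorter than 5 ms simultaneously; both observables
are therefore controllable and analytically checkable.  Voltage traces embed
a stereotyped biphasic spike waveform in white Gaussian noise at a chosen
peak-to-noise SNR, so the detection stage can be scored against the exact
ground-truth spike times.

Startle sessions draw no-gap / pulse amplitudes around a baseline with a
configurable coefficient of variation and scale gap / prepulse amplitudes by
the preset's true inhibition, so the downstream GPIAS / PPI estimators can
be checked for bias by parameter recovery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import optimize, stats

from .core import RawRecording
from .presets import BehaviorPreset, EphysPreset
from .startle import DEFAULT_TRIAL_COUNTS, StartleSession, StartleTrial

logger = logging.getLogger(__name__)

__all__ = [
    "IsiMixtureParams",
    "GroundTruthSpikes",
    "SpikeTemplate",
    "solve_isi_mixture",
    "gen_spike_times",
    "make_template",
    "gen_voltage",
    "gen_group",
    "gen_startle_session",
    "InfeasibleTargetError",
]


class InfeasibleTargetError(ValueError):
    """Raised when a (rate, short-ISI fraction) target cannot be realised."""


@dataclass(frozen=True)
class IsiMixtureParams:
    """Parameters of the refractory-offset ISI mixture (times in ms).

    ISI = refractory + X,  X ~ w * Gamma(shape, mean burst_mean)
                               + (1 - w) * Exp(tonic_mean)
    """

    burst_weight: float  # w, in [0, 1]
    burst_shape: float  # gamma shape parameter
    burst_mean: float  # ms, gamma mean
    tonic_mean: float  # ms, exponential mean (may be inf when w == 1)
    refractory: float = 1.0  # ms

    def __post_init__(self) -> None:
        if not 0.0 <= self.burst_weight <= 1.0:
            raise ValueError("burst_weight must be in [0, 1]")
        for v, label in (
            (self.burst_shape, "burst_shape"),
            (self.burst_mean, "burst_mean"),
            (self.tonic_mean, "tonic_mean"),
            (self.refractory, "refractory"),
        ):
            if not v > 0:
                raise ValueError(f"{label} must be > 0")

    @property
    def mean_isi_ms(self) -> float:
        w = self.burst_weight
        tonic = 0.0 if w == 1.0 else (1.0 - w) * self.tonic_mean
        return self.refractory + w * self.burst_mean + tonic

    @property
    def rate_hz(self) -> float:
        return 1000.0 / self.mean_isi_ms

    def short_fraction(self, threshold_ms: float = 5.0) -> float:
        """P(ISI < threshold) under the mixture, in closed form."""
        c = threshold_ms - self.refractory
        if c <= 0:
            return 0.0
        w = self.burst_weight
        f_burst = stats.gamma.cdf(c, a=self.burst_shape, scale=self.burst_mean / self.burst_shape)
        f_tonic = 0.0 if w == 1.0 else 1.0 - math.exp(-c / self.tonic_mean)
        return float(w * f_burst + (1.0 - w) * f_tonic)


@dataclass(frozen=True)
class GroundTruthSpikes:
    """Exact spike times of one simulated animal plus its generative truth."""

    spike_times: np.ndarray  # s, strictly increasing
    true_rate: float  # Hz, the mixture's implied mean rate
    duration: float  # s
    preset_name: str = ""
    seed: int | None = None
    mixture: IsiMixtureParams | None = None

    @property
    def n_spikes(self) -> int:
        return int(np.asarray(self.spike_times).size)


@dataclass(frozen=True)
class SpikeTemplate:
    """Unit-normalised biphasic extracellular waveform (trough = -1)."""

    waveform: np.ndarray  # min exactly -1
    fs: float  # Hz
    peak_amplitude_uv: float  # µV magnitude of the (negative-going) trough

    @property
    def support_ms(self) -> float:
        return 1000.0 * self.waveform.size / self.fs

    @property
    def samples_uv(self) -> np.ndarray:
        return self.waveform * self.peak_amplitude_uv


def solve_isi_mixture(
    target_rate: float,
    target_short_fraction: float,
    burst_shape: float = 2.0,
    burst_mean: float = 3.0,
    refractory: float = 1.0,
    threshold_ms: float = 5.0,
    tol: float = 1e-9,
) -> IsiMixtureParams:
    """Invert (mean rate, short-ISI fraction) into mixture parameters.

    Solves for the burst weight ``w`` and tonic mean such that the mixture's
    implied mean ISI equals ``1000 / target_rate`` ms and P(ISI < 5 ms)
    equals ``target_short_fraction``.  The attainable fraction runs from the
    tonic-only value (w = 0) up to the burst CDF at the threshold (w -> 1);
    exactly at the upper boundary the solver returns w = 1, where the tonic
    component has zero weight and the rate constraint is vacuous.

    Raises
    ------
    InfeasibleTargetError
        If the target fraction lies outside the attainable interval, or the
        target rate is too high for the refractory period / burst mean.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    mean_isi = 1000.0 / target_rate
    if mean_isi <= refractory:
        raise InfeasibleTargetError(
            f"rate {target_rate} Hz implies a mean ISI of {mean_isi:.3f} ms, "
            f"not above the {refractory} ms refractory period"
        )
    m_free = mean_isi - refractory  # mean of the non-refractory part X
    if m_free <= burst_mean:
        raise InfeasibleTargetError(
            f"rate {target_rate} Hz leaves a free mean of {m_free:.3f} ms, "
            f"not above the burst mean {burst_mean} ms"
        )
    c = threshold_ms - refractory
    f_burst = float(stats.gamma.cdf(c, a=burst_shape, scale=burst_mean / burst_shape))

    def tonic_mean_at(w: float) -> float:
        # Enforces the mean constraint: w*burst_mean + (1-w)*tonic = m_free.
        return (m_free - w * burst_mean) / (1.0 - w)

    def short_frac_at(w: float) -> float:
        if w >= 1.0:
            return f_burst
        return w * f_burst + (1.0 - w) * (1.0 - math.exp(-c / tonic_mean_at(w)))

    lo, hi = short_frac_at(0.0), f_burst
    if not (lo - tol <= target_short_fraction <= hi + tol):
        raise InfeasibleTargetError(
            f"short-ISI fraction {target_short_fraction} is outside the "
            f"attainable interval [{lo:.6f}, {hi:.6f}] for rate {target_rate} Hz "
            f"(burst Gamma(shape={burst_shape}, mean={burst_mean} ms), "
            f"refractory {refractory} ms)"
        )
    if abs(target_short_fraction - hi) <= tol:
        w = 1.0
        tonic = np.inf
    elif abs(target_short_fraction - lo) <= tol:
        w = 0.0
        tonic = m_free
    else:
        w = float(
            optimize.brentq(
                lambda x: short_frac_at(x) - target_short_fraction,
                0.0,
                1.0 - 1e-12,
                xtol=1e-14,
                rtol=8.9e-16,
            )
        )
        tonic = tonic_mean_at(w)
    params = IsiMixtureParams(
        burst_weight=w,
        burst_shape=burst_shape,
        burst_mean=burst_mean,
        tonic_mean=tonic,
        refractory=refractory,
    )
    # Postcondition self-check (rate constraint vacuous at the w = 1 boundary).
    if w < 1.0 and not math.isclose(params.mean_isi_ms, mean_isi, rel_tol=1e-6):
        raise AssertionError("mixture mean ISI failed to match the target rate")
    if not math.isclose(
        params.short_fraction(threshold_ms), target_short_fraction, abs_tol=1e-6
    ):
        raise AssertionError("mixture short-ISI fraction failed to match the target")
    return params


def gen_spike_times(
    mix: IsiMixtureParams, duration: float, seed: int
) -> GroundTruthSpikes:
    """Sample a spike train of the renewal process over ``[0, duration]`` s.

    The first spike falls one ISI after t = 0; identical arguments give
    identical output.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    duration_ms = duration * 1000.0
    mean_isi = mix.mean_isi_ms
    times: list[np.ndarray] = []
    total_ms = 0.0
    while total_ms <= duration_ms:
        n = max(64, int(1.3 * (duration_ms - total_ms) / mean_isi) + 32)
        if mix.burst_weight >= 1.0:
            draws = rng.gamma(mix.burst_shape, mix.burst_mean / mix.burst_shape, n)
        elif mix.burst_weight <= 0.0:
            draws = rng.exponential(mix.tonic_mean, n)
        else:
            is_burst = rng.random(n) < mix.burst_weight
            burst = rng.gamma(mix.burst_shape, mix.burst_mean / mix.burst_shape, n)
            tonic = rng.exponential(mix.tonic_mean, n)
            draws = np.where(is_burst, burst, tonic)
        isis = mix.refractory + draws
        block = total_ms + np.cumsum(isis)
        times.append(block)
        total_ms = float(block[-1])
    all_ms = np.concatenate(times)
    spike_s = all_ms[all_ms <= duration_ms] / 1000.0
    return GroundTruthSpikes(
        spike_times=spike_s,
        true_rate=mix.rate_hz,
        duration=duration,
        seed=seed,
        mixture=mix,
    )


def make_template(
    fs: float = 60_000.0,
    peak_amplitude_uv: float = 80.0,
    support_ms: float = 1.0,
) -> SpikeTemplate:
    """Biphasic, negative-dominant difference-of-Gaussians spike waveform.

    A fast negative trough followed by a slower positive rebound, the
    canonical extracellular action-potential shape.  Support defaults to
    1.0 ms so a template never outlasts the generator's refractory period.
    """
    n = int(round(support_ms * fs / 1000.0))
    t = (np.arange(n) - n // 2) / fs * 1000.0  # ms, trough near 0
    wave = -np.exp(-0.5 * (t / 0.10) ** 2) + 0.35 * np.exp(-0.5 * ((t - 0.25) / 0.18) ** 2)
    wave /= -wave.min()  # trough exactly -1
    if wave.min() >= -abs(wave).max() * 0.999:  # pragma: no cover - shape guard
        raise AssertionError("template dominant extremum must be negative")
    return SpikeTemplate(waveform=wave, fs=fs, peak_amplitude_uv=peak_amplitude_uv)


def gen_voltage(
    spikes: GroundTruthSpikes,
    template: SpikeTemplate | None = None,
    noise_sd: float = 10.0,
    fs: float = 60_000.0,
    seed: int | None = None,
    metadata: dict[str, Any] | None = None,
) -> RawRecording:
    """Embed each ground-truth spike in Gaussian noise of SD ``noise_sd`` µV.

    One template instance is summed in, centred (trough) at each spike time;
    overlapping placements simply add (logged at debug level).  With
    ``noise_sd = 0`` the trace is the pure template comb.
    """
    if template is None:
        template = make_template(fs=fs)
    if template.fs != fs:
        raise ValueError("template sampling rate must match the trace rate")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n = int(round(spikes.duration * fs))
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        trace = rng.standard_normal(n, dtype=np.float32) * np.float32(noise_sd)
    else:
        trace = np.zeros(n, dtype=np.float32)
    wave = template.samples_uv.astype(np.float32)
    half = wave.size // 2
    centers = np.round(np.asarray(spikes.spike_times) * fs).astype(np.int64)
    n_overlap = 0
    last_end = -1
    for c in centers:
        lo = c - half
        hi = lo + wave.size
        if lo < last_end:
            n_overlap += 1
        last_end = hi
        w_lo = max(0, -lo)
        w_hi = wave.size - max(0, hi - n)
        if w_hi <= w_lo:
            continue
        trace[lo + w_lo : lo + w_hi] += wave[w_lo:w_hi]
    if n_overlap:
        logger.debug("summed %d overlapping template placements", n_overlap)
    meta = dict(metadata or {})
    meta.setdefault("preset", spikes.preset_name)
    meta.setdefault("seed", seed)
    meta.setdefault("unit", "uV")
    return RawRecording(samples=trace, fs=fs, metadata=meta)


def gen_group(
    preset: EphysPreset,
    master_seed: int,
    template: SpikeTemplate | None = None,
    snr: float = 8.0,
    fs: float = 60_000.0,
    burst_shape: float = 2.0,
    burst_mean: float = 3.0,
    refractory: float = 1.0,
    min_rate: float = 0.5,
) -> list[tuple[RawRecording, GroundTruthSpikes]]:
    """Simulate one animal group: recordings plus their ground truths.

    Per-animal true rates are Normal(group mean, between-animal SD) truncated
    below ``min_rate`` Hz (resampled); every animal's ISI mixture is solved
    for its own rate at the preset's shared short-ISI fraction.  Seeds are
    derived deterministically: animal ``i`` spikes use
    ``master_seed * 1000 + i`` and its noise uses that value plus 500000.
    """
    if template is None:
        template = make_template(fs=fs)
    if snr <= 0:
        raise ValueError("snr must be > 0")
    noise_sd = template.peak_amplitude_uv / snr
    rate_rng = np.random.default_rng(master_seed)
    out: list[tuple[RawRecording, GroundTruthSpikes]] = []
    for i in range(preset.n_animals):
        rate = float(rate_rng.normal(preset.group_mean_rate, preset.between_animal_sd))
        while rate < min_rate:
            rate = float(
                rate_rng.normal(preset.group_mean_rate, preset.between_animal_sd)
            )
        mix = solve_isi_mixture(
            rate,
            preset.short_isi_fraction,
            burst_shape=burst_shape,
            burst_mean=burst_mean,
            refractory=refractory,
        )
        spike_seed = master_seed * 1000 + i
        gt = gen_spike_times(mix, preset.duration, seed=spike_seed)
        gt = replace(gt, preset_name=preset.name)
        rec = gen_voltage(
            gt,
            template=template,
            noise_sd=noise_sd,
            fs=fs,
            seed=spike_seed + 500_000,
            metadata={
                "animal": f"{preset.name}_a{i:02d}",
                "group": preset.group,
                "phase": preset.phase,
                "preset": preset.name,
                "true_rate_hz": rate,
                "snr": snr,
            },
        )
        out.append((rec, gt))
    return out


def _damped_sinusoid(
    amplitude: float, fs: float = 2000.0, duration_s: float = 0.2
) -> np.ndarray:
    """Platform ring-down: 50 Hz sinusoid, 1 s decay constant.

    Scaled so its initial amplitude is ``amplitude / 2``; the peak-to-peak
    over the first cycle is then within ~1% of ``amplitude``.
    """
    t = np.arange(int(round(duration_s * fs))) / fs
    return (amplitude / 2.0) * np.sin(2 * np.pi * 50.0 * t) * np.exp(-t / 1.0)


def gen_startle_session(
    preset: BehaviorPreset,
    seed: int,
    trial_counts: dict[str, int] | None = None,
    with_waveforms: bool = False,
    waveform_fs: float = 2000.0,
) -> StartleSession:
    """Simulate one startle session (GPIAS block + PPI block).

    No-gap and pulse amplitudes are ``baseline * (1 + cv * eps)`` with eps
    standard normal; gap amplitudes are additionally scaled by
    ``1 - gpias_true/100`` and prepulse amplitudes by ``1 - ppi_true/100``.
    No-stimulus trials carry only small baseline platform motion.  Negative
    draws are clipped to 0 (and logged).  Trial order is shuffled within the
    session.
    """
    counts = dict(DEFAULT_TRIAL_COUNTS if trial_counts is None else trial_counts)
    rng = np.random.default_rng(seed)
    cv = preset.trial_cv
    base = preset.baseline_amp
    scale = {
        "gap": 1.0 - preset.gpias_true / 100.0,
        "no_gap": 1.0,
        "pulse": 1.0,
        "prepulse": 1.0 - preset.ppi_true / 100.0,
    }
    trials: list[StartleTrial] = []
    n_clipped = 0
    for trial_type in ("gap", "no_gap", "pulse", "prepulse", "no_stim"):
        for _ in range(counts.get(trial_type, 0)):
            if trial_type == "no_stim":
                amp = abs(rng.normal(0.0, 0.02 * base))
            else:
                amp = base * scale[trial_type] * (1.0 + cv * rng.standard_normal())
            if amp < 0:
                n_clipped += 1
                amp = 0.0
            waveform = None
            if with_waveforms:
                waveform = _damped_sinusoid(amp, fs=waveform_fs)
            trials.append(
                StartleTrial(
                    trial_type=trial_type,
                    amplitude=float(amp),
                    waveform=waveform,
                    waveform_fs=waveform_fs if with_waveforms else None,
                )
            )
    if n_clipped:
        logger.info("clipped %d negative startle amplitudes to 0", n_clipped)
    rng.shuffle(trials)  # type: ignore[arg-type]
    return StartleSession(
        trials=trials,
        metadata={
            "preset": preset.name,
            "group": preset.group,
            "phase": preset.phase,
            "seed": seed,
            "gpias_true": preset.gpias_true,
            "ppi_true": preset.ppi_true,
            "trial_cv": cv,
        },
        expected_counts=counts,
    )
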
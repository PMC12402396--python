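"""Study-condition presets for the synthetic-data generator.

An :class:`EphysPreset` pins down a group's spontaneous-firing statistics
(mean rate across animals, between-animal SD, fraction of inter-spike
intervals shorter than 5 ms), and a :class:`BehaviorPreset` pins down a
group's startle-inhibition levels (GPIAS and PPI, in percent).  The four
ephys presets and four behavior presets shipped in ``presets.yaml`` encode
the salicylate-tinnitus vs. saline-control conditions before and after
midbrain stimulation; the stimulation descriptors on post-phase presets are
inert metadata.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "EphysPreset",
    "BehaviorPreset",
    "PresetCatalog",
    "load_catalog",
]


@dataclass(frozen=True)
class EphysPreset:
    """Firing-statistics target for one group/phase condition."""

    name: str
    group_mean_rate: float  # Hz, mean spontaneous rate across animals
    between_animal_sd: float  # Hz
    short_isi_fraction: float  # P(ISI < 5 ms), in [0, 1)
    duration: float = 300.0  # s of recording per animal
    n_animals: int = 7
    group: str = ""
    phase: str = ""
    stimulation: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if self.group_mean_rate <= 0:
            raise ValueError("group_mean_rate must be > 0")
        if not 0.0 <= self.short_isi_fraction < 1.0:
            raise ValueError("short_isi_fraction must be in [0, 1)")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.between_animal_sd < 0:
            raise ValueError("between_animal_sd must be >= 0")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")


@dataclass(frozen=True)
class BehaviorPreset:
    """True startle-inhibition levels for one group/phase condition.

    ``gpias_true`` and ``ppi_true`` are the inhibition percentages the
    generated sessions encode; ``baseline_amp`` is the mean no-gap/pulse
    startle amplitude in arbitrary platform-force units and ``trial_cv``
    the trial-to-trial coefficient of variation.
    """

    name: str
    gpias_true: float  # percent
    ppi_true: float  # percent
    baseline_amp: float = 100.0
    trial_cv: float = 0.15
    group: str = ""
    phase: str = ""

    def __post_init__(self) -> None:
        for v, label in ((self.gpias_true, "gpias_true"), (self.ppi_true, "ppi_true")):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{label} must be in [0, 100]")
        if self.trial_cv < 0:
            raise ValueError("trial_cv must be >= 0")
        if self.baseline_amp <= 0:
            raise ValueError("baseline_amp must be > 0")


@dataclass(frozen=True)
class PresetCatalog:
    version: int
    notes: str
    ephys: dict[str, EphysPreset] = field(default_factory=dict)
    behavior: dict[str, BehaviorPreset] = field(default_factory=dict)


def _build_catalog(raw: dict[str, Any]) -> PresetCatalog:
    defaults = raw.get("defaults", {})
    duration = float(defaults.get("duration_s", 300.0))
    n_animals = int(defaults.get("n_animals", 7))
    baseline_amp = float(defaults.get("baseline_amp", 100.0))
    trial_cv = float(defaults.get("trial_cv", 0.15))

    ephys = {
        name: EphysPreset(
            name=name,
            group_mean_rate=float(spec["group_mean_rate_hz"]),
            between_animal_sd=float(spec["between_animal_sd_hz"]),
            short_isi_fraction=float(spec["short_isi_fraction"]),
            duration=float(spec.get("duration_s", duration)),
            n_animals=int(spec.get("n_animals", n_animals)),
            group=spec.get("group", ""),
            phase=spec.get("phase", ""),
            stimulation=spec.get("stimulation"),
        )
        for name, spec in raw.get("ephys", {}).items()
    }
    behavior = {
        name: BehaviorPreset(
            name=name,
            gpias_true=float(spec["gpias_true"]),
            ppi_true=float(spec["ppi_true"]),
            baseline_amp=float(spec.get("baseline_amp", baseline_amp)),
            trial_cv=float(spec.get("trial_cv", trial_cv)),
            group=spec.get("group", ""),
            phase=spec.get("phase", ""),
        )
        for name, spec in raw.get("behavior", {}).items()
    }
    return PresetCatalog(
        version=int(raw.get("version", 0)),
        notes=str(raw.get("notes", "")).strip(),
        ephys=ephys,
        behavior=behavior,
    )


def load_catalog(path: str | None = None) -> PresetCatalog:
    """Load the preset catalog (the packaged one unless *path* is given)."""
    if path is None:
        text = (
            importlib.resources.files("spontfire")
            .joinpath("presets.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return _build_catalog(yaml.safe_load(text))
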
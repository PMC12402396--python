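from __future__ import annotations

import numpy as np
import pytest

import spontfire as sf


@pytest.fixture(scope="session")
def catalog():
    return sf.load_catalog()


@pytest.fixture(scope="session")
def template():
    return sf.make_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(20250921)


def make_spiky_recording(
    spike_times_s,
    duration=2.0,
    noise_sd=1.0,
    peak_uv=80.0,
    fs=60_000.0,
    seed=0,
):
    """Recording with templates at known times in (optionally faint) noise."""
    gt = sf.GroundTruthSpikes(
        spike_times=np.asarray(spike_times_s, dtype=float),
        true_rate=len(spike_times_s) / duration,
        duration=duration,
    )
    tpl = sf.make_template(fs=fs, peak_amplitude_uv=peak_uv)
    return sf.gen_voltage(gt, tpl, noise_sd=noise_sd, fs=fs, seed=seed), gt
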
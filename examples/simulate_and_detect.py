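"""Simulate one extracellular recording and recover its spikes.

Builds a 60-s synthetic trace (9 Hz unit, 22% short ISIs, SNR 8), band-pass
filters it (300-6000 Hz zero-phase Butterworth), detects spikes at 5x the
normal-scaled MAD, and scores the detection against the exact ground truth.
"""

import numpy as np

import spontfire as sf

mix = sf.solve_isi_mixture(target_rate=9.0, target_short_fraction=0.22)
truth = sf.gen_spike_times(mix, duration=60.0, seed=1)
template = sf.make_template()  # biphasic, 80 µV negative-going trough
recording = sf.gen_voltage(truth, template, noise_sd=10.0, seed=2)

filtered = sf.bandpass(recording)
train = sf.detect_spikes(filtered)

det, true = train.spike_times, truth.spike_times
i = np.searchsorted(true, det)
nearest = np.minimum(
    np.abs(det - true[np.clip(i - 1, 0, true.size - 1)]),
    np.abs(det - true[np.clip(i, 0, true.size - 1)]),
)
matched = int(np.sum(nearest <= 1e-3))

print(f"ground truth : {truth.n_spikes} spikes at {truth.true_rate:.2f} Hz")
print(f"detected     : {train.n_spikes} spikes")
print(f"matched +/-1 ms : {matched} "
      f"({100 * matched / truth.n_spikes:.2f}% recovery, "
      f"{train.n_spikes - matched} false positives)")
# Near-perfect recovery at SNR 8: the detection stage, not waveform realism,
# is the property being exercised here.
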
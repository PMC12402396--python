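# Catalog of study-condition presets (ephys firing/burstiness targets and
# startle-behavior inhibition levels) used by the synthetic-data generator.
version: 1
notes: >
  Post-treatment behavioral readouts for the control group are reported
  ambiguously in the source data (42.01 appears once as a GPIAS and once as
  a PPI value); this catalog uses 42.01 for control post GPIAS and 96.13 for
  control post PPI. The salicylate group's post-treatment PPI is described
  as unchanged from baseline, so the baseline value (92.97) is carried for
  tinnitus_post PPI.
defaults:
  duration_s: 300.0
  n_animals: 7
  baseline_amp: 100.0
  trial_cv: 0.15
ephys:
  tinnitus_pre:
    group: tinnitus
    phase: pre
    group_mean_rate_hz: 15.11
    between_animal_sd_hz: 2.64
    short_isi_fraction: 0.2489
  tinnitus_post:
    group: tinnitus
    phase: post
    group_mean_rate_hz: 6.07
    between_animal_sd_hz: 2.03
    short_isi_fraction: 0.2443
    stimulation:
      pulse_rate_hz: 100
      pulse_amplitude_ua: 100
      pulse_width_us: 60
  control_pre:
    group: control
    phase: pre
    group_mean_rate_hz: 5.17
    between_animal_sd_hz: 1.31
    short_isi_fraction: 0.1986
  control_post:
    group: control
    phase: post
    group_mean_rate_hz: 4.84
    between_animal_sd_hz: 1.42
    short_isi_fraction: 0.1993
    stimulation:
      pulse_rate_hz: 100
      pulse_amplitude_ua: 100
      pulse_width_us: 60
behavior:
  tinnitus_baseline:
    group: tinnitus
    phase: pre
    gpias_true: 44.40
    ppi_true: 92.97
  tinnitus_post:
    group: tinnitus
    phase: post
    gpias_true: 21.20
    ppi_true: 92.97
  control_baseline:
    group: control
    phase: pre
    gpias_true: 41.51
    ppi_true: 96.20
  control_post:
    group: control
    phase: post
    gpias_true: 42.01
    ppi_true: 96.13
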
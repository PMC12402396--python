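# Methods

`spontfire` re-implements, as a tested library, the analysis chain used to
characterise spontaneous single-unit activity in auditory cortex under a
salicylate tinnitus model with midbrain deep-brain stimulation: raw
extracellular voltage → zero-phase band-pass → MAD-threshold spike
detection → binary trains at 60 kHz / 5 kHz → boxcar firing-rate series and
ISI statistics → nonparametric group statistics, plus the GPIAS/PPI startle
indices used for behavioral tinnitus assessment.  Because the original rat
recordings are not publicly deposited, a calibrated synthetic-data
generator stands in for them; every stage is validated by parameter
recovery against exact ground truth rather than against archived data.

## The generative spiking model

Each simulated unit is a stationary renewal process whose inter-spike
interval is

    ISI = r + X,   X ~ w · Gamma(k, mean m_b) + (1 − w) · Exp(m_t)

with refractory offset `r = 1 ms`, burst shape `k = 2` and burst mean
`m_b = 3 ms` by default.  This form was chosen because the two observables
the analysis targets — the mean rate and the fraction of ISIs below 5 ms —
are both analytically controllable:

* mean ISI = `r + w·m_b + (1−w)·m_t` (ms) must equal `1000 / rate`;
* `P(ISI < 5 ms) = w·F_Gamma(4 ms) + (1−w)·(1 − e^{−4/m_t})`.

`solve_isi_mixture` eliminates `m_t` through the mean constraint and solves
the one-dimensional root problem for `w` by bracketed bisection
(`brentq`, tolerance ≪ 1e-9), then self-checks both constraints to 1e-6.
The attainable short-ISI range for a given rate runs from the tonic-only
value up to `F_Gamma(4 ms)` ≈ 0.745; targets outside it raise an error
naming the interval.  At the exact upper boundary the solver returns
`w = 1`; the tonic component then has zero weight, the mean-rate constraint
is unattainable (the mixture mean degenerates to `r + m_b`) and is treated
as vacuous — a documented boundary case, not a supported operating point.

Per-animal rates are drawn `Normal(group mean, between-animal SD)`,
resampled below 0.5 Hz to avoid degenerate near-empty recordings; each
animal's mixture is solved at its own rate but the group's shared short-ISI
fraction, so pooled fractions recover the group target.  Rates are constant
within a recording: the analysed epochs are 5-min spontaneous periods with
no modelled trend.

### Condition presets

The four ephys presets (`presets.yaml`, versioned) encode the study
conditions: group mean rate ± between-animal SD of 15.11 ± 2.64 Hz
(tinnitus, pre-stimulation), 6.07 ± 2.03 (tinnitus, post), 5.17 ± 1.31
(control, pre), 4.84 ± 1.42 (control, post); short-ISI fractions 24.89,
24.43, 19.86 and 19.93 %.  Stimulation descriptors (100 Hz, 100 µA, 60 µs)
ride along as inert metadata on post-phase presets.  Behavior presets carry
GPIAS/PPI of 44.40/92.97 % (tinnitus baseline), 41.51/96.20 % (control
baseline), 21.20 % GPIAS post-salicylate, and 42.01/96.13 % (control
post).  The source reporting of the control group's post values is
ambiguous (42.01 appears once as GPIAS and once as PPI); the catalog notes
field flags this, uses 96.13 % for control post PPI, and carries the
unchanged baseline 92.97 % for the tinnitus group's post PPI.

### Voltage synthesis

Spikes are embedded as a unit-normalised biphasic difference-of-Gaussians
template (fast negative trough, slower positive rebound; 1.0 ms support at
60 kHz — kept at or under the refractory period so overlapping placements
stay rare; overlaps are summed, not an error) in white Gaussian noise.  The
default peak-to-noise SNR is 8 (80 µV trough, 10 µV noise SD): high enough
that detection accuracy, not waveform realism, is the property under test.
What the generator does **not** emulate: multi-unit overlap and sorting
ambiguity, electrode drift, stimulation artifacts, line noise,
non-stationary rates, correlated (1/f or band-limited) background.  Passing
recovery tests therefore demonstrates the correctness of the analysis
chain, not its robustness to every pathology of real recordings.

### Startle sessions

A session holds 16 gap + 16 no-gap trials (GPIAS block) and 15 pulse + 10
prepulse + 8 no-stimulus trials (PPI block).  No-gap/pulse amplitudes are
`baseline · (1 + cv·ε)` with ε standard normal and trial CV 0.15 by
default; gap and prepulse amplitudes are scaled by `1 − true/100`; negative
draws clip to 0 (logged); no-stimulus trials carry ~2 % baseline motion.
Optional per-trial waveforms are damped sinusoids (50 Hz, 1-s decay) whose
first-cycle peak-to-peak equals the trial amplitude within ~1 %, so the
offline peak-to-peak extraction path is exercised.  The estimators are
ratios of means, so the mean estimated index has only a second-order
(≈ cv²/16, < 0.2 %) upward-relative bias at cv 0.15 — verified < 0.5
points empirically over 1000 sessions.

## Filtering

4th-order Butterworth band-pass, 300–6000 Hz, applied forward–backward in
second-order sections (`sosfiltfilt`): zero net phase, effective 8th-order
magnitude.  The stated "zero-phase fourth-order" is read as a 4th-order
prototype per pass — whether the combined response should count as 4th
order is left open and documented rather than guessed.  Edges use reflect
padding of three settling lengths (settling ≈ order · fs/low-cutoff
samples), keeping startup transients out of the first rate-series second;
traces shorter than the padding are rejected.

## Spike detection

Noise is estimated by the median absolute deviation about the median.  The
defaults pair the conventional multiplier `k = 5` with the
normal-consistent scaling (×1.4826), i.e. an effective 5σ threshold.  The
raw (unscaled) MAD is available via `mad_scaling="raw"`, and a
mean-absolute-deviation variant via `mad_center="mean"`, since the
acronym's expansion is ambiguous in parts of the literature; with raw
scaling, `k = 5` corresponds to only ≈ 3.4σ, where the Rice crossing rate
of 300–6000 Hz band-limited noise (~12 false events/s) would swamp
single-unit rates — the reason the scaled estimator is the default.
Detection is negative-polarity by default (extracellular spikes are
negative-dominant; positive and both-polarity modes exist), aligns each
threshold crossing to the trace minimum within a 1-ms window, and enforces
a 1-ms dead time.  The dead time matches the generator's refractory offset,
so no true ISI can be lost to it.  Binarisation places one sample per spike
at `round(t·fs)`; downsampling 60 kHz → 5 kHz OR-pools blocks of 12
samples, which preserves event counts whenever spikes are ≥ 0.2 ms apart
(guaranteed by the dead time) — decimation, by contrast, can silently drop
spikes.

## Rate series and ISI statistics

The firing-rate series is a centred 1-s boxcar count over the 5 kHz binary
train divided by the window's in-bounds coverage at each sample — a
zero-phase smoother whose edge normalisation avoids the half-window rate
droop of naive convolution.  Its integral reproduces the spike count to
within 0.5 % (edge effect only).  ISI histograms use half-open 5-ms bins
`[0,5), [5,10), …` up to a display-level 500-ms overflow bin that keeps
totals conserved; an interval of exactly 5 ms is *not* short (strict
inequality).

## Group statistics

Per-timepoint comparisons use the two-group Kruskal–Wallis test (retained
rather than substituted by the equivalent Mann–Whitney; both are exposed)
with midrank tie correction and the chi-square (df = 1) approximation, plus
the rank-biserial correlation `r = 2U/(n_A n_B) − 1` as effect size, tiered
low (< 0.2) / medium ([0.2, 0.5)) / high (≥ 0.5) wherever p < 0.05.  The
scan grid is one test per second at window centres — adjacent 1-s boxcar
windows on that grid share no content, so the tests are as close to
independent as the smoother allows; testing every 5 kHz sample would be
~100 % redundant between neighbours.  No multiple-testing correction is
applied by default (matching the reporting style the scan reproduces);
Benjamini–Hochberg is available behind a flag.

Group-mean comparisons run a per-group normality test at α = 0.05 — the
Lilliefors-corrected KS test by default for rate data (the plain KS test
with estimated parameters is anticonservative; below n = 4, where the
Lilliefors tables end, Shapiro–Wilk substitutes) and Shapiro–Wilk for
behavioral data — then route to paired/unpaired t-tests or to the Wilcoxon
signed-rank / Mann–Whitney U.  Degenerate ties degrade to (0, p = 1) with a
warning.  ISI distributions are compared with the asymptotic two-sample KS
test, and short-ISI proportions with Pearson's chi-square on the 2×2 table,
df = 1, no continuity correction (expected counts here are in the
thousands); expected cells below 5 trigger an exact-test warning.  Total
spike counts before vs. after stimulation use a two-tailed paired t-test.

All rank statistics are cross-checked in the test suite against independent
brute-force oracles (direct midrank computation, exhaustive pair counting,
full ECDF scans, the raw Pearson formula) to 1e-10 on an exhaustive battery
of small samples (n ≤ 8) with and without ties.

## Problem sizes and validation scales

Chosen as the package's own verification design: recovery tests run the
full pipeline at the study scale — 7 animals per group, 300-s recordings,
SNR 8 — with group-mean tolerance 2·SD/√7, pooled short-ISI tolerance ±1
percentage point, behavioral tolerance ±3 points over 7 sessions at trial
CV 0.15, and detection fidelity ≥ 99 % recovery with ≤ 1 % false positives
at a ±1 ms matching window.  Generator calibration uses 10⁶ Monte-Carlo
ISIs (tolerance 0.005).  The null calibration of the timepoint scan uses
200 simulated 7-vs-7 experiments of 30-s ground-truth trains (6000 pooled
tests; acceptance band 0.03–0.07 at α = 0.05) — the scan consumes rate
series, so voltage synthesis and detection add nothing under the null.

## Known limitations

* Single-channel, single-unit-stream analysis only: no spike sorting, no
  synchrony or cross-correlation measures, no burst-detection algorithms
  beyond the short-ISI fraction.
* The chi-square statistics of the original ISI comparisons scale with the
  real data's pooled ISI counts and are not reproduced at desk scale; the
  package reproduces the proportions, not the test statistics' magnitudes.
* Stationarity within a recording is assumed; nonstationary rate profiles
  would require extending the generator.
* The acoustic and stimulation hardware parameters (gap timing, pulse
  levels, electrode geometry) are carried as metadata only and never
  modelled.
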
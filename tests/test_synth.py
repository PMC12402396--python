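"""Generator calibration: the ISI mixture solver, spike sampler, voltage
embedding, group sampler and startle-session generator."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

import spontfire as sf

PRESET_NAMES = ["tinnitus_pre", "tinnitus_post", "control_pre", "control_post"]


def draw_mixture_isis(mix: sf.IsiMixtureParams, n: int, rng) -> np.ndarray:
    """Independent Monte-Carlo draw of the stated mixture (test-side oracle)."""
    is_burst = rng.random(n) < mix.burst_weight
    burst = rng.gamma(mix.burst_shape, mix.burst_mean / mix.burst_shape, n)
    tonic = rng.exponential(mix.tonic_mean, n)
    return mix.refractory + np.where(is_burst, burst, tonic)


class TestSolveIsiMixture:
    def test_boundary_burst_only(self):
        f_burst = sps.gamma.cdf(4.0, a=2.0, scale=1.5)  # P(X < 5-1 ms)
        mix = sf.solve_isi_mixture(10.0, f_burst)
        assert mix.burst_weight == pytest.approx(1.0)

    def test_boundary_tonic_only(self):
        # Tonic-only short fraction for the mean the rate dictates.
        m_free = 1000.0 / 5.0 - 1.0
        target = 1.0 - np.exp(-4.0 / m_free)
        mix = sf.solve_isi_mixture(5.0, target)
        assert mix.burst_weight == pytest.approx(0.0, abs=1e-9)
        assert mix.tonic_mean == pytest.approx(m_free)

    def test_infeasible_target_names_interval(self):
        with pytest.raises(sf.InfeasibleTargetError, match=r"attainable interval"):
            sf.solve_isi_mixture(5.0, 0.9)

    def test_rate_too_high(self):
        with pytest.raises(sf.InfeasibleTargetError):
            sf.solve_isi_mixture(400.0, 0.2)

    def test_solved_constraints_hold(self):
        mix = sf.solve_isi_mixture(15.11, 0.2489)
        assert mix.rate_hz == pytest.approx(15.11, rel=1e-9)
        assert mix.short_fraction() == pytest.approx(0.2489, abs=1e-9)

    def test_monte_carlo_short_fraction(self, rng):
        """10^6 draws from the stated mixture hit the target within 0.005."""
        mix = sf.solve_isi_mixture(15.11, 0.2489)
        isi = draw_mixture_isis(mix, 1_000_000, rng)
        assert np.mean(isi < 5.0) == pytest.approx(0.2489, abs=0.005)
        assert isi.mean() == pytest.approx(1000.0 / 15.11, rel=0.005)

    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_preset_calibration(self, catalog, name, rng):
        """Every shipped preset's mixture reproduces its short-ISI fraction."""
        p = catalog.ephys[name]
        mix = sf.solve_isi_mixture(p.group_mean_rate, p.short_isi_fraction)
        isi = draw_mixture_isis(mix, 1_000_000, rng)
        assert np.mean(isi < 5.0) == pytest.approx(p.short_isi_fraction, abs=0.005)


class TestGenSpikeTimes:
    def test_deterministic(self):
        mix = sf.solve_isi_mixture(8.0, 0.21)
        a = sf.gen_spike_times(mix, 60.0, seed=5)
        b = sf.gen_spike_times(mix, 60.0, seed=5)
        np.testing.assert_array_equal(a.spike_times, b.spike_times)

    def test_count_matches_renewal_expectation(self):
        mix = sf.solve_isi_mixture(5.0, 0.1986)
        gt = sf.gen_spike_times(mix, 300.0, seed=17)
        assert abs(gt.n_spikes - 1500) <= 3 * np.sqrt(1500)

    def test_refractory_and_bounds(self):
        mix = sf.solve_isi_mixture(20.0, 0.3)
        gt = sf.gen_spike_times(mix, 30.0, seed=2)
        d = np.diff(gt.spike_times)
        assert d.min() * 1000.0 >= mix.refractory
        assert gt.spike_times[0] >= 0 and gt.spike_times[-1] <= 30.0

    def test_degenerate_window(self):
        mix = sf.solve_isi_mixture(10.0, 0.2)
        gt = sf.gen_spike_times(mix, 0.0005, seed=1)
        assert gt.n_spikes <= 1


class TestGenVoltage:
    def test_noiseless_single_spike(self, template):
        gt = sf.GroundTruthSpikes(
            spike_times=np.array([1.0]), true_rate=0.5, duration=2.0
        )
        rec = sf.gen_voltage(gt, template, noise_sd=0.0, seed=0)
        wave = template.samples_uv
        half = wave.size // 2
        lo = 60_000 - half
        np.testing.assert_allclose(rec.samples[lo : lo + wave.size], wave, atol=1e-5)
        mask = np.ones(rec.n_samples, dtype=bool)
        mask[lo : lo + wave.size] = False
        assert np.all(rec.samples[mask] == 0)

    def test_noiseless_extrema_count(self, template):
        times = np.array([0.25, 0.5, 0.9, 1.4])
        gt = sf.GroundTruthSpikes(spike_times=times, true_rate=2.0, duration=2.0)
        rec = sf.gen_voltage(gt, template, noise_sd=0.0, seed=0)
        deep = rec.samples < -0.5 * template.peak_amplitude_uv
        n_events = np.count_nonzero(deep[1:] & ~deep[:-1])
        assert n_events == times.size


class TestGenGroup:
    def test_sizes_and_ground_truth(self, catalog):
        p = dataclasses.replace(catalog.ephys["control_pre"], duration=1.0)
        pairs = sf.gen_group(p, master_seed=9)
        assert len(pairs) == 7
        for rec, gt in pairs:
            assert isinstance(rec, sf.RawRecording)
            assert isinstance(gt, sf.GroundTruthSpikes)
            assert rec.duration == pytest.approx(1.0)

    def test_zero_between_animal_sd(self, catalog):
        p = dataclasses.replace(
            catalog.ephys["control_pre"], between_animal_sd=0.0, duration=0.5
        )
        pairs = sf.gen_group(p, master_seed=3)
        rates = [rec.metadata["true_rate_hz"] for rec, _ in pairs]
        assert rates == pytest.approx([p.group_mean_rate] * 7)

    def test_grand_mean_of_true_rates(self, catalog):
        """200 groups of 7: the grand mean matches the preset distribution."""
        p = dataclasses.replace(catalog.ephys["control_pre"], duration=0.05)
        rates = []
        for g in range(200):
            for rec, _ in sf.gen_group(p, master_seed=10_000 + g):
                rates.append(rec.metadata["true_rate_hz"])
        se = p.between_animal_sd / np.sqrt(len(rates))
        assert np.mean(rates) == pytest.approx(p.group_mean_rate, abs=3 * se)


class TestGenStartleSession:
    def test_noiseless_inversion(self, catalog):
        p = dataclasses.replace(catalog.behavior["tinnitus_baseline"], trial_cv=0.0)
        session = sf.gen_startle_session(p, seed=1)
        assert sf.gpias_index(session) == pytest.approx(44.40)
        assert sf.ppi_index(session) == pytest.approx(92.97)

    def test_full_inhibition(self, catalog):
        p = dataclasses.replace(
            catalog.behavior["tinnitus_baseline"], gpias_true=100.0, trial_cv=0.0
        )
        session = sf.gen_startle_session(p, seed=1)
        assert np.all(session.amplitudes("gap") == 0)
        assert sf.gpias_index(session) == pytest.approx(100.0)

    def test_no_inhibition_unbiased(self, catalog):
        """gpias_true = 0: gap and no-gap identically distributed."""
        p = dataclasses.replace(catalog.behavior["tinnitus_baseline"], gpias_true=0.0)
        estimates = [
            sf.gpias_index(sf.gen_startle_session(p, seed=s)) for s in range(100)
        ]
        # SE of the mean estimate ~ cv * 100 / sqrt(16) / sqrt(100) ~ 0.4
        assert np.mean(estimates) == pytest.approx(0.0, abs=1.5)

    def test_trial_counts_and_determinism(self, catalog):
        p = catalog.behavior["control_baseline"]
        s1 = sf.gen_startle_session(p, seed=4)
        s2 = sf.gen_startle_session(p, seed=4)
        counts = {
            tt: len(s1.amplitudes(tt))
            for tt in ("gap", "no_gap", "pulse", "prepulse", "no_stim")
        }
        assert counts == {"gap": 16, "no_gap": 16, "pulse": 15, "prepulse": 10,
                          "no_stim": 8}
        assert [t.amplitude for t in s1.trials] == [t.amplitude for t in s2.trials]
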
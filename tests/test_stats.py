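"""Rank statistics vs. brute-force oracles; normality-gated comparisons."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spontfire as sf
from oracles import bf_chi2, bf_kruskal_h, bf_ks_d, bf_rank_biserial, bf_u_statistic

small_group = st.lists(
    st.integers(min_value=0, max_value=6).map(float), min_size=2, max_size=8
)


class TestKruskalWallis:
    def test_identical_multisets_h_zero(self):
        h, p = sf.kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_values(self):
        h, p = sf.kruskal_wallis([2, 2, 2], [2, 2])
        assert (h, p) == (0.0, 1.0)

    def test_separated_groups_match_oracle(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        h, _ = sf.kruskal_wallis(a, b)
        assert h == pytest.approx(bf_kruskal_h(a, b), abs=1e-10)

    def test_shift_invariance(self):
        a, b = [1.0, 5.0, 2.0], [4.0, 0.5, 9.0]
        h0, _ = sf.kruskal_wallis(a, b)
        h1, _ = sf.kruskal_wallis(np.add(a, 100.0), np.add(b, 100.0))
        assert h1 == pytest.approx(h0, abs=1e-12)

    @settings(deadline=None, max_examples=120, derandomize=True)
    @given(a=small_group, b=small_group)
    def test_matches_brute_force_with_ties(self, a, b):
        if len(set(a + b)) == 1:
            return  # degenerate tie case covered above
        h, _ = sf.kruskal_wallis(a, b)
        assert h == pytest.approx(bf_kruskal_h(a, b), abs=1e-10)


class TestRankBiserial:
    def test_complete_separation(self):
        assert sf.rank_biserial([4, 5, 6], [1, 2, 3]) == pytest.approx(1.0)
        assert sf.rank_biserial([1, 2, 3], [4, 5, 6]) == pytest.approx(-1.0)

    def test_identical_groups(self):
        assert sf.rank_biserial([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_pair_counting_example(self):
        a, b = [3.0, 4.0, 5.0], [1.0, 2.0, 6.0]
        assert sf.rank_biserial(a, b) == pytest.approx(bf_rank_biserial(a, b))

    @settings(deadline=None, max_examples=120, derandomize=True)
    @given(a=small_group, b=small_group)
    def test_matches_pair_enumeration(self, a, b):
        r = sf.rank_biserial(a, b)
        assert r == pytest.approx(bf_rank_biserial(a, b), abs=1e-10)
        u = bf_u_statistic(a, b)
        assert r == pytest.approx(2 * u / (len(a) * len(b)) - 1, abs=1e-10)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(a=small_group, b=small_group)
    def test_monotone_transform_invariance(self, a, b):
        r0 = sf.rank_biserial(a, b)
        f = lambda x: np.exp(np.asarray(x) / 2.0)  # strictly increasing
        assert sf.rank_biserial(f(a), f(b)) == pytest.approx(r0, abs=1e-12)


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "r,p,tier",
        [
            (0.6, 0.01, "high"),
            (0.9, 0.20, "ns"),
            (0.2, 0.01, "medium"),  # boundary inclusive at 0.2
            (0.19, 0.01, "low"),
            (-0.5, 0.04, "high"),  # |r| at the 0.5 boundary
            (0.49, 0.04, "medium"),
        ],
    )
    def test_tiers(self, r, p, tier):
        assert sf.classify_effect(r, p) == tier

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sf.classify_effect(1.5, 0.01)


class TestTimepointScan:
    def _series(self, rates, n=5, fs=10.0):
        return [
            sf.RateSeries(t=np.arange(n) / fs, rate=np.full(n, r) + np.arange(n),
                          window=1.0, fs=fs)
            for r in rates
        ]

    def test_single_row_when_step_spans_recording(self):
        a = self._series([1.0, 2.0], n=10)
        b = self._series([5.0, 6.0], n=10)
        table = sf.timepoint_scan(a, b, step=1.0)
        assert len(table) == 1

    def test_mismatched_lengths_rejected(self):
        a = self._series([1.0, 2.0], n=10)
        b = self._series([5.0, 6.0], n=12)
        with pytest.raises(ValueError, match="share length"):
            sf.timepoint_scan(a, b)

    def test_columns_and_tier_gate(self):
        rng = np.random.default_rng(1)
        fs = 10.0
        mk = lambda mu: [
            sf.RateSeries(t=np.arange(100) / fs,
                          rate=np.abs(rng.normal(mu, 1.0, 100)),
                          window=1.0, fs=fs)
            for _ in range(4)
        ]
        table = sf.timepoint_scan(mk(5.0), mk(5.0), step=1.0)
        assert set(table.columns) >= {"t_s", "H", "p", "rank_biserial", "effect_tier"}
        ns_rows = table[table.p >= 0.05]
        assert (ns_rows.effect_tier == "ns").all()


class TestCompareGroupMeans:
    def test_identical_paired_degenerate(self):
        a = [1.0, 2.0, 3.0, 4.0]
        with pytest.warns(UserWarning, match="identical"):
            cmp = sf.compare_group_means(a, a, paired=True)
        assert cmp.statistic == 0.0 and cmp.p == 1.0

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            sf.compare_group_means([1, 2, 3], [1, 2, 3, 4], paired=True)

    def test_normality_gate_routes_to_t_test(self):
        """Two Gaussian n=7 samples should usually take the parametric route."""
        rng = np.random.default_rng(314)
        routed_t = 0
        for _ in range(1000):
            cmp = sf.compare_group_means(rng.normal(0, 1, 7), rng.normal(0, 1, 7))
            routed_t += cmp.test_used == "unpaired t"
        assert routed_t >= 800

    def test_power_at_group_separation(self):
        """15.11±2.64 vs 5.17±1.31 Hz, n=7: detected at p<0.001 essentially
        always."""
        rng = np.random.default_rng(2718)
        hits = 0
        for _ in range(1000):
            cmp = sf.compare_group_means(
                rng.normal(15.11, 2.64, 7), rng.normal(5.17, 1.31, 7)
            )
            hits += cmp.p < 0.001
        assert hits >= 990


class TestKsTwoSample:
    def test_identical_samples(self):
        d, _ = sf.ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_disjoint_supports(self):
        d, _ = sf.ks_two_sample([1.0, 2.0], [10.0, 11.0])
        assert d == 1.0

    def test_matches_brute_force_ecdf_scan(self, rng):
        mix_a = sf.solve_isi_mixture(15.11, 0.2489)
        mix_b = sf.solve_isi_mixture(5.17, 0.1986)
        a = sf.gen_spike_times(mix_a, 80.0, seed=1).spike_times
        b = sf.gen_spike_times(mix_b, 220.0, seed=2).spike_times
        isis_a, isis_b = sf.isis(a)[:1000], sf.isis(b)[:1000]
        d, _ = sf.ks_two_sample(isis_a, isis_b)
        assert d == pytest.approx(bf_ks_d(isis_a, isis_b), abs=1e-12)


class TestChi2ShortIsi:
    def test_equal_proportions(self):
        chi2, p = sf.chi2_short_isi((25, 75), (50, 150))
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_table(self):
        chi2, _ = sf.chi2_short_isi((20, 80), (10, 90))
        assert chi2 == pytest.approx(3.9216, abs=1e-4)
        assert chi2 == pytest.approx(bf_chi2([[20, 80], [10, 90]]), abs=1e-10)

    def test_row_swap_symmetry(self):
        c1, _ = sf.chi2_short_isi((20, 80), (10, 90))
        c2, _ = sf.chi2_short_isi((10, 90), (20, 80))
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_small_expected_counts_warn(self):
        with pytest.warns(UserWarning, match="expected cell"):
            sf.chi2_short_isi((1, 5), (2, 4))


class TestPairedSpikeCountTest:
    def test_no_change(self):
        cmp = sf.paired_spike_count_test([100, 200, 300], [100, 200, 300])
        assert cmp.statistic == 0.0 and cmp.p == 1.0

    def test_constant_shift_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            cmp = sf.paired_spike_count_test([110, 210, 310], [100, 200, 300])
        assert cmp.p == 0.0

    def test_power_pre_vs_post_suppression(self):
        """Counts at the tinnitus pre/post group rates: the drop is detected
        in essentially every replicate."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(1000):
            before = rng.normal(15.11, 2.64, 7) * 300.0
            after = rng.normal(6.07, 2.03, 7) * 300.0
            hits += sf.paired_spike_count_test(before, after).p < 0.05
        assert hits >= 990
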
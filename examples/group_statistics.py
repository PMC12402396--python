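"""Per-timepoint rank tests and ISI comparisons between two conditions.

Simulates 7 animals per group (60-s ground-truth trains at the elevated vs.
normal baseline conditions), scans 1-s timepoints with Kruskal-Wallis +
rank-biserial effect tiers, and compares the pooled ISI distributions with
the two-sample KS test and the short-ISI 2x2 chi-square.
"""

import numpy as np

import spontfire as sf

catalog = sf.load_catalog()
rng = np.random.default_rng(0)
groups = {}
for name in ("tinnitus_pre", "control_pre"):
    p = catalog.ephys[name]
    series, pooled = [], []
    for a in range(7):
        rate = max(0.5, rng.normal(p.group_mean_rate, p.between_animal_sd))
        mix = sf.solve_isi_mixture(rate, p.short_isi_fraction)
        gt = sf.gen_spike_times(mix, 60.0, seed=1000 + 10 * a + (name == "control_pre"))
        train = sf.to_binary_train(gt.spike_times, 5000.0, 60.0)
        series.append(sf.sfr(train))
        pooled.append(sf.isis(gt.spike_times))
    groups[name] = (series, np.concatenate(pooled))

table = sf.timepoint_scan(groups["tinnitus_pre"][0], groups["control_pre"][0])
sig = table["p"] < 0.05
print(f"timepoints: {len(table)}, significant: {int(sig.sum())} "
      f"({100 * sig.mean():.0f}%)")
print("effect tiers:", table["effect_tier"].value_counts().to_dict())

isis_a, isis_b = groups["tinnitus_pre"][1], groups["control_pre"][1]
d, ks_p = sf.ks_two_sample(isis_a, isis_b)
short = lambda x: int(np.sum(x < 5.0))
chi2, chi2_p = sf.chi2_short_isi(
    (short(isis_a), isis_a.size - short(isis_a)),
    (short(isis_b), isis_b.size - short(isis_b)),
)
print(f"KS D = {d:.4f} (p = {ks_p:.2e}); chi2 = {chi2:.1f} (p = {chi2_p:.2e})")
# The elevated condition separates from control at nearly every timepoint
# with high effect sizes, and its ISI distribution is shifted toward short
# intervals (larger burst fraction).
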
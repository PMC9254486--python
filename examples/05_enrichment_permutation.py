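"""Matched-permutation colocalization test between chromatin markers and
R-loop peaks.

The observed statistic is merged base-pair overlap; the null re-places the
marker peaks uniformly over the mask-free genome, preserving each peak's
length (and, for ChIP-chip tracks, its probe density).  This dataset
plants marker enrichment factors of 2.0, 1.0 and 0.5, so the recovered
log2 fold enrichments should sit near +1, 0 and -1.
"""

import rloopscape as rl

ds = rl.generate_dataset(rl.SimulationConfig(seed=11))

results, table = rl.enrichment_panel(
    {"S2": ds.tracks.rloops["S2"]},
    ds.tracks.markers,
    ds.mask,
    ds.layout,
    cfg=rl.ShuffleConfig(n_permutations=500),
    seed=23,
)
cols = ["marker", "observed_bp", "null_mean_bp", "log2_fold", "p_adjusted", "direction"]
print(table[cols].round(3).to_string(index=False))
print("\nplanted rho: bound_factor=2.0, independent_factor=1.0, avoided_factor=0.5")
print("p_adjusted is Bonferroni over the 3-cell panel of one-tailed empirical p-values")

# ChIP-chip-style marker: the shuffle additionally preserves probe density
pm = rl.ProbeMap(ds.tracks.probes)
shuffled, achieved = rl.shuffle_once(
    ds.tracks.chipchip_peaks, ds.mask, ds.layout, probe_map=pm,
    cfg=rl.ShuffleConfig(), rng=5,
)
print(f"\nprobe-density-matched shuffle: {100 * achieved:.1f}% of "
      f"{len(shuffled)} peaks within the 2-SD density tolerance")
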
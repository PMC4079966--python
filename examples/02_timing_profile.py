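"""Compute a continuous replication-timing profile from fraction reads.

The per-bin score is the weighted average (w.x)/sum(x) of RPKM across the
four fractions with weights 0.125/0.375/0.625/0.875 (latest to earliest);
high values replicate early. The raw score is loess-smoothed over ~200 kb.
"""

import numpy as np

import replitime as rt

config = rt.SimulationConfig(seed=7)
truth = rt.simulate_genome(config)
reads = rt.simulate_fraction_reads(truth, config)

grid = rt.BinGrid(config.chrom_sizes, width=10_000)
signal = rt.fraction_signal_from_reads(reads, grid)
profile = rt.smooth_profile(rt.compute_profile(signal))
profile.log2_ratio = rt.timing_ratio(signal)

true_t = np.concatenate(
    [truth.true_timing(c, grid.starts(c) + 5_000) for c in grid.chroms]
)
ok = np.isfinite(profile.smoothed)
r = np.corrcoef(profile.smoothed[ok], true_t[ok])[0, 1]

print(f"{grid.total_bins} bins of 10 kb; {int(ok.sum())} scored")
print(f"score range: {np.nanmin(profile.smoothed):.3f} .. {np.nanmax(profile.smoothed):.3f}")
print(f"Pearson r between smoothed score and planted replication time: {r:.3f}")
# r above ~0.95 means the weighted score tracks the planted timing almost
# perfectly at this depth; the bounds stay inside [0.125, 0.875] by design.
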
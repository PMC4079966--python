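"""Annotate called domains with feature densities and per-chromosome timing.

TSS-like point features are planted at 10 per 100 kb in early domains and 2
in late domains; counting feature starts per called domain should recover
that contrast. The per-chromosome summary compares one chromosome's 10-kb
timing values against the pooled rest with a Mann-Whitney U test.
"""

import numpy as np

import replitime as rt

config = rt.SimulationConfig(seed=7)
truth = rt.simulate_genome(config)
reads = rt.simulate_fraction_reads(truth, config)
tss = rt.simulate_features(truth, config, config.tss_density)

# feature density per planted domain, aggregated by label
table = rt.feature_density(tss, truth.domains).table
for label, grp in table.groupby("label"):
    density = grp["count"].sum() / grp["length_bp"].sum() * 1e5
    print(f"TSS density in {label:>5} domains: {density:5.2f} per 100 kb")

# per-chromosome timing distribution and a target-vs-rest rank test
grid = rt.BinGrid(config.chrom_sizes, width=10_000)
profile = rt.smooth_profile(
    rt.compute_profile(rt.fraction_signal_from_reads(reads, grid))
)
summary = rt.chromosome_timing_summary(profile, target="chrX")
print(summary.summaries.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"chrX vs autosomes: Mann-Whitney U = {summary.statistic:.0f}, p = {summary.pvalue:.3g}")
# Densities near 10 and 2 recover the planted contrast. All chromosomes were
# simulated from the same timing distribution here, so the test should not
# reject (p well above any conventional threshold).
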
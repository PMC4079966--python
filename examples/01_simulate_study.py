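"""Generate a synthetic Repli-Seq study with planted replication domains.

Builds a 20-Mb four-chromosome genome tiled with 100-500-kb early/late
domains, draws four S-phase fraction read sets whose proportions follow each
bin's true replication time, and writes everything as BED/chrom.sizes text.
"""

from pathlib import Path

import replitime as rt

outdir = Path("scratch/example_study")

config = rt.SimulationConfig(seed=7)
truth = rt.simulate_genome(config)
reads = rt.simulate_fraction_reads(truth, config)
tss = rt.simulate_features(truth, config, config.tss_density)

rt.write_simulation(outdir, config, truth, reads, {"tss": tss})

print(f"genome: {sum(config.chrom_sizes.values()) / 1e6:.0f} Mb over {len(config.chrom_sizes)} chromosomes")
print(f"planted domains: {len(truth.domains)} (early fraction {truth.early_fraction():.3f})")
for frac in rt.FRACTIONS:
    print(f"  {frac:>9}: {len(reads[frac]):>7} reads")
print(f"written to {outdir}/")
# The early fraction of the genome should sit near the configured 0.5, and
# read totals are largest in the early/late fractions because domain times
# concentrate in the outer S-phase quarters.
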
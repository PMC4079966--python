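# replitime

Replication-timing analysis of Repli-Seq data: continuous timing profiles,
HMM-based replication-domain calling, and cross-cell-line comparison of
static vs dynamic domains.

## The problem

In Repli-Seq, actively replicating cells are pulse-labeled with BrdU and
flow-sorted into four S-phase fractions — early (E), early-mid (E–M),
late-mid (L–M) and late (L) — and the nascent DNA of each fraction is
sequenced. A genomic region's reads concentrate in the fraction matching the
time it replicates, so comparing read abundance across fractions reveals the
genome's replication-timing program: broad (>100 kb) domains that replicate
coherently early or late in S phase, and, across cell lines, the distinction
between *static* domains (same timing everywhere) and *dynamic* domains that
switch. This package implements the computational side of that analysis for
anyone working with fraction-sorted replication sequencing data (it was
built around *Drosophila* cell-line data, but nothing is genome-specific).

## Method

**Continuous profile.** Per 10-kb bin, RPKM is computed for each fraction
and combined into the weighted score

&nbsp;&nbsp;&nbsp;&nbsp;s = (w · x) / Σₖ xₖ,&nbsp;&nbsp;&nbsp;w = (0.125, 0.375, 0.625, 0.875)

where x is the RPKM vector ordered latest → earliest and the weights are the
midpoints of each fraction's nominal quarter of S phase; s ∈ [0.125, 0.875],
high = early. The score is smoothed chromosome-wise by loess (tricube
weights, degree 2) over a ~200-kb window.

**Domain calling.** On 5-kb windows stepped every 1 kb, the bivariate
(E, L) RPKM — normalized by each chromosome's mean RPKM to correct for
aneuploidy, and capped at the 95th percentile — is modeled with a
three-state hidden Markov model (early / late / indeterminate), each state
emitting a bivariate normal. Emissions are seeded by k-means (k = 3) on the
log₂(E/L) ratio; each chromosome is trained by Baum-Welch (stop at
Δlog L < 0.05) and decoded by Viterbi; state runs shorter than 40 windows
(~45 kb) are merged into their larger neighbour.

**Comparison and annotation.** Across ≥2 cell lines, every 1-kb position is
classified static early / static late / dynamic / indeterminate; domains are
annotated with point-feature densities (TSS, ORC sites, per 100 kb),
bp-weighted median track enrichments, and per-chromosome timing
distributions with a Mann-Whitney U test (e.g. X vs autosomes).

A synthetic-data module generates multi-chromosome genomes with planted
early/late domains, fraction reads drawn from
p_k(t) ∝ exp(−κ(t − m_k)²), copy-number effects and point features, so the
whole pipeline is testable against known truth.

## Worked example

`examples/` holds one short script per capability. Calling domains on a
synthetic 20-Mb study (`python examples/03_call_domains.py`) prints:

```
early            24
late             23
indeterminate     1
chr2L: 6 EM iterations, final logL 9316.0
chr2R: 9 EM iterations, final logL 10159.0
chr3L: 7 EM iterations, final logL 9091.0
chrX: 7 EM iterations, final logL 9285.7
position-level agreement with planted labels: 0.9886
```

i.e. the HMM recovers 47 of the 67 planted domains as merged early/late
intervals (neighbouring same-label domains merge), converges in a handful of
EM sweeps per chromosome, and reproduces the planted label at 98.9% of 1-kb
positions. The cross-line comparison (`examples/04_static_dynamic.py`) on
three lines with a planted 10% switch fraction prints class fractions of
42.3% static early, 46.5% static late, 10.5% dynamic and 0.7% indeterminate.

The same stages are available from a shell:

```bash
replitime simulate --outdir study --seed 7
replitime domains --late study/reads_late.bed --late-mid study/reads_late_mid.bed \
    --early-mid study/reads_early_mid.bed --early study/reads_early.bed \
    --chrom-sizes study/chrom.sizes --outdir out --sample line1
# ...call domains for each remaining cell line, then:
replitime compare out/domains_line1.bed out/domains_line2.bed \
    --chrom-sizes study/chrom.sizes --outdir out
```

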
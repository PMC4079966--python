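"""Synthetic Repli-Seq data with known ground truth.

The generator plants early/late replication domains on a multi-chromosome
genome, assigns each domain a true replication time ``t`` in [0, 1] (early
domains high, late domains low), and draws sequencing reads for the four
S-phase fractions (late, late-mid, early-mid, early). Within a genomic bin
the total read count is Poisson with mean proportional to the chromosome's
copy-number multiplier, and the counts are apportioned across fractions with
probabilities

    p_k(t) ∝ exp(−κ · (t − m_k)²),   m_k ∈ {0.125, 0.375, 0.625, 0.875}

where κ (the concentration) controls how sharply reads concentrate in the
fraction whose nominal S-phase quarter contains ``t``. This is the minimal
smooth model under which the weighted timing score is an approximately
unbiased estimator of ``t``. Point features (TSS, ORC sites) are homogeneous
point processes with domain-label-dependent densities.

Everything is driven by a single integer seed: fixing the seed fixes every
output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import write_bed, write_chrom_sizes

#: fraction order used throughout the package: latest to earliest S phase
FRACTIONS = ("late", "late_mid", "early_mid", "early")

#: midpoints of the nominal S-phase quarters, aligned with FRACTIONS
FRACTION_MIDPOINTS = np.array([0.125, 0.375, 0.625, 0.875])

_DEFAULT_CHROMS = {"chr2L": 5_000_000, "chr2R": 5_000_000, "chr3L": 5_000_000, "chrX": 5_000_000}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic Repli-Seq study.

    Defaults describe a 20-Mb genome with 100–500-kb domains, half the genome
    replicating early, 100 reads per 10-kb bin per line, and a concentration
    high enough that a bin at t = 0.95 places >80% of its reads in the early
    fraction.
    """

    chrom_sizes: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_CHROMS))
    domain_min_bp: int = 100_000
    domain_max_bp: int = 500_000
    frac_early: float = 0.5
    copy_number: Mapping[str, float] = field(default_factory=dict)
    mean_reads_per_bin: float = 100.0
    sim_bin_bp: int = 10_000
    concentration: float = 20.0
    read_length: int = 50
    seed: int = 0
    tss_density: Mapping[str, float] = field(
        default_factory=lambda: {"early": 10.0, "late": 2.0}
    )  # per 100 kb
    orc_density: Mapping[str, float] = field(
        default_factory=lambda: {"early": 6.0, "late": 1.0}
    )  # per 100 kb

    def __post_init__(self):
        if len(self.chrom_sizes) < 1 or any(l <= 0 for l in self.chrom_sizes.values()):
            raise ValueError("chromosome lengths must be positive")
        if not 0 < self.frac_early < 1:
            raise ValueError("frac_early must be in (0, 1)")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not 0 < self.domain_min_bp <= self.domain_max_bp:
            raise ValueError("need 0 < domain_min_bp <= domain_max_bp")
        if self.domain_min_bp > max(self.chrom_sizes.values()):
            raise ValueError("domain_min_bp exceeds every chromosome length")
        if any(d < 0 for d in self.tss_density.values()) or any(
            d < 0 for d in self.orc_density.values()
        ):
            raise ValueError("feature densities must be >= 0")

    def multiplier(self, chrom: str) -> float:
        return float(self.copy_number.get(chrom, 1.0))

    def as_flat_dict(self) -> dict[str, str]:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, Mapping):
                v = ",".join(f"{k}:{val}" for k, val in v.items())
            d[f.name] = str(v)
        return d


@dataclass
class SyntheticTruth:
    """Planted domain structure: disjoint labeled intervals tiling each chromosome."""

    domains: pd.DataFrame  # chrom, start, end, label, t
    chrom_sizes: dict[str, int]

    def true_timing(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """True replication time at base-pair positions on one chromosome."""
        d = self.domains[self.domains["chrom"] == chrom]
        idx = np.searchsorted(d["start"].to_numpy(), positions, side="right") - 1
        return d["t"].to_numpy()[idx]

    def true_label(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        d = self.domains[self.domains["chrom"] == chrom]
        idx = np.searchsorted(d["start"].to_numpy(), positions, side="right") - 1
        return d["label"].to_numpy()[idx]

    def early_fraction(self) -> float:
        lengths = self.domains["end"] - self.domains["start"]
        early = lengths[self.domains["label"] == "early"].sum()
        return float(early / lengths.sum())


def _domain_t(label: str, rng: np.random.Generator) -> float:
    # early domains sample t from the top S-phase quarter, late from the bottom
    lo, hi = (0.75, 1.0) if label == "early" else (0.0, 0.25)
    return float(rng.uniform(lo, hi))


def simulate_genome(config: SimulationConfig) -> SyntheticTruth:
    """Tile each chromosome with early/late domains of random length.

    Domain lengths are drawn uniformly on [domain_min_bp, domain_max_bp] on a
    ``sim_bin_bp`` lattice (so read bins never straddle a boundary). Labels are
    assigned greedily toward the requested early fraction, which keeps the
    achieved fraction within one domain length of the target.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    early_bp = 0
    total_bp = 0
    lat = config.sim_bin_bp
    for chrom, length in config.chrom_sizes.items():
        pos = 0
        while pos < length:
            lo = max(1, config.domain_min_bp // lat)
            hi = max(lo, config.domain_max_bp // lat)
            dlen = int(rng.integers(lo, hi + 1)) * lat
            end = min(pos + dlen, length)
            if length - end < config.domain_min_bp:
                end = length  # absorb a too-short remainder into this domain
            # greedy toward the target early fraction: achieved stays within
            # one domain length of the request
            label = "early" if early_bp <= config.frac_early * total_bp else "late"
            rows.append((chrom, pos, end, label, _domain_t(label, rng)))
            if label == "early":
                early_bp += end - pos
            total_bp += end - pos
            pos = end
    domains = pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "t"])
    return SyntheticTruth(domains=domains, chrom_sizes=dict(config.chrom_sizes))


def fraction_probabilities(t: np.ndarray, concentration: float) -> np.ndarray:
    """p_k(t) over the four fractions; shape (len(t), 4). κ = 0 gives 1/4 each."""
    t = np.asarray(t, dtype=float)
    logits = -concentration * (t[..., None] - FRACTION_MIDPOINTS) ** 2
    w = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return w / w.sum(axis=-1, keepdims=True)


def simulate_fraction_reads(
    truth: SyntheticTruth, config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, pd.DataFrame]:
    """Draw one BED read set per S-phase fraction.

    Per simulation bin the total count is Poisson with mean
    ``mean_reads_per_bin × copy_number``, split multinomially across fractions
    by ``p_k(t)``; read starts are uniform within the bin, written as
    fixed-length single-end intervals on the + strand.
    """
    missing = set(config.chrom_sizes) - set(truth.domains["chrom"])
    if missing:
        raise ValueError(f"truth does not cover chromosomes: {sorted(missing)}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    reads: dict[str, list[pd.DataFrame]] = {f: [] for f in FRACTIONS}
    for chrom, length in config.chrom_sizes.items():
        starts = np.arange(0, length, config.sim_bin_bp)
        ends = np.minimum(starts + config.sim_bin_bp, length)
        widths = ends - starts
        mean = config.mean_reads_per_bin * config.multiplier(chrom) * widths / config.sim_bin_bp
        totals = rng.poisson(mean)
        t = truth.true_timing(chrom, starts)
        probs = fraction_probabilities(t, config.concentration)
        counts = np.empty((len(starts), 4), dtype=int)
        for i in range(len(starts)):
            counts[i] = rng.multinomial(totals[i], probs[i])
        for k, frac in enumerate(FRACTIONS):
            n_per_bin = counts[:, k]
            bin_idx = np.repeat(np.arange(len(starts)), n_per_bin)
            offs = rng.random(bin_idx.size) * (widths[bin_idx] - config.read_length).clip(min=1)
            s = (starts[bin_idx] + offs.astype(int)).astype(int)
            df = pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": np.sort(s),
                    "end": np.sort(s) + config.read_length,
                    "name": ".",
                    "score": 0,
                    "strand": "+",
                }
            )
            reads[frac].append(df)
    return {f: pd.concat(parts, ignore_index=True) for f, parts in reads.items()}


def simulate_features(
    truth: SyntheticTruth,
    config: SimulationConfig,
    densities: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Homogeneous point process per domain at the label's density (per 100 kb)."""
    if densities is None:
        densities = config.tss_density
    if any(d < 0 for d in densities.values()):
        raise ValueError("densities must be >= 0")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rows = []
    for dom in truth.domains.itertuples(index=False):
        lam = densities.get(dom.label, 0.0) * (dom.end - dom.start) / 1e5
        n = rng.poisson(lam)
        pos = np.sort(rng.integers(dom.start, dom.end, size=n))
        for p in pos:
            rows.append((dom.chrom, int(p), int(p) + 1, dom.label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def perturb_truth(
    truth: SyntheticTruth, switch_fraction: float, seed: int
) -> SyntheticTruth:
    """Flip the early/late label of a random domain subset covering ~``switch_fraction``
    of the genome — the planted 'dynamic' regions for a derived cell line.

    Domains are visited in random order and flipped whenever doing so brings
    the flipped-bp total closer to the target, so the achieved fraction is
    within about half a domain length of the request.
    """
    rng = np.random.default_rng(seed)
    domains = truth.domains.copy().reset_index(drop=True)
    lengths = (domains["end"] - domains["start"]).to_numpy()
    target = switch_fraction * lengths.sum()
    order = rng.permutation(len(domains))
    flipped = 0.0
    flip_idx = []
    for i in order:
        if abs(flipped + lengths[i] - target) < abs(flipped - target):
            flip_idx.append(i)
            flipped += lengths[i]
    for i in flip_idx:
        new_label = "late" if domains.at[i, "label"] == "early" else "early"
        domains.at[i, "label"] = new_label
        domains.at[i, "t"] = _domain_t(new_label, rng)
    return SyntheticTruth(domains=domains, chrom_sizes=dict(truth.chrom_sizes))


def write_simulation(
    outdir: str | Path,
    config: SimulationConfig,
    truth: SyntheticTruth,
    reads: Mapping[str, pd.DataFrame],
    features: Mapping[str, pd.DataFrame] | None = None,
) -> None:
    """Write the full synthetic study: per-fraction read BEDs, chrom.sizes,
    truth BED (label in column 4) and the config as flat key=value text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_chrom_sizes(config.chrom_sizes, outdir / "chrom.sizes")
    for frac, df in reads.items():
        write_bed(df, outdir / f"reads_{frac}.bed")
    write_bed(truth.domains[["chrom", "start", "end", "label"]], outdir / "truth_domains.bed")
    for name, df in (features or {}).items():
        write_bed(df, outdir / f"features_{name}.bed")
    with open(outdir / "config.txt", "w") as fh:
        for k, v in config.as_flat_dict().items():
            fh.write(f"{k}={v}\n")
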
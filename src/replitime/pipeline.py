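"""End-to-end pipeline stages tying binning, timing, segmentation and comparison
together, with provenance-stamped outputs.

Defaults are the study constants: 10-kb nonoverlapping profile bins; 5-kb
windows stepped 1 kb for segmentation; fraction weights 0.125/0.375/0.625/
0.875 (latest → earliest); ~200-kb loess window; 95th-percentile cap;
Baum-Welch tolerance 0.05; 40-window minimum run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import (
    BinGrid,
    cap_percentile,
    fraction_signal_from_reads,
    normalize_by_chromosome,
)
from .comparison import chromosome_timing_summary, classify_positions, genome_fractions
from .io import provenance_header, read_bed, read_chrom_sizes, write_bed, write_bedgraph
from .segmentation import DomainSet, segment_genome
from .simulate import FRACTIONS
from .timing import TimingProfile, compute_profile, smooth_profile, timing_ratio

logger = logging.getLogger("replitime")


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters; defaults are the study's values."""

    fraction_files: dict[str, str] = field(default_factory=dict)
    chrom_sizes: str | Mapping[str, int] = ""
    profile_bin_bp: int = 10_000
    hmm_window_bp: int = 5_000
    hmm_step_bp: int = 1_000
    loess_window_bp: int = 200_000
    cap_q: float = 95.0
    hmm_tol: float = 0.05
    min_run: int = 40
    self_transition: float = 0.998
    chromosomes: Sequence[str] | None = None
    normalization_mode: str = "divide"
    seed: int = 0
    outdir: str = "."

    def sizes(self) -> dict[str, int]:
        sizes = (
            dict(self.chrom_sizes)
            if isinstance(self.chrom_sizes, Mapping)
            else read_chrom_sizes(self.chrom_sizes)
        )
        if self.chromosomes:
            missing = set(self.chromosomes) - set(sizes)
            if missing:
                raise ValueError(f"chromosomes not in sizes file: {sorted(missing)}")
            sizes = {c: sizes[c] for c in self.chromosomes}
        return sizes

    def as_flat_dict(self) -> dict[str, str]:
        d = {}
        for f in dataclasses.fields(self):
            if f.name == "outdir":  # output location must not change file content
                continue
            v = getattr(self, f.name)
            if isinstance(v, Mapping):
                v = ",".join(f"{k}:{val}" for k, val in v.items())
            d[f.name] = str(v)
        return d

    def require_fractions(self) -> dict[str, str]:
        missing = [f for f in FRACTIONS if f not in self.fraction_files]
        if missing:
            raise ValueError(f"missing fraction file(s): {missing}")
        return {f: self.fraction_files[f] for f in FRACTIONS}


def run_profile(config: PipelineConfig, write: bool = True) -> TimingProfile:
    """Binning → timing score → loess smoothing → log2 ratio (+ bedGraphs)."""
    reads = config.require_fractions()
    sizes = config.sizes()
    grid = BinGrid(sizes, width=config.profile_bin_bp)
    signal = fraction_signal_from_reads(reads, grid)
    profile = compute_profile(signal)
    profile = smooth_profile(profile, window_bp=config.loess_window_bp)
    profile.log2_ratio = timing_ratio(signal)
    logger.info("profile: %d bins on %d chromosomes", grid.total_bins, len(sizes))
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = provenance_header(config.as_flat_dict(), seed=config.seed)
        frame = grid.to_frame()
        for name, values in (
            ("timing_raw", profile.raw),
            ("timing_smoothed", profile.smoothed),
            ("timing_log2_ratio", profile.log2_ratio),
        ):
            df = frame.copy()
            df["value"] = values
            write_bedgraph(df, outdir / f"{name}.bedgraph", header=header)
    return profile


def run_domains(config: PipelineConfig, sample: str = "sample", write: bool = True) -> DomainSet:
    """Binning (5 kb/1 kb) → chromosome normalization → cap → HMM segmentation."""
    reads = config.require_fractions()
    sizes = config.sizes()
    for chrom in list(sizes):
        if sizes[chrom] < config.hmm_window_bp:
            logger.warning("chromosome %s shorter than one window; skipped", chrom)
            del sizes[chrom]
    grid = BinGrid(sizes, width=config.hmm_window_bp, step=config.hmm_step_bp)
    signal = fraction_signal_from_reads(reads, grid)
    signal = normalize_by_chromosome(signal, mode=config.normalization_mode)
    signal = cap_percentile(signal, q=config.cap_q)
    ratio = timing_ratio(signal)
    domains, models = segment_genome(
        signal,
        ratio,
        seed=config.seed,
        tol=config.hmm_tol,
        min_run=config.min_run,
        self_transition=config.self_transition,
        sample=sample,
    )
    for chrom, model in models.items():
        logger.info(
            "domains: %s chrom=%s iterations=%d dlogL=%.4g",
            sample,
            chrom,
            len(model.loglik_trace),
            model.loglik_trace[-1] - model.loglik_trace[-2]
            if len(model.loglik_trace) > 1
            else float("nan"),
        )
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = provenance_header(config.as_flat_dict(), seed=config.seed)
        write_bed(domains.intervals, outdir / f"domains_{sample}.bed", header=header)
        with open(outdir / f"model_{sample}.json", "w") as fh:
            json.dump(domains.model_params, fh, indent=1)
        with open(outdir / f"training_{sample}.log", "w") as fh:
            for chrom, model in models.items():
                for it, ll in enumerate(model.loglik_trace):
                    fh.write(f"{sample}\t{chrom}\t{it}\t{ll:.6f}\n")
    return domains


def load_domain_set(path: str | Path, sample: str = "") -> DomainSet:
    df = read_bed(path)
    df = df.rename(columns={"name": "label"})
    keep = [c for c in ("chrom", "start", "end", "label", "score") if c in df.columns]
    return DomainSet(intervals=df[keep], sample=sample or Path(path).stem)


def run_compare(
    config: PipelineConfig,
    domain_sets: Sequence[DomainSet],
    write: bool = True,
) -> dict:
    """Static/dynamic classification across samples plus a fraction report."""
    sizes = config.sizes()
    classes = classify_positions(domain_sets, sizes, step=config.hmm_step_bp)
    fractions = genome_fractions(classes)
    report = {
        "samples": [ds.sample for ds in domain_sets],
        "class_fractions": fractions,
        "class_bp": classes.class_bp,
        "total_bp": classes.total_bp,
    }
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = provenance_header(config.as_flat_dict(), seed=config.seed)
        write_bed(classes.intervals, outdir / "replication_classes.bed", header=header)
        with open(outdir / "comparison_report.json", "w") as fh:
            json.dump(report, fh, indent=1)
    return report
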
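"""Read counting and RPKM signal on genomic bin grids.

Two grids are used downstream: nonoverlapping 10-kb bins for the continuous
timing profile and 5-kb windows stepped every 1 kb for the HMM segmentation
input. Reads are assigned to bins by their 5'-most aligned base (strand
aware); on sliding grids a read contributes to every window containing that
position. RPKM normalizes by bin length (kb) and library size (millions of
mapped reads); because RPKM hides per-chromosome coverage differences in
aneuploid lines, signals can additionally be normalized by the mean RPKM
across all fractions per chromosome, and capped at a genome-wide percentile
to suppress spuriously amplified bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import FRACTIONS


@dataclass(frozen=True)
class BinGrid:
    """A genome-wide grid of (possibly overlapping) windows.

    Windows start every ``step`` bp from 0 while the start lies inside the
    chromosome; each extends ``width`` bp, truncated at the chromosome end.
    ``step == width`` gives a nonoverlapping tiling. Coordinates are 0-based
    half-open.
    """

    chrom_sizes: Mapping[str, int]
    width: int
    step: int | None = None

    def __post_init__(self):
        step = self.width if self.step is None else self.step
        object.__setattr__(self, "step", step)
        if self.width <= 0 or not 0 < step <= self.width:
            raise ValueError("need width > 0 and 0 < step <= width")
        if self.width % step != 0:
            raise ValueError("width must be a multiple of step")
        if not self.chrom_sizes or any(l <= 0 for l in self.chrom_sizes.values()):
            raise ValueError("chromosome lengths must be positive")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.step)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chroms)

    def offsets(self) -> dict[str, int]:
        """Start index of each chromosome's bins in the flat genome-wide order."""
        off, pos = {}, 0
        for c in self.chroms:
            off[c] = pos
            pos += self.n_bins(c)
        return off

    def starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom)) * self.step

    def ends(self, chrom: str) -> np.ndarray:
        return np.minimum(self.starts(chrom) + self.width, self.chrom_sizes[chrom])

    def to_frame(self) -> pd.DataFrame:
        parts = [
            pd.DataFrame({"chrom": c, "start": self.starts(c), "end": self.ends(c)})
            for c in self.chroms
        ]
        return pd.concat(parts, ignore_index=True)

    def chrom_slice(self, chrom: str) -> slice:
        off = self.offsets()[chrom]
        return slice(off, off + self.n_bins(chrom))


def _five_prime(df: pd.DataFrame) -> np.ndarray:
    pos = df["start"].to_numpy(copy=True)
    if "strand" in df.columns:
        rev = (df["strand"] == "-").to_numpy()
        pos[rev] = df["end"].to_numpy()[rev] - 1
    return pos


def _load_reads(source) -> pd.DataFrame:
    """Accept a BED-like DataFrame, a BED path, or a BAM path (via pysam)."""
    if isinstance(source, pd.DataFrame):
        return source
    path = Path(source)
    if path.suffix.lower() == ".bam":
        import pysam

        rows = []
        with pysam.AlignmentFile(str(path), "rb") as bam:
            for aln in bam.fetch(until_eof=True):
                if aln.is_unmapped:
                    continue
                rows.append(
                    (
                        aln.reference_name,
                        aln.reference_start,
                        aln.reference_end,
                        "-" if aln.is_reverse else "+",
                    )
                )
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    from .io import read_bed

    return read_bed(path)


def count_reads(reads, grid: BinGrid) -> np.ndarray:
    """Per-window read counts over the whole grid (flat array, grid order).

    A read is placed by its 5'-most aligned base; on sliding grids it is
    counted in every window containing that base. Reads on chromosomes absent
    from the grid are skipped with a warning.
    """
    df = _load_reads(reads)
    counts = np.zeros(grid.total_bins, dtype=np.int64)
    if df.empty:
        return counts
    off = grid.offsets()
    skipped = set(df["chrom"].unique()) - set(grid.chroms)
    if skipped:
        warnings.warn(f"skipping reads on chromosomes absent from grid: {sorted(skipped)}")
    w = grid.width // grid.step
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in off:
            continue
        n = grid.n_bins(chrom)
        pos = _five_prime(sub)
        pos = pos[(pos >= 0) & (pos < grid.chrom_sizes[chrom])]
        elem = np.bincount(pos // grid.step, minlength=n)[:n]
        if w == 1:
            win = elem
        else:
            # window i covers elementary bins i .. i+w-1 (truncated at the end)
            cs = np.concatenate([[0], np.cumsum(elem)])
            hi = np.minimum(np.arange(n) + w, n)
            win = cs[hi] - cs[:n]
        counts[off[chrom] : off[chrom] + n] = win
    return counts


def rpkm(counts: np.ndarray, grid: BinGrid, library_size: int) -> np.ndarray:
    """count / (bin length in kb × library size in millions)."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    lengths = np.concatenate([grid.ends(c) - grid.starts(c) for c in grid.chroms])
    return counts / ((lengths / 1e3) * (library_size / 1e6))


@dataclass
class FractionSignal:
    """Per-bin RPKM for the four S-phase fractions on one grid.

    ``values`` has one row per bin (grid order) and one column per fraction,
    ordered latest → earliest.
    """

    grid: BinGrid
    values: np.ndarray  # (n_bins, 4)
    library_sizes: np.ndarray  # (4,)
    fractions: tuple[str, ...] = FRACTIONS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.total_bins, len(self.fractions)):
            raise ValueError("values shape does not match grid/fractions")
        if not np.all(np.isfinite(self.values)) or (self.values < 0).any():
            raise ValueError("signal values must be finite and >= 0")

    def fraction(self, name: str) -> np.ndarray:
        return self.values[:, self.fractions.index(name)]

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.grid.chrom_slice(chrom)]

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        for i, f in enumerate(self.fractions):
            df[f] = self.values[:, i]
        return df


def fraction_signal_from_reads(
    reads: Mapping[str, "pd.DataFrame | str | Path"],
    grid: BinGrid,
    library_sizes: Mapping[str, int] | None = None,
) -> FractionSignal:
    """Count and RPKM-normalize one read source per fraction.

    Library size defaults to the number of mapped reads in each source.
    """
    missing = [f for f in FRACTIONS if f not in reads]
    if missing:
        raise ValueError(f"missing fraction read sets: {missing}")
    values = np.zeros((grid.total_bins, 4))
    libs = np.zeros(4)
    for i, frac in enumerate(FRACTIONS):
        df = _load_reads(reads[frac])
        counts = count_reads(df, grid)
        lib = library_sizes[frac] if library_sizes else len(df)
        libs[i] = lib
        if lib == 0:
            warnings.warn(f"fraction {frac} has no mapped reads; signal left at zero")
            continue
        values[:, i] = rpkm(counts, grid, lib)
    return FractionSignal(grid=grid, values=values, library_sizes=libs)


def normalize_by_chromosome(signal: FractionSignal, mode: str = "divide") -> FractionSignal:
    """Scale each chromosome by its mean RPKM over all four fractions.

    Division gives each chromosome proportional representation regardless of
    copy number (the aneuploidy correction); ``mode='multiply'`` applies the
    inverse weighting.
    """
    if mode not in ("divide", "multiply"):
        raise ValueError("mode must be 'divide' or 'multiply'")
    values = signal.values.copy()
    for chrom in signal.grid.chroms:
        sl = signal.grid.chrom_slice(chrom)
        mean = values[sl].mean()
        if mean == 0:
            warnings.warn(f"chromosome {chrom} has zero mean RPKM; left unnormalized")
            continue
        values[sl] = values[sl] / mean if mode == "divide" else values[sl] * mean
    return replace(signal, values=values)


def cap_percentile(signal: FractionSignal, q: float = 95.0) -> FractionSignal:
    """Cap each fraction at its genome-wide q-th percentile (linear interpolation)."""
    if not 0 < q < 100:
        raise ValueError("q must be in (0, 100)")
    values = signal.values.copy()
    caps = np.percentile(values, q, axis=0)
    return replace(signal, values=np.minimum(values, caps))
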
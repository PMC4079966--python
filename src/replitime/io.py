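"""Readers and writers for the plain-text genomic formats the pipeline consumes.

All coordinates are 0-based half-open (BED convention). Continuous tracks are
written as bedGraph; every output file carries a provenance header (``#``-prefixed
key=value lines) so that identical configuration and inputs yield byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__

BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file into an ordered dict."""
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        chrom, length = line.split()[:2]
        sizes[chrom] = int(length)
    if not sizes:
        raise ValueError(f"no chromosomes found in {path}")
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{l}\n" for c, l in sizes.items()))


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file; extra columns are named per the BED convention."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        skiprows=_count_track_lines(path),
    )
    ncol = min(df.shape[1], len(BED_COLUMNS))
    df.columns = list(BED_COLUMNS[:ncol]) + [f"col{i}" for i in range(ncol, df.shape[1])]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def _count_track_lines(path: str | Path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            elif not line.startswith("#"):
                break
    return n


def write_bed(df: pd.DataFrame, path: str | Path, header: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header or ():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        skiprows=_count_track_lines(path),
        names=["chrom", "start", "end", "value"],
    )
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path, header: list[str] | None = None) -> None:
    """Write chrom/start/end/value records, dropping rows with missing values."""
    out = df.dropna(subset=["value"])
    with open(path, "w") as fh:
        for line in header or ():
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")


def config_hash(config: Mapping) -> str:
    """Stable short hash of a flat configuration mapping."""
    payload = json.dumps({k: str(v) for k, v in sorted(config.items())}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance_header(config: Mapping, seed: int | None = None) -> list[str]:
    """Provenance lines embedded in every output file.

    Deliberately timestamp-free: rerunning with the same configuration and
    inputs must produce byte-identical files.
    """
    lines = [f"replitime={__version__}", f"config_hash={config_hash(config)}"]
    if seed is not None:
        lines.append(f"seed={seed}")
    lines += [f"{k}={v}" for k, v in sorted(config.items())]
    return lines
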
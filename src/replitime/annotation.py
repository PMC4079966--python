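"""Domain annotation: feature densities and signal enrichment summaries.

Point features (TSS, ORC sites) are counted into domains by their start
position — which keeps counts unambiguous at boundaries and densities
additive — and scaled per 100 kb. Continuous tracks (histone marks,
DNA-binding proteins, expression) are normalized genome-wide (z-score by
default), then summarized per domain by the base-pair-weighted median of the
overlapping track values; matrices of such medians can be compared between
two samples as a log2 difference-ratio layer, or laid out over 10-kb bins
ordered from latest to earliest replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .segmentation import DomainSet
from .timing import TimingProfile


def _region_frame(regions) -> pd.DataFrame:
    if isinstance(regions, DomainSet):
        return regions.intervals
    if isinstance(regions, Mapping):  # chrom sizes → whole chromosomes
        return pd.DataFrame(
            {"chrom": list(regions), "start": 0, "end": list(regions.values())}
        )
    return regions


@dataclass
class FeatureDensityTable:
    """Per-region feature count, length and density per 100 kb."""

    table: pd.DataFrame  # chrom, start, end [, label], count, length_bp, density_per_100kb


def feature_density(features: pd.DataFrame, regions) -> FeatureDensityTable:
    """Count feature start positions per region; density = count / length × 1e5."""
    reg = _region_frame(regions).reset_index(drop=True)
    lengths = (reg["end"] - reg["start"]).to_numpy()
    if (lengths <= 0).any():
        raise ValueError("zero-length region")
    counts = np.zeros(len(reg), dtype=int)
    for chrom, sub in features.groupby("chrom"):
        pos = np.sort(sub["start"].to_numpy())
        mask = reg["chrom"] == chrom
        counts[mask] = np.searchsorted(pos, reg.loc[mask, "end"]) - np.searchsorted(
            pos, reg.loc[mask, "start"]
        )
    out = reg.copy()
    out["count"] = counts
    out["length_bp"] = lengths
    out["density_per_100kb"] = counts / lengths * 1e5
    return FeatureDensityTable(table=out)


def _normalize_track(track: pd.DataFrame, normalization: str) -> pd.DataFrame:
    """Genome-wide per-track normalization, weighted by interval length."""
    t = track.copy()
    v = t["value"].to_numpy(dtype=float)
    w = (t["end"] - t["start"]).to_numpy(dtype=float)
    if normalization == "none":
        return t
    if normalization == "z":
        mean = np.average(v, weights=w)
        var = np.average((v - mean) ** 2, weights=w)
        # a constant track has zero variance; by convention its z-score is 0
        t["value"] = (v - mean) / np.sqrt(var) if var > 0 else np.zeros_like(v)
        return t
    if normalization == "quantile":
        order = np.argsort(v, kind="stable")
        cdf = np.empty_like(v)
        cw = np.cumsum(w[order])
        cdf[order] = (cw - w[order] / 2) / cw[-1]  # bp-weighted mid-rank in [0, 1]
        t["value"] = cdf
        return t
    raise ValueError("normalization must be 'z', 'quantile' or 'none'")


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cutoff = cw[-1] / 2
    return float(v[np.searchsorted(cw, cutoff)])


@dataclass
class EnrichmentMatrix:
    """Rows = tracks, columns = regions (or ordered bins); cells = median values."""

    values: pd.DataFrame
    normalization: dict[str, str] = field(default_factory=dict)
    epsilon: float | None = None


def median_signal(
    track: pd.DataFrame,
    regions,
    normalization: str = "z",
) -> pd.Series:
    """Per-region bp-weighted median of the genome-normalized track.

    Regions with no overlapping track datum are flagged missing (NaN).
    """
    reg = _region_frame(regions).reset_index(drop=True)
    t = _normalize_track(track, normalization)
    out = np.full(len(reg), np.nan)
    for chrom, sub in t.groupby("chrom"):
        ts = sub["start"].to_numpy()
        te = sub["end"].to_numpy()
        tv = sub["value"].to_numpy(dtype=float)
        for i in reg.index[reg["chrom"] == chrom]:
            lo, hi = reg.at[i, "start"], reg.at[i, "end"]
            ov = np.minimum(te, hi) - np.maximum(ts, lo)
            m = ov > 0
            if m.any():
                out[i] = _weighted_median(tv[m], ov[m].astype(float))
    return pd.Series(out, index=reg.index, name="median")


def median_signal_matrix(
    tracks: Mapping[str, pd.DataFrame],
    regions,
    normalization: str = "z",
) -> EnrichmentMatrix:
    """One median_signal row per track over a shared set of regions."""
    reg = _region_frame(regions).reset_index(drop=True)
    rows = {name: median_signal(tr, reg, normalization) for name, tr in tracks.items()}
    values = pd.DataFrame(rows).T
    values.columns = [f"{c}:{s}-{e}" for c, s, e in zip(reg["chrom"], reg["start"], reg["end"])]
    return EnrichmentMatrix(values=values, normalization={n: normalization for n in tracks})


def difference_ratio(
    matrix_a: EnrichmentMatrix, matrix_b: EnrichmentMatrix, epsilon: float = 1e-6
) -> EnrichmentMatrix:
    """Elementwise log2((a + ε)/(b + ε)) between two matching matrices."""
    a, b = matrix_a.values, matrix_b.values
    if a.shape != b.shape or list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        raise ValueError("matrices do not share rows and regions")
    layer = np.log2((a + epsilon) / (b + epsilon))
    return EnrichmentMatrix(values=layer, normalization=dict(matrix_a.normalization), epsilon=epsilon)


def order_bins_by_timing(
    profile: TimingProfile,
    tracks: Mapping[str, pd.DataFrame],
    normalization: str = "z",
) -> EnrichmentMatrix:
    """Per-track normalized value over 10-kb bins sorted latest → earliest.

    Bins are ordered ascending by timing score, ties broken by (chromosome,
    start); each cell is the bp-weighted mean of the normalized track over
    the bin. Unscored bins are dropped. The timing score itself is included
    as the first row.
    """
    bins = profile.grid.to_frame()
    bins["timing"] = profile.best_score()
    bins = bins[np.isfinite(bins["timing"])]
    bins = bins.sort_values(["timing", "chrom", "start"], kind="stable").reset_index(drop=True)
    data = {"timing": bins["timing"].to_numpy()}
    for name, tr in tracks.items():
        t = _normalize_track(tr, normalization)
        vals = np.full(len(bins), np.nan)
        for chrom, sub in t.groupby("chrom"):
            ts, te = sub["start"].to_numpy(), sub["end"].to_numpy()
            tv = sub["value"].to_numpy(dtype=float)
            for i in bins.index[bins["chrom"] == chrom]:
                lo, hi = bins.at[i, "start"], bins.at[i, "end"]
                ov = (np.minimum(te, hi) - np.maximum(ts, lo)).clip(min=0)
                if ov.sum() > 0:
                    vals[i] = float(np.average(tv, weights=ov))
        data[name] = vals
    values = pd.DataFrame(data).T
    values.columns = [f"{c}:{s}-{e}" for c, s, e in zip(bins["chrom"], bins["start"], bins["end"])]
    return EnrichmentMatrix(values=values, normalization={n: normalization for n in tracks})
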
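"""Continuous replication-timing score and its smoothing.

Each 10-kb bin gets the weighted average score

    s = (w · x) / Σ x,   w = (0.125, 0.375, 0.625, 0.875)

where x is the bin's RPKM over the four S-phase fractions ordered latest →
earliest. The weights are the midpoints of each fraction's nominal S-phase
quarter, so a bin whose reads all come from the earliest fraction scores
0.875 and one supported only by the latest fraction scores 0.125; high values
mean early replication. The score is undefined (NaN) where all four fractions
are zero. To suppress bins with spurious amplification or negligible
coverage, the score is smoothed chromosome-wise over a ~200-kb window by
local polynomial regression (tricube weights, degree 2), which also imputes
missing bins where regression support exists.

The log2 early/late ratio uses only the earliest and latest fractions, with a
pseudocount to keep it finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinGrid, FractionSignal

#: S-phase quarter midpoints, latest fraction first — high score = early replication
TIMING_WEIGHTS = np.array([0.125, 0.375, 0.625, 0.875])

SCORE_MIN, SCORE_MAX = 0.125, 0.875


def weighted_timing_score(x: np.ndarray, weights: np.ndarray = TIMING_WEIGHTS) -> np.ndarray:
    """(w · x) / Σx per bin; NaN where the bin has no reads in any fraction.

    Invariant to rescaling x by any positive constant, and bounded by the
    smallest and largest weight.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("fraction signal must be non-negative")
    total = x.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = (x @ weights) / total
    return np.where(total > 0, score, np.nan)


def loess(
    x: np.ndarray,
    y: np.ndarray,
    eval_x: np.ndarray,
    k: int,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial regression with tricube weights over the k nearest points.

    Plain loess: for each evaluation point, fit a weighted polynomial to the k
    nearest observations (tricube weight on distance scaled by the furthest
    neighbour) and evaluate it there. Observations with NaN response are
    ignored, so evaluation points inside gaps are imputed from the fit.
    """
    mask = np.isfinite(y)
    xo, yo = np.asarray(x, float)[mask], np.asarray(y, float)[mask]
    if xo.size == 0:
        return np.full(len(eval_x), np.nan)
    k = min(k, xo.size)
    out = np.empty(len(eval_x))
    order = np.argsort(xo, kind="stable")
    xo, yo = xo[order], yo[order]
    for i, x0 in enumerate(np.asarray(eval_x, float)):
        d = np.abs(xo - x0)
        nn = np.argpartition(d, k - 1)[:k]
        dn, xn, yn = d[nn], xo[nn], yo[nn]
        dmax = dn.max()
        if dmax == 0:
            out[i] = yn.mean()
            continue
        w = (1 - (dn / dmax) ** 3) ** 3
        deg = min(degree, len(np.unique(xn)) - 1)
        # centre for conditioning; weighted LSQ via sqrt-weight trick
        coef = np.polyfit(xn - x0, yn, deg, w=np.sqrt(np.maximum(w, 1e-12)))
        out[i] = coef[-1]
    return out


@dataclass
class TimingProfile:
    """Raw and smoothed timing score plus log2 early/late ratio on a 10-kb grid."""

    grid: BinGrid
    raw: np.ndarray
    smoothed: np.ndarray | None = None
    log2_ratio: np.ndarray | None = None

    def chrom_raw(self, chrom: str) -> np.ndarray:
        return self.raw[self.grid.chrom_slice(chrom)]

    def chrom_smoothed(self, chrom: str) -> np.ndarray:
        if self.smoothed is None:
            raise ValueError("profile has not been smoothed")
        return self.smoothed[self.grid.chrom_slice(chrom)]

    def best_score(self) -> np.ndarray:
        return self.raw if self.smoothed is None else self.smoothed

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["raw"] = self.raw
        if self.smoothed is not None:
            df["smoothed"] = self.smoothed
        if self.log2_ratio is not None:
            df["log2_ratio"] = self.log2_ratio
        return df


def compute_profile(signal: FractionSignal) -> TimingProfile:
    """Raw weighted timing score from a four-fraction RPKM signal."""
    return TimingProfile(grid=signal.grid, raw=weighted_timing_score(signal.values))


def smooth_profile(
    profile: TimingProfile, window_bp: int = 200_000, clip: bool = True
) -> TimingProfile:
    """Chromosome-wise loess of the raw score over a physical window.

    The neighbourhood holds ``window_bp / bin_width`` bins (minimum 4); missing
    bins are imputed from the local fit. Smoothed values are clipped to the
    theoretical score range unless ``clip=False``. Chromosomes with fewer than
    4 scored bins are passed through unsmoothed with a warning.
    """
    grid = profile.grid
    k = max(4, round(window_bp / grid.width))
    smoothed = np.full_like(profile.raw, np.nan)
    for chrom in grid.chroms:
        sl = grid.chrom_slice(chrom)
        raw = profile.raw[sl]
        mid = (grid.starts(chrom) + grid.ends(chrom)) / 2
        n_ok = int(np.isfinite(raw).sum())
        if n_ok == 0:
            continue
        if n_ok < 4:
            warnings.warn(f"chromosome {chrom}: only {n_ok} scored bins; not smoothed")
            smoothed[sl] = raw
            continue
        smoothed[sl] = loess(mid, raw, mid, k=k, degree=2)
    if clip:
        smoothed = np.clip(smoothed, SCORE_MIN, SCORE_MAX)
    return TimingProfile(
        grid=grid, raw=profile.raw, smoothed=smoothed, log2_ratio=profile.log2_ratio
    )


def default_pseudocount(signal: FractionSignal) -> float:
    """5th percentile of nonzero RPKM over the earliest and latest fractions."""
    el = np.stack([signal.fraction("early"), signal.fraction("late")])
    nz = el[el > 0]
    return float(np.percentile(nz, 5)) if nz.size else 1.0


def timing_ratio(signal: FractionSignal, pseudocount: float | None = None) -> np.ndarray:
    """log2((early + c) / (late + c)) per bin, earliest and latest fractions only."""
    if pseudocount is None:
        pseudocount = default_pseudocount(signal)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    early, late = signal.fraction("early"), signal.fraction("late")
    return np.log2((early + pseudocount) / (late + pseudocount))
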
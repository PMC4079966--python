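"""Cross-cell-line domain comparison and per-chromosome timing summaries.

Positions (on a 1-kb grid) that are called early in every cell line are
static early; late in every line, static late; early in at least one line
and late in at least one other, dynamic. Everything else — an indeterminate
call without an early/late conflict, or no call at all — is indeterminate.
Class fractions are reported over the whole assembly grid so they sum to 1.

The per-chromosome summary compares the distribution of 10-kb timing values
of a target chromosome (e.g. the X) against the pooled remaining chromosomes
with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .segmentation import DomainSet
from .timing import TimingProfile

CLASS_NAMES = ("static_early", "static_late", "dynamic", "indeterminate")

_CODE = {"none": 0, "early": 1, "late": 2, "indeterminate": 3}


@dataclass
class CrossSampleClasses:
    """Per-position replication class across samples, plus merged intervals."""

    intervals: pd.DataFrame  # chrom, start, end, class
    class_bp: dict[str, int]
    total_bp: int

    def fractions(self) -> dict[str, float]:
        return {c: self.class_bp.get(c, 0) / self.total_bp for c in CLASS_NAMES}


def classify_positions(
    domain_sets: Sequence[DomainSet],
    chrom_sizes: Mapping[str, int],
    step: int = 1000,
) -> CrossSampleClasses:
    """Apply the static/dynamic rule at every grid position and merge runs."""
    if len(domain_sets) < 2:
        raise ValueError("need at least two samples")
    chrom_lists = [frozenset(ds.intervals["chrom"].unique()) for ds in domain_sets]
    if len(set(chrom_lists)) > 1:
        detail = " vs ".join(str(sorted(c)) for c in set(chrom_lists))
        raise ValueError(f"samples cover mismatched chromosome sets: {detail}")
    rows = []
    class_bp = {c: 0 for c in CLASS_NAMES}
    total_bp = 0
    for chrom, length in chrom_sizes.items():
        positions = np.arange(0, length, step)
        widths = np.minimum(positions + step, length) - positions
        total_bp += int(widths.sum())
        codes = np.stack(
            [
                np.vectorize(_CODE.get, otypes=[int])(ds.label_at(chrom, positions))
                for ds in domain_sets
            ]
        )
        any_early = (codes == 1).any(axis=0)
        any_late = (codes == 2).any(axis=0)
        all_early = (codes == 1).all(axis=0)
        all_late = (codes == 2).all(axis=0)
        cls = np.full(len(positions), "indeterminate", dtype=object)
        cls[all_early] = "static_early"
        cls[all_late] = "static_late"
        cls[any_early & any_late] = "dynamic"
        for name in CLASS_NAMES:
            class_bp[name] += int(widths[cls == name].sum())
        # merge contiguous same-class positions
        change = np.flatnonzero(cls[1:] != cls[:-1]) + 1
        bounds = np.concatenate([[0], change, [len(positions)]])
        for i in range(len(bounds) - 1):
            lo, hi = bounds[i], bounds[i + 1] - 1
            rows.append(
                (chrom, int(positions[lo]), int(positions[hi] + widths[hi]), cls[lo])
            )
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "class"])
    return CrossSampleClasses(intervals=intervals, class_bp=class_bp, total_bp=total_bp)


def genome_fractions(classes: CrossSampleClasses) -> dict[str, float]:
    """Per-class fraction of the assembly; sums to 1 exactly over the grid."""
    return classes.fractions()


@dataclass
class ChromosomeTimingSummary:
    """Five-number summaries per chromosome plus a target-vs-background rank test."""

    summaries: pd.DataFrame  # chrom, n, min, q1, median, q3, max
    target: str
    statistic: float
    pvalue: float


def chromosome_timing_summary(
    profile: TimingProfile,
    target: str,
    background: Sequence[str] | None = None,
) -> ChromosomeTimingSummary:
    """Compare one chromosome's 10-kb timing values against pooled others.

    Uses the smoothed score when available, raw otherwise; missing bins are
    dropped. The test is a two-sided Mann-Whitney U.
    """
    score = profile.best_score()
    grid = profile.grid
    if background is None:
        background = [c for c in grid.chroms if c != target]
    rows = []
    for chrom in grid.chroms:
        v = score[grid.chrom_slice(chrom)]
        v = v[np.isfinite(v)]
        if v.size:
            q = np.percentile(v, [0, 25, 50, 75, 100])
            rows.append((chrom, v.size, *q))
    summaries = pd.DataFrame(
        rows, columns=["chrom", "n", "min", "q1", "median", "q3", "max"]
    )
    tv = score[grid.chrom_slice(target)]
    tv = tv[np.isfinite(tv)]
    bv = np.concatenate(
        [score[grid.chrom_slice(c)] for c in background]
    ) if background else np.empty(0)
    bv = bv[np.isfinite(bv)]
    if tv.size == 0 or bv.size == 0:
        raise ValueError("target or background has no scored bins")
    stat, p = mannwhitneyu(tv, bv, alternative="two-sided")
    return ChromosomeTimingSummary(
        summaries=summaries, target=target, statistic=float(stat), pvalue=float(p)
    )
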
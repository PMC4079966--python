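import numpy as np
import pytest

import replitime as rt


@pytest.fixture(scope="session")
def small_config():
    """A 4-Mb two-chromosome study: fast enough for per-module tests."""
    return rt.SimulationConfig(
        chrom_sizes={"chrA": 2_000_000, "chrB": 2_000_000}, seed=11
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return rt.simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_reads(small_truth, small_config):
    return rt.simulate_fraction_reads(small_truth, small_config)


@pytest.fixture(scope="session")
def default_config():
    """The study conditions: 20-Mb genome, 100-500-kb domains, 100 reads/bin."""
    return rt.SimulationConfig(seed=23)


@pytest.fixture(scope="session")
def default_truth(default_config):
    return rt.simulate_genome(default_config)


@pytest.fixture(scope="session")
def default_reads(default_truth, default_config):
    return rt.simulate_fraction_reads(default_truth, default_config)


@pytest.fixture(scope="session")
def default_segmentation(default_reads, default_config):
    """HMM input signal, segmentation and models for the default study."""
    grid = rt.BinGrid(default_config.chrom_sizes, width=5_000, step=1_000)
    signal = rt.fraction_signal_from_reads(default_reads, grid)
    signal = rt.normalize_by_chromosome(signal)
    signal = rt.cap_percentile(signal, 95)
    ratio = rt.timing_ratio(signal)
    domains, models = rt.segment_genome(signal, ratio, seed=default_config.seed)
    return signal, domains, models


def label_accuracy(domains: rt.DomainSet, truth: rt.SyntheticTruth, step=1000):
    """Fraction of grid positions whose called label matches the planted label."""
    hits = total = 0
    for chrom, length in truth.chrom_sizes.items():
        pos = np.arange(0, length, step)
        hits += (domains.label_at(chrom, pos) == truth.true_label(chrom, pos)).sum()
        total += len(pos)
    return hits / total


def boundary_errors(domains: rt.DomainSet, truth: rt.SyntheticTruth):
    """Distance from each interior planted boundary to the nearest called one."""
    errs = []
    iv = domains.intervals
    for chrom in truth.chrom_sizes:
        tb = truth.domains[truth.domains["chrom"] == chrom]["start"].to_numpy()[1:]
        sub = iv[(iv["chrom"] == chrom) & (iv["label"] != "indeterminate")]
        if len(sub) < 2:
            continue
        cb = np.unique(np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy()]))[1:-1]
        if cb.size == 0:
            continue
        errs.extend(np.abs(cb - b).min() for b in tb)
    return np.asarray(errs)
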
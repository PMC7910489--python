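import numpy as np
import pytest

from hicwaves import LibraryInfo, SimConfig, simulate_experiment
from hicwaves.simulate import SpikeSpec


@pytest.fixture(scope="session")
def small_config():
    """A compact two-chromosome study used by several integration tests."""
    return SimConfig(
        chrom_sizes={"chr1": 10_000_000, "chr2": 10_000_000},
        mean_depth=1_000_000,
        max_span=2_000_000,
        n_genes=60,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture
def libraries_2x2():
    return [
        LibraryInfo("a_r1", "a", 1, 1_000_000),
        LibraryInfo("a_r2", "a", 2, 1_000_000),
        LibraryInfo("b_r1", "b", 1, 1_000_000),
        LibraryInfo("b_r2", "b", 2, 1_000_000),
    ]


def make_promoter_spikes(n_genes, n_spiked, transition, fold=3.0, couple=False):
    """Evenly spread promoter spikes, alternating up/down."""
    step = max(1, n_genes // n_spiked)
    return [
        SpikeSpec(
            "promoter", f"g{(i * step) % n_genes:04d}", transition,
            1 if i % 2 else -1, fold, couple_expression=couple,
        )
        for i in range(n_spiked)
    ]
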
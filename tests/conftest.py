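import numpy as np
import pandas as pd
import pytest

from accesspanel import blood, scoring, simulate
from accesspanel.intervals import Peak, PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_peakset(rng, n, n_chroms=2, max_pos=1000, width_range=(20, 120)):
    rows = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, max_pos))
        width = int(rng.integers(*width_range))
        rows.append(Peak(chrom, start, start + width, f"p{i}",
                         float(rng.uniform(0.5, 100.0))))
    return PeakSet.from_peaks(rows)


@pytest.fixture
def small_sim_config():
    """Fast simulation config for unit tests."""
    return simulate.SimulationConfig(n_regions=400, samples_per_type=8,
                                     blood_samples_per_celltype=4, seed=7)


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale simulation shared across tests (expensive)."""
    config = simulate.SimulationConfig(seed=11)
    regions, matrix, truth = simulate.simulate_atac(config)
    return config, regions, matrix, truth


def blood_weighted_mean_of(matrix):
    cpm = scoring.cpm_normalize(matrix)
    return blood.weighted_blood_mean(cpm.select_label("pbmc").counts,
                                     cpm.select_label("neutrophil").counts)
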
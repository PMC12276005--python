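import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

import tagbench as tb

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_layout() -> tb.GenomeLayout:
    """2 x 1 Mb toy genome with a small blacklist, for fast unit tests."""
    return tb.default_layout(n_chroms=2, chrom_length=1_000_000)


@pytest.fixture(scope="session")
def small_sites(small_layout):
    cfg = tb.SimulationConfig(n_accessible=60, seed=11)
    _, sites = tb.simulate_genome(cfg, layout=small_layout)
    return sites


@pytest.fixture(scope="session")
def small_library(small_layout, small_sites) -> tb.FragmentLibrary:
    cfg = tb.SimulationConfig(
        n_accessible=60, n_unique_molecules=5000, seed=11
    )
    return tb.simulate_library(small_layout, small_sites, cfg, library_id="unit")


def random_intervals(rng, n, chrom_len=10_000, chroms=("chr1", "chr2"), max_w=400):
    """Random (possibly overlapping) interval records on a toy genome."""
    rows = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        w = int(rng.integers(1, max_w))
        s = int(rng.integers(0, chrom_len - w))
        rows.append((chrom, s, s + w))
    return rows


@pytest.fixture
def rng():
    return np.random.default_rng(202_406)
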
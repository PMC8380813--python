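import numpy as np
import pytest

from nicscall.cnv import CopyNumberCaller, default_reference_panel
from nicscall.genome import build_bin_grid

SMALL_LENGTHS = {
    "1": 60_000_000,
    "2": 50_000_000,
    "16": 45_000_000,
    "X": 40_000_000,
    "Y": 20_000_000,
}


@pytest.fixture(scope="session")
def hg19_grid():
    return build_bin_grid()


@pytest.fixture(scope="session")
def small_grid():
    """A miniature genome for fast unit tests (175 bins)."""
    return build_bin_grid(SMALL_LENGTHS)


@pytest.fixture(scope="session")
def flat_small_grid():
    """Same miniature genome with constant GC (no amplification bias)."""
    grid = build_bin_grid(SMALL_LENGTHS)
    return grid.with_gc(np.full(grid.n_bins, 0.42))


@pytest.fixture(scope="session")
def small_caller(small_grid):
    caller = CopyNumberCaller(random_state=11)
    caller.fit(default_reference_panel(small_grid))
    return caller


@pytest.fixture(scope="session")
def flat_small_caller(flat_small_grid):
    caller = CopyNumberCaller(random_state=11)
    caller.fit(default_reference_panel(flat_small_grid))
    return caller
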
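"""Shared fixtures: one standard crystal form and two session-scoped
simulated collections (an outlier-selection benchmark and a clean
parameter-recovery collection), so expensive scaling runs happen once."""

from __future__ import annotations

import numpy as np
import pytest

import ssxmerge as sx
from ssxmerge.selection import run_selection
from ssxmerge.symmetry import UnitCell, space_group

BENCH_SEED = 7
RECOVERY_SEED = 11
D_MIN = 2.6
WILSON_B = 73.6
SCALE_C = 2000.0


@pytest.fixture(scope="session")
def c2221():
    return space_group("C2221")


@pytest.fixture(scope="session")
def std_cell():
    # orthorhombic C-centred form giving ~5,000 unique reflections at 2.6 A
    return UnitCell(52.0, 60.0, 108.0)


@pytest.fixture(scope="session")
def truth(std_cell, c2221):
    return sx.make_ground_truth(
        std_cell, c2221, D_MIN, scale_C=SCALE_C, wilson_B=WILSON_B,
        seed=BENCH_SEED,
    )


@pytest.fixture(scope="session")
def benchmark(truth):
    """20 good / 5 low-ISa / 3 mis-indexed planted-outlier benchmark."""
    return sx.make_benchmark_collection(truth, 20, 5, 3, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def benchmark_selection(benchmark, std_cell, c2221):
    return run_selection(list(benchmark.datasets), std_cell, c2221)


@pytest.fixture(scope="session")
def recovery(std_cell, c2221):
    """30 clean datasets for K / B / ISa / Wilson-B parameter recovery."""
    truth = sx.make_ground_truth(
        std_cell, c2221, D_MIN, scale_C=SCALE_C, wilson_B=WILSON_B,
        seed=RECOVERY_SEED,
    )
    coll = sx.make_benchmark_collection(truth, 30, 0, 0, seed=RECOVERY_SEED)
    return coll


@pytest.fixture(scope="session")
def recovery_selection(recovery, std_cell, c2221):
    return run_selection(list(recovery.datasets), std_cell, c2221)


@pytest.fixture(scope="session")
def small_collection(c2221):
    """Cheap 6-dataset collection at 3.2 A for fast pipeline tests."""
    cell = UnitCell(52.0, 60.0, 108.0)
    truth = sx.make_ground_truth(cell, c2221, 3.2, scale_C=SCALE_C,
                                 wilson_B=WILSON_B, seed=5)
    return sx.make_benchmark_collection(truth, 4, 1, 1, seed=5)
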
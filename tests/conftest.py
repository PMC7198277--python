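import numpy as np
import pandas as pd
import pytest

from replitime import (
    CoverageTable,
    GenomeDefinition,
    RTProgram,
    SimulationConfig,
    WindowGrid,
    make_windows,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_genome():
    return GenomeDefinition(
        (("chr1", 300_000), ("chr2", 100_000), ("chrX", 99_999)),
        {"pericentric": [("chr1", 0, 50_000)]},
    )


@pytest.fixture(scope="session")
def two_domain_genome():
    """2 Mb chromosome: earliest-replicating left half, latest right half."""
    return GenomeDefinition((("chr1", 2_000_000),))


@pytest.fixture(scope="session")
def two_domain_reads(two_domain_genome):
    program = RTProgram(
        "wt",
        (("chr1", 0, 1_000_000, 0.0), ("chr1", 1_000_000, 2_000_000, 1.0)),
    )
    config = SimulationConfig(library_size=600_000, replicates=2, noise_sd=0.0, seed=11)
    return simulate_reads(two_domain_genome, program, config)


def coverage_from_counts(grid: WindowGrid, columns: dict, meta_rows: list) -> CoverageTable:
    """Build a CoverageTable directly from count columns (test helper).

    ``meta_rows``: list of (sample, condition, phase, replicate, retained).
    """
    counts = pd.DataFrame({k: np.asarray(v) for k, v in columns.items()})
    meta = pd.DataFrame(
        [
            {"sample": s, "condition": c, "phase": p, "replicate": r, "retained": t,
             "skipped": 0}
            for s, c, p, r, t in meta_rows
        ]
    ).set_index("sample")
    return CoverageTable(grid, counts, meta)


@pytest.fixture
def uniform_grid(small_genome):
    return make_windows(small_genome, 100_000, 10_000)
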
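"""Shared fixtures.

The "benchmark" fixtures are session-scoped because several acceptance
criteria reuse the same synthetic dataset (seed 42; 200 proteins of length
100-400; 200 non-decoy reads of 150 bp; substitution rate 0.05; no indels)
and the same default-parameter search run.
"""

from __future__ import annotations

import numpy as np
import pytest

from txsearch.db_index import IndexParams, chunk_database
from txsearch.extend_ungapped import ScoringParams
from txsearch.scheduler import SearchConfig, run_search
from txsearch.seeding_filter import SearchStats
from txsearch.testkit import SimConfig, best_subject_by_sw, simulate

BENCHMARK_CONFIG = SimConfig(
    seed=42,
    n_proteins=200,
    protein_len_range=(100, 400),
    n_reads=200,
    read_length=150,
    substitution_rate=0.05,
    indel_rate=0.0,
    decoy_fraction=0.0,
)


@pytest.fixture(scope="session")
def scoring() -> ScoringParams:
    return ScoringParams()


@pytest.fixture(scope="session")
def benchmark_data():
    return simulate(BENCHMARK_CONFIG)


@pytest.fixture(scope="session")
def benchmark_chunks(benchmark_data):
    return chunk_database(benchmark_data.proteins, params=IndexParams())


@pytest.fixture(scope="session")
def benchmark_run(benchmark_data, benchmark_chunks):
    """Default-parameter search of the benchmark; returns (hits, stats)."""
    stats = SearchStats()
    hits = run_search(benchmark_data.reads, benchmark_chunks, SearchConfig(), stats=stats)
    return hits, stats


@pytest.fixture(scope="session")
def benchmark_oracle(benchmark_data):
    """Smith-Waterman best subject per read (the sensitivity reference)."""
    return best_subject_by_sw(benchmark_data.reads, benchmark_data.proteins)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
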
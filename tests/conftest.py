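"""Shared fixtures: seeded pangenomes, their graphs/indexes, and read sets.

The two pangenome scales are built once per session: a small 8-reference
toy (seed 11, k=15) for oracle-equivalence batteries and a larger
50-reference collection (seed 42, k=31) exercising the full density
spectrum of colors.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ccdbg import (ColorIndex, FixtureSpec, ReferenceCollection, build_ccdbg,
                   extract_kmer_colors, generate_pangenome, simulate_reads)


@pytest.fixture(scope="session")
def seed11_refs():
    refs, _ = generate_pangenome(FixtureSpec(n_refs=8, length=500, seed=11))
    return refs


@pytest.fixture(scope="session")
def seed11_graph(seed11_refs):
    return build_ccdbg(ReferenceCollection(seed11_refs, k=15))


@pytest.fixture(scope="session")
def seed11_index(seed11_graph, seed11_refs):
    return ColorIndex.from_ccdbg(seed11_graph, [n for n, _ in seed11_refs], w=7)


@pytest.fixture(scope="session")
def seed11_colors(seed11_refs):
    return extract_kmer_colors(ReferenceCollection(seed11_refs, k=15))


@pytest.fixture(scope="session")
def seed11_reads(seed11_refs, seed11_colors):
    reads, truth = simulate_reads(
        seed11_refs, set(seed11_colors), k=15, read_length=150,
        n_reads=1000, positive_fraction=0.75, error_rate=0.01, seed=5)
    return reads, truth


@pytest.fixture(scope="session")
def seed42_refs():
    refs, _ = generate_pangenome(FixtureSpec(seed=42))  # N=50, L=20000
    return refs


@pytest.fixture(scope="session")
def seed42_graph(seed42_refs):
    return build_ccdbg(ReferenceCollection(seed42_refs, k=31))


@pytest.fixture(scope="session")
def seed42_index(seed42_graph, seed42_refs):
    return ColorIndex.from_ccdbg(seed42_graph, [n for n, _ in seed42_refs], w=15)
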
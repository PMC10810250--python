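"""K-mer dictionary: exact lookup, streaming cache, oracle batteries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccdbg import ReferenceCollection, build_ccdbg, build_dictionary, revcomp

import oracles


@pytest.fixture(scope="module")
def toy():
    g = build_ccdbg(ReferenceCollection([("a", "AACCG")], k=3))
    return g, build_dictionary(g, w=2)


def test_single_unitig_offsets(toy):
    g, d = toy
    u = g.unitigs[0].sequence
    for off in range(3):
        hit = d.lookup(u[off:off + 3])
        assert (hit.unitig_id, hit.offset, hit.forward) == (1, off, True)


def test_absent_kmer_returns_bottom(toy):
    _, d = toy
    assert d.lookup("AAA") is None


def test_reverse_complement_same_site_flipped_orientation(toy):
    g, d = toy
    u = g.unitigs[0].sequence
    fwd = d.lookup(u[1:4])
    rev = d.lookup(revcomp(u[1:4]))
    assert (rev.unitig_id, rev.offset) == (fwd.unitig_id, fwd.offset)
    assert rev.forward != fwd.forward


def test_wrong_length_query_rejected(toy):
    _, d = toy
    with pytest.raises(ValueError):
        d.lookup("ACGT")


def test_w_geq_k_rejected(toy):
    g, _ = toy
    with pytest.raises(ValueError):
        build_dictionary(g, w=3)


def exhaustive_map(graph):
    """Oracle: every (canonical k-mer) -> (unitig id, offset) by direct scan."""
    out = {}
    for u in graph.unitigs:
        for off in range(len(u.sequence) - graph.k + 1):
            out[oracles.canon(u.sequence[off:off + graph.k])] = (u.id, off)
    return out


def test_lookup_battery_against_exhaustive_map(seed11_graph, seed11_index):
    d = seed11_index.dictionary
    truth = exhaustive_map(seed11_graph)
    keys = sorted(truth)
    rng = np.random.default_rng(101)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    hits = misses = 0
    for _ in range(10000):
        x = keys[rng.integers(0, len(keys))]
        hit = d.lookup(x)
        assert (hit.unitig_id, hit.offset) == truth[x]
        # orientation contract: the site re-spells the query as reported
        us = int(d.starts[hit.unitig_id - 1])
        site = d.blob[us + hit.offset:us + hit.offset + d.k]
        assert site == (x if hit.forward else oracles.rc(x))
        hits += 1
    for _ in range(10000):
        x = bases[rng.integers(0, 4, size=15)].tobytes().decode()
        expected = truth.get(oracles.canon(x))
        hit = d.lookup(x)
        if expected is None:
            assert hit is None
            misses += 1
        else:
            assert (hit.unitig_id, hit.offset) == expected
    assert hits == 10000 and misses > 0


def test_every_hit_respells_the_query(seed11_index):
    d = seed11_index.dictionary
    rng = np.random.default_rng(7)
    starts = d.starts
    for _ in range(500):
        ui = int(rng.integers(0, d.m))
        us, ue = int(starts[ui]), int(starts[ui + 1])
        off = int(rng.integers(0, ue - us - d.k + 1))
        x = d.blob[us + off:us + off + d.k]
        hit = d.lookup(x)
        site = d.blob[int(starts[hit.unitig_id - 1]) + hit.offset:
                      int(starts[hit.unitig_id - 1]) + hit.offset + d.k]
        assert site == x if hit.forward else site == revcomp(x)


def test_streaming_full_unitig_all_cache_hits(seed11_graph, seed11_index):
    d = seed11_index.dictionary
    u = max(seed11_graph.unitigs, key=lambda u: len(u.sequence))
    hits, cache_hits = d.streaming_lookup(u.sequence)
    assert all(h is not None and h.unitig_id == u.id for h in hits)
    assert [h.offset for h in hits] == list(range(len(u.sequence) - d.k + 1))
    assert cache_hits == len(u.sequence) - d.k


def test_streaming_all_absent(seed11_index):
    d = seed11_index.dictionary
    q = "A" * 60  # homopolymer absent from the fixture
    if d.lookup(q[:15]) is None:
        hits, _ = d.streaming_lookup(q)
        assert all(h is None for h in hits)


def test_streaming_too_short(seed11_index):
    hits, cache_hits = seed11_index.dictionary.streaming_lookup("ACGT")
    assert hits == [] and cache_hits == 0


def test_streaming_equals_batch_on_simulated_reads(seed11_index, seed11_reads):
    d = seed11_index.dictionary
    reads, _ = seed11_reads
    for name, seq in reads:
        streamed, _ = d.streaming_lookup(seq)
        independent = [d.lookup(seq[i:i + d.k])
                       for i in range(len(seq) - d.k + 1)]
        assert streamed == independent


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.text(alphabet="ACGT", min_size=15, max_size=80))
def test_streaming_equals_batch_property(seed11_index, seq):
    d = seed11_index.dictionary
    streamed, _ = d.streaming_lookup(seq)
    assert streamed == [d.lookup(seq[i:i + d.k])
                        for i in range(len(seq) - d.k + 1)]
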
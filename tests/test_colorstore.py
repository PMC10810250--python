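"""Hybrid color codec, Elias-Fano directory, and color iterators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccdbg import ColorStore, EliasFano, decode_color, encode_color
from ccdbg.colorstore import classify, TAG_BITVECTOR, TAG_DENSE, TAG_SPARSE

import oracles


def random_color(rng, N):
    size = int(rng.integers(1, N + 1))
    return sorted(int(v) for v in
                  rng.choice(np.arange(1, N + 1), size=size, replace=False))


# -- density routing ----------------------------------------------------

def test_density_thresholds():
    N = 100
    assert classify(10, N) == TAG_SPARSE  # 10/100 < 1/4
    assert classify(80, N) == TAG_DENSE  # 80/100 > 3/4
    assert classify(50, N) == TAG_BITVECTOR
    # exact boundaries fall to the bitvector representation
    assert classify(25, N) == TAG_BITVECTOR
    assert classify(75, N) == TAG_BITVECTOR


def test_full_color_has_empty_complement_payload():
    for N in (2, 10, 57):
        tag, bits = encode_color(list(range(1, N + 1)), N)
        assert tag == "dense-complement"
        # only the count header remains after the tag: delta(0 + 1) = "1"
        assert bits == "1"
        assert decode_color(tag, bits, N) == list(range(1, N + 1))


def test_invalid_colors_rejected():
    with pytest.raises(ValueError):
        encode_color([], 10)
    with pytest.raises(ValueError):
        encode_color([3, 2], 10)
    with pytest.raises(ValueError):
        encode_color([1, 11], 10)


def test_round_trip_and_code_length_all_densities():
    rng = np.random.default_rng(13)
    for trial in range(1000):
        N = int(rng.integers(2, 120))
        C = random_color(rng, N)
        tag, bits = encode_color(C, N)
        assert decode_color(tag, bits, N) == C
        assert len(bits) == oracles.hybrid_payload_length(C, N)


def test_round_trip_at_exact_density_boundaries():
    N = 100
    for size in (25, 75):
        C = list(range(1, size + 1))
        tag, bits = encode_color(C, N)
        assert tag == "bitvector"
        assert decode_color(tag, bits, N) == C


# -- Elias-Fano ----------------------------------------------------------

def test_elias_fano_trivial_and_identity():
    ef = EliasFano([0], 1)
    assert ef.access(1) == 0
    q = 37
    ef = EliasFano(list(range(q)), q)
    assert [ef.access(j) for j in range(1, q + 1)] == list(range(q))


def test_elias_fano_rejects_unsorted():
    with pytest.raises(ValueError):
        EliasFano([3, 3, 5], 10)


def test_elias_fano_random_sequences_match_array():
    rng = np.random.default_rng(17)
    for _ in range(1000):
        n = int(rng.integers(1, 60))
        u = int(rng.integers(n, n + 10 ** 4))
        vals = sorted(int(v) for v in
                      rng.choice(np.arange(u, dtype=np.int64), size=n,
                                 replace=False))
        ef = EliasFano(vals, u)
        assert [ef.access(j) for j in range(1, n + 1)] == vals


def test_elias_fano_serialization_round_trip():
    vals = [0, 5, 6, 99, 10 ** 6]
    ef = EliasFano(vals, 10 ** 6 + 1)
    ef2 = EliasFano.from_bytes(ef.to_bytes())
    assert [ef2.access(j) for j in range(1, 6)] == vals


# -- iterators -----------------------------------------------------------

def test_next_geq_examples():
    store = ColorStore([[2, 4, 13, 25]], N=100)
    it = store.iterator(1)
    assert it.next_geq(2) == 2  # equal-to case
    assert it.next_geq(5) == 13
    assert it.next_geq(26) == 101  # sentinel N+1
    assert it.next() == 101  # exhaustion is absorbing


def test_iterator_semantics_per_representation():
    rng = np.random.default_rng(19)
    # force each representation: sparse, bitvector, dense (materialized and not)
    cases = []
    for _ in range(500):
        N = int(rng.integers(4, 90))
        cases.append((random_color(rng, N), N))
    for threshold in (65536, 0):  # 0 forces complement-walking iterators
        for C, N in cases:
            store = ColorStore([C], N, materialize_threshold=threshold)
            it = store.iterator(1)
            # full enumeration via next()
            seen = [it.value()]
            while True:
                v = it.next()
                if v > N:
                    break
                seen.append(v)
            assert seen == C
            # next_geq against the linear-scan oracle
            it2 = store.iterator(1)
            for x in sorted(int(v) for v in rng.integers(1, N + 2, size=20)):
                assert it2.next_geq(x) == oracles.next_geq_oracle(C, x, N)


def test_store_offsets_and_decode_every_color(seed11_graph):
    store = ColorStore(seed11_graph.colors, seed11_graph.N)
    for j, C in enumerate(seed11_graph.colors, start=1):
        assert store.color(j) == list(C)
        assert store.cardinality(j) == len(C)
    total = sum(store.bit_length(j) for j in range(1, store.M + 1))
    assert total == store.nbits


def test_hybrid_beats_all_bitvector_on_pangenome(seed42_graph):
    store = ColorStore(seed42_graph.colors, seed42_graph.N)
    assert store.nbits <= store.M * store.N


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.integers(2, 64), st.data())
def test_round_trip_property(N, data):
    C = sorted(data.draw(st.sets(st.integers(1, N), min_size=1)))
    tag, bits = encode_color(C, N)
    assert decode_color(tag, bits, N) == C
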
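"""Pseudoalignment algorithms vs naive per-k-mer oracles."""

import numpy as np
import pytest

from ccdbg import (BACKOFF_LIKE, KALLISTO_LIKE, SkipPolicy, full_intersection,
                   intersect, skipping_pseudoalign, threshold_union)
from ccdbg.colorstore import ColorStore
from ccdbg.pseudoalign import threshold_for, union_threshold

import oracles


def make_iterators(colors, N):
    store = ColorStore(colors, N)
    return [store.iterator(j) for j in range(1, len(colors) + 1)]


# -- intersect -----------------------------------------------------------

def test_intersect_identity_and_example():
    (it,) = make_iterators([[1, 3, 5, 7]], 10)
    assert intersect([it]) == [1, 3, 5, 7]
    its = make_iterators([[1, 3, 5, 7], [3, 4, 5], [5, 6, 7]], 10)
    assert intersect(its) == [5]


def test_intersect_requires_iterators():
    with pytest.raises(ValueError):
        intersect([])


def test_intersect_random_families_match_set_oracle():
    rng = np.random.default_rng(19)
    for _ in range(2000):
        N = int(rng.integers(3, 40))
        p = int(rng.integers(1, 9))
        colors = [sorted(int(v) for v in rng.choice(
            np.arange(1, N + 1), size=int(rng.integers(1, N + 1)),
            replace=False)) for _ in range(p)]
        expected = sorted(set.intersection(*(set(c) for c in colors)))
        assert intersect(make_iterators(colors, N)) == expected


# -- threshold arithmetic -------------------------------------------------

def test_threshold_is_exact_ceiling():
    assert threshold_for(5, 0.8) == 4  # 5*0.8 = 4 exactly, "at least" keeps 4
    assert threshold_for(6, 0.8) == 5  # ceil(4.8)
    assert threshold_for(3, 1.0) == 3
    assert threshold_for(10, 0.05) == 1
    with pytest.raises(ValueError):
        threshold_for(5, 0.0)
    with pytest.raises(ValueError):
        threshold_for(5, 1.5)


def test_union_counting_example():
    # colors [1,2] (score 2), [2,3] (score 1), [2,4] (score 1); s=4, tau=0.5
    store = ColorStore([[1, 2], [2, 3], [2, 4]], N=4)
    scored = [(store.iterator(1), 2), (store.iterator(2), 1),
              (store.iterator(3), 1)]
    t = threshold_for(4, 0.5)
    assert union_threshold(scored, t, 4) == [1, 2]


# -- read-level equivalence ----------------------------------------------

def test_full_intersection_trivial_cases(seed11_index, seed11_graph):
    # no positive k-mer -> unmapped
    r = full_intersection(seed11_index, "A" * 40)
    if r.n_positive == 0:
        assert not r.mapped and r.refs == []
    # read wholly inside one unitig -> that unitig's color
    u = max(seed11_graph.unitigs, key=lambda u: len(u.sequence))
    r = full_intersection(seed11_index, u.sequence)
    assert r.refs == list(seed11_graph.colors[u.color_id - 1])
    assert r.n_colors == 1


def test_full_intersection_matches_oracle(seed11_index, seed11_colors,
                                          seed11_reads):
    reads, _ = seed11_reads
    k = seed11_index.k
    for name, seq in reads:
        got = full_intersection(seed11_index, seq, name=name)
        assert got.refs == oracles.naive_full_intersection(
            seed11_colors, seq, k)


def test_threshold_union_tau1_equals_full_intersection_single_color(
        seed11_index, seed11_graph):
    u = max(seed11_graph.unitigs, key=lambda u: len(u.sequence))
    fi = full_intersection(seed11_index, u.sequence)
    tu = threshold_union(seed11_index, u.sequence, tau=1.0, s_mode="positive")
    assert tu.refs == fi.refs


def test_threshold_union_matches_oracle(seed11_index, seed11_colors,
                                        seed11_reads):
    reads, _ = seed11_reads
    k = seed11_index.k
    for name, seq in reads[:300]:
        for s_mode in ("positive", "all"):
            got = threshold_union(seed11_index, seq, tau=0.8, s_mode=s_mode)
            assert got.refs == oracles.naive_threshold_union(
                seed11_colors, seq, k, 0.8, s_mode)


def test_threshold_union_superset_of_full_intersection(seed11_index,
                                                       seed11_reads):
    reads, _ = seed11_reads
    for _, seq in reads[:200]:
        fi = set(full_intersection(seed11_index, seq).refs)
        tu = set(threshold_union(seed11_index, seq, tau=1.0,
                                 s_mode="positive").refs)
        assert fi <= tu


def test_bad_threshold_parameters_rejected(seed11_index):
    with pytest.raises(ValueError):
        threshold_union(seed11_index, "ACGT" * 10, tau=2.0)
    with pytest.raises(ValueError):
        threshold_union(seed11_index, "ACGT" * 10, s_mode="bogus")


# -- skipping heuristics --------------------------------------------------

def test_error_free_single_unitig_read_uses_two_queries(seed11_graph,
                                                        seed11_index):
    u = max(seed11_graph.unitigs, key=lambda u: len(u.sequence))
    assert len(u.sequence) >= seed11_index.k + 2
    res, trace = skipping_pseudoalign(seed11_index, u.sequence, KALLISTO_LIKE)
    assert trace.n_queries == 2  # first k-mer + bookend
    assert res.refs == list(seed11_graph.colors[u.color_id - 1])


def test_no_indexed_kmers_queries_every_position(seed11_index):
    q = "A" * 60
    if seed11_index.dictionary.lookup(q[:15]) is None:
        res, trace = skipping_pseudoalign(seed11_index, q, BACKOFF_LIKE)
        assert trace.n_queries == len(q) - seed11_index.k + 1
        assert not res.mapped


@pytest.mark.parametrize("policy", [KALLISTO_LIKE, BACKOFF_LIKE],
                         ids=["kallisto-like", "backoff-like"])
def test_skipping_instrumented_consistency(policy, seed11_index, seed11_colors,
                                           seed11_reads):
    reads, _ = seed11_reads
    k = seed11_index.k
    for name, seq in reads:
        res, trace = skipping_pseudoalign(seed11_index, seq, policy)
        assert trace.n_queries <= len(seq) - k + 1
        # the result is exactly the intersection over confirmed k-mers
        sets = [set(seed11_colors[oracles.canon(seq[pos:pos + k])])
                for pos, _ in trace.confirmed]
        expected = sorted(set.intersection(*sets)) if sets else []
        assert res.refs == expected


def test_skipping_policy_validation():
    with pytest.raises(ValueError):
        SkipPolicy(on_miss="bogus")
    with pytest.raises(ValueError):
        SkipPolicy(on_unexpected_unitig="bogus")


def test_restart_invariance(seed11_index, seed11_reads):
    """Query results are independent of any prior streaming state."""
    reads, _ = seed11_reads
    sample = reads[:50]
    first = [full_intersection(seed11_index, s).refs for _, s in sample]
    again = [full_intersection(seed11_index, s).refs for _, s in sample[::-1]]
    assert first == again[::-1]
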
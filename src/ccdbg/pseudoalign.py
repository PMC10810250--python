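"""Pseudoalignment: mapping a read to the set of compatible references.

Four query algorithms over the index:

* **full-intersection** — the intersection of the colors of all positive
  (indexed) k-mers of the read;
* **threshold-union** — references occurring in at least ceil(s * tau) of
  the counted k-mer colors, with s either the number of positive k-mers
  (``s_mode="positive"``) or all |Q|-k+1 k-mers (``s_mode="all"``);
* **skipping heuristics** — jump-ahead strategies that assume consecutive
  k-mers share a unitig and only query bookending k-mers, with
  configurable behavior on a missed jump (query-next or iterative
  back-off) and on landing in an unexpected unitig (query-next, back-off,
  or an aggressive re-jump to the new unitig's implied end).

Color intersection/union work over Next/Next-GEQ iterators with the N+1
sentinel (leapfrog for intersection, a heap-merge for scored union).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from fractions import Fraction


@dataclass
class QueryResult:
    name: str
    refs: list[int]  # sorted, 1-based reference ids; empty iff unmapped
    n_kmers: int  # k-mers queried against the dictionary
    n_positive: int  # k-mers found in the dictionary
    n_colors: int  # distinct color ids touched

    @property
    def mapped(self) -> bool:
        return bool(self.refs)

    @property
    def status(self) -> str:
        return "mapped" if self.refs else "unmapped"


@dataclass(frozen=True)
class SkipPolicy:
    """Fixed-per-run resolution strategy for the skipping heuristics."""

    on_miss: str = "query-next"  # or "back-off"
    on_unexpected_unitig: str = "query-next"  # or "back-off" | "aggressive-jump"
    back_off_limit: int = 4

    def __post_init__(self):
        if self.on_miss not in ("query-next", "back-off"):
            raise ValueError(f"bad on_miss {self.on_miss!r}")
        if self.on_unexpected_unitig not in ("query-next", "back-off",
                                             "aggressive-jump"):
            raise ValueError(f"bad on_unexpected_unitig {self.on_unexpected_unitig!r}")


KALLISTO_LIKE = SkipPolicy(on_miss="query-next",
                           on_unexpected_unitig="aggressive-jump")
BACKOFF_LIKE = SkipPolicy(on_miss="back-off", on_unexpected_unitig="back-off",
                          back_off_limit=4)
PRESETS = {"kallisto-like": KALLISTO_LIKE, "backoff-like": BACKOFF_LIKE}


def intersect(iterators) -> list[int]:
    """Leapfrog intersection of p >= 1 color iterators (Next-GEQ based)."""
    if not iterators:
        raise ValueError("intersect requires at least one iterator")
    N = iterators[0].N
    out = []
    cand = max(it.value() for it in iterators)
    while cand <= N:
        for it in iterators:
            v = it.next_geq(cand)
            if v != cand:
                cand = v
                break
        else:
            out.append(cand)
            cand += 1
    return out


def union_threshold(scored_iterators, t: int, N: int) -> list[int]:
    """References whose summed scores across colors reach ``t``.

    ``scored_iterators`` is a list of (iterator, score) pairs; a heap-based
    multiway merge accumulates, per reference id, the total score of the
    colors containing it.
    """
    heap = [(it.value(), j) for j, (it, _) in enumerate(scored_iterators)
            if it.value() <= N]
    heapq.heapify(heap)
    out = []
    while heap:
        v = heap[0][0]
        tally = 0
        while heap and heap[0][0] == v:
            _, j = heapq.heappop(heap)
            it, score = scored_iterators[j]
            tally += score
            nv = it.next()
            if nv <= N:
                heapq.heappush(heap, (nv, j))
        if tally >= t:
            out.append(v)
    return out


def _stream_unitigs(index, seq):
    """Stream all k-mers; distinct unitig ids with per-unitig positive counts."""
    hits, _ = index.dictionary.streaming_lookup(seq)
    counts: dict[int, int] = {}
    n_pos = 0
    for h in hits:
        if h is not None:
            n_pos += 1
            counts[h.unitig_id] = counts.get(h.unitig_id, 0) + 1
    return counts, len(hits), n_pos


def color_id_list(index, seq) -> tuple[tuple[int, ...], int, int]:
    """Sorted distinct color ids of a read plus (n_kmers, n_positive)."""
    counts, n_kmers, n_pos = _stream_unitigs(index, seq)
    cids = sorted({index.color_rank.color_id(u) for u in counts})
    return tuple(cids), n_kmers, n_pos


def full_intersection(index, seq: str, name: str = "") -> QueryResult:
    """Intersect the colors of all positive k-mers of the read."""
    cids, n_kmers, n_pos = color_id_list(index, seq)
    if not cids:
        return QueryResult(name, [], n_kmers, n_pos, 0)
    refs = intersect([index.color_store.iterator(c) for c in cids])
    return QueryResult(name, refs, n_kmers, n_pos, len(cids))


def threshold_for(s: int, tau: float) -> int:
    """ceil(s * tau) with exact rational arithmetic (no float comparisons)."""
    frac = Fraction(tau).limit_denominator(10 ** 6)
    if not 0 < frac <= 1:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    return max(1, -((-s * frac.numerator) // frac.denominator))


def threshold_union(index, seq: str, tau: float = 0.8,
                    s_mode: str = "positive", name: str = "") -> QueryResult:
    """References compatible with at least ceil(s * tau) counted k-mer colors."""
    if s_mode not in ("positive", "all"):
        raise ValueError(f"s_mode must be 'positive' or 'all', got {s_mode!r}")
    counts, n_kmers, n_pos = _stream_unitigs(index, seq)
    if not counts:
        threshold_for(1, tau)  # still validate tau
        return QueryResult(name, [], n_kmers, n_pos, 0)
    # aggregate per-unitig scores by color id (scores of equal ids summed)
    color_scores: dict[int, int] = {}
    for u, score in counts.items():
        c = index.color_rank.color_id(u)
        color_scores[c] = color_scores.get(c, 0) + score
    s = n_pos if s_mode == "positive" else n_kmers
    t = threshold_for(s, tau)
    scored = [(index.color_store.iterator(c), sc)
              for c, sc in sorted(color_scores.items())]
    refs = union_threshold(scored, t, index.N)
    return QueryResult(name, refs, n_kmers, n_pos, len(color_scores))


@dataclass
class SkipTrace:
    """Instrumentation of one skipping query, for consistency checks."""

    confirmed: list = field(default_factory=list)  # (position, unitig id)
    n_queries: int = 0  # distinct dictionary queries issued


def _implied_jump(hit, n_kmers: int, pos: int, unitig_len: int, k: int) -> int:
    """K-mers to skip: distance to the hit unitig's end in read direction,
    capped at the end of the read."""
    remaining = (unitig_len - k) - hit.offset if hit.forward else hit.offset
    return min(remaining, n_kmers - 1 - pos)


def skipping_pseudoalign(index, seq: str, policy: SkipPolicy = KALLISTO_LIKE,
                         name: str = "") -> tuple[QueryResult, SkipTrace]:
    """Skipping-heuristic pseudoalignment under a fixed policy.

    Every positive queried k-mer is *confirmed* (contributes its unitig's
    color); the result is the intersection of the colors of the distinct
    confirmed unitigs. Per-read memoization guarantees at most |Q|-k+1
    dictionary queries.
    """
    k = index.k
    trace = SkipTrace()
    n_kmers = len(seq) - k + 1
    if n_kmers <= 0:
        return QueryResult(name, [], 0, 0, 0), trace
    d = index.dictionary
    ulen = index.unitig_lengths
    cache: dict[int, object] = {}

    def query(pos: int):
        if pos not in cache:
            trace.n_queries += 1
            cache[pos] = d.lookup(seq[pos:pos + k])
        return cache[pos]

    confirmed: dict[int, int] = {}  # position -> unitig id

    def confirm(pos, hit):
        confirmed.setdefault(pos, hit.unitig_id)

    def back_off(anchor: int, jump: int, expected_unitig: int):
        """Iteratively halve the jump looking for a k-mer of the expected
        unitig; returns the position to continue from."""
        d_ = jump
        for _ in range(policy.back_off_limit):
            d_ = max(1, d_ // 2)
            t2 = anchor + d_
            r = query(t2)
            if r is not None:
                confirm(t2, r)
                return t2  # re-anchor at the found k-mer
            if d_ == 1:
                break
        return anchor + jump + 1  # fall through to query-next

    pos = 0
    while pos < n_kmers:
        r = query(pos)
        if r is None:
            pos += 1
            continue
        confirm(pos, r)
        jump = _implied_jump(r, n_kmers, pos, ulen[r.unitig_id - 1], k)
        if jump <= 0:
            pos += 1
            continue
        target = pos + jump
        r2 = query(target)
        if r2 is not None and r2.unitig_id == r.unitig_id:
            confirm(target, r2)  # scenario A: bookend found
            pos = target + 1
        elif r2 is None:  # scenario B: jump and miss
            if policy.on_miss == "query-next":
                pos = target + 1
            else:
                pos = back_off(pos, jump, r.unitig_id)
        else:  # scenario C: jump into an unexpected unitig
            confirm(target, r2)
            if policy.on_unexpected_unitig == "query-next":
                pos = target + 1
            elif policy.on_unexpected_unitig == "aggressive-jump":
                pos = target  # re-anchor: next iteration jumps to its end
                jump2 = _implied_jump(r2, n_kmers, target,
                                      ulen[r2.unitig_id - 1], k)
                if jump2 <= 0:
                    pos = target + 1
            else:
                pos = back_off(pos, jump, r.unitig_id)

    trace.confirmed = sorted(confirmed.items())
    units = sorted(set(confirmed.values()))
    if not units:
        return QueryResult(name, [], trace.n_queries, 0, 0), trace
    cids = sorted({index.color_rank.color_id(u) for u in units})
    refs = intersect([index.color_store.iterator(c) for c in cids])
    return QueryResult(name, refs, trace.n_queries, len(confirmed), len(cids)), trace
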
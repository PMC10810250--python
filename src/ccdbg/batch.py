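"""Two-pass multi-query optimization for full-intersection pseudoalignment.

Pass 1 computes, per read, the sorted list of distinct color ids its
positive k-mers touch (dictionary + rank only — no color decoding). The
lists are sorted lexicographically and collated so identical lists share
one entry. Pass 2 decodes and intersects each *distinct* non-empty list
exactly once and fans the shared result back to all its reads. Output is
identical to running full-intersection independently per read, in the
original read order; only the work is deduplicated.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pseudoalign import QueryResult, color_id_list, intersect


def collate_color_lists(lists):
    """Group read ordinals by identical color-id list, lexicographic order.

    ``lists`` is a sequence of tuples of color ids (one per read). Returns
    an ordered list of ``(color_id_list, [read ordinals])``.
    """
    groups: dict[tuple, list[int]] = {}
    for ordinal, cids in enumerate(lists):
        groups.setdefault(tuple(cids), []).append(ordinal)
    return [(cids, groups[cids]) for cids in sorted(groups)]


@dataclass
class TwoPassResult:
    results: list[QueryResult]  # in original read order
    n_intersections: int  # == number of distinct non-empty color-id lists


def two_pass_map(index, reads) -> TwoPassResult:
    """Map ``reads`` (iterable of (name, sequence)) in two passes."""
    reads = list(reads)
    lists = []
    diags = []
    for _, seq in reads:
        cids, n_kmers, n_pos = color_id_list(index, seq)
        lists.append(cids)
        diags.append((n_kmers, n_pos))
    results: list[QueryResult | None] = [None] * len(reads)
    n_intersections = 0
    for cids, ordinals in collate_color_lists(lists):
        if cids:
            n_intersections += 1
            refs = intersect([index.color_store.iterator(c) for c in cids])
        else:
            refs = []
        for o in ordinals:
            n_kmers, n_pos = diags[o]
            results[o] = QueryResult(reads[o][0], list(refs),
                                     n_kmers, n_pos, len(cids))
    return TwoPassResult(results, n_intersections)
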
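"""Unitig id -> color id in 1 + o(1) bits per unitig.

With unitigs laid out so that equal color ids are contiguous, a bit-vector
B[1..m] marks the last unitig of every color group (B[m] is always set, so
popcount(B) = M), and

    Color-ID(u_i) = Rank1(i, B) + 1

where Rank1(i, B) counts ones in the half-open prefix B[1, i). Rank is O(1)
via one absolute count per 512-bit superblock plus on-the-fly popcounts of
at most seven 64-bit words.
"""

from __future__ import annotations

import numpy as np

_WORDS_PER_SUPER = 8  # 512-bit superblocks


class ColorRank:
    def __init__(self, words: np.ndarray, m: int, M: int) -> None:
        self.words = np.ascontiguousarray(words, dtype=np.uint64)
        self.m = m
        self.M = M
        pops = np.bitwise_count(self.words).astype(np.int64)
        nsuper = (len(self.words) + _WORDS_PER_SUPER - 1) // _WORDS_PER_SUPER
        self.super = np.zeros(nsuper + 1, dtype=np.int64)
        for s in range(nsuper):
            self.super[s + 1] = self.super[s] + int(
                pops[s * _WORDS_PER_SUPER:(s + 1) * _WORDS_PER_SUPER].sum())

    def get(self, i: int) -> int:
        """Bit B[i], 1-based."""
        if not 1 <= i <= self.m:
            raise IndexError(f"bit index {i} out of [1, {self.m}]")
        j = i - 1
        return (int(self.words[j >> 6]) >> (j & 63)) & 1

    def rank1(self, i: int) -> int:
        """Number of ones in B[1, i), 1 <= i <= m+1."""
        if not 1 <= i <= self.m + 1:
            raise IndexError(f"rank position {i} out of [1, {self.m + 1}]")
        j = i - 1  # count ones among the first j bits (0-based prefix)
        word, bit = j >> 6, j & 63
        s = word // _WORDS_PER_SUPER
        count = int(self.super[s])
        for w in range(s * _WORDS_PER_SUPER, word):
            count += int(self.words[w]).bit_count()
        if bit:
            count += (int(self.words[word]) & ((1 << bit) - 1)).bit_count()
        return count

    def color_id(self, i: int) -> int:
        """Color id of unitig i (1-based), Rank1(i, B) + 1."""
        if not 1 <= i <= self.m:
            raise IndexError(f"unitig id {i} out of [1, {self.m}]")
        return self.rank1(i) + 1

    def bits(self) -> np.ndarray:
        """B as a boolean array of length m (index 0 is B[1])."""
        j = np.arange(self.m)
        return (self.words[j >> 6] >> (j & 63).astype(np.uint64)) & np.uint64(1) == 1

    @property
    def overhead_bits(self) -> int:
        """Directory bits on top of the m raw bits (the o(m) term)."""
        return self.super.size * 64


def build_color_rank(color_ids: list[int]) -> ColorRank:
    """Build B from the per-unitig color ids of a color-grouped layout.

    Raises ``ValueError`` if equal ids are not contiguous (the layout
    premise of the whole mapping).
    """
    m = len(color_ids)
    if m == 0:
        raise ValueError("empty layout")
    seen = set()
    prev = None
    nwords = (m + 63) >> 6
    words = np.zeros(nwords, dtype=np.uint64)
    M = 0
    for idx, cid in enumerate(color_ids):
        if cid != prev:
            if cid in seen:
                raise ValueError(f"color id {cid} is not contiguous in the layout")
            seen.add(cid)
            M += 1
            if idx > 0:
                j = idx - 1
                words[j >> 6] |= np.uint64(1) << np.uint64(j & 63)
            prev = cid
    j = m - 1
    words[j >> 6] |= np.uint64(1) << np.uint64(j & 63)
    return ColorRank(words, m, M)
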
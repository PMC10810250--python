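"""Order-preserving exact k-mer dictionary over the color-sorted unitigs.

The unitig spellings are stored contiguously (in exactly the ccdBG's
color-sorted order — the order-preserving property the rank-based color
mapping depends on). Lookup(x) locates the canonical form of x through a
*minimizer* bucket: every w-mer occurrence in the unitig spellings is
indexed under its strand-canonical 2-bit code, a query k-mer picks the
w-mer with the smallest seeded 64-bit hash, and each candidate site is
verified by direct string comparison — the dictionary is exact even when
buckets collide.

Streaming queries over consecutive k-mers of a read first test whether the
next k-mer extends the previously hit (unitig, offset) position before
falling back to minimizer search; a cache-hit counter is exposed for
testing. A miss clears only the position cache, not the minimizer cache.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import CCDBG
from .kmers import CODE, _canon, mix64, revcomp

#: fixed minimizer hash seed, recorded in the index header
DEFAULT_MINIMIZER_SEED = 0x9E3779B97F4A7C15

_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in CODE.items():
    _LUT[ord(_b)] = _c


@dataclass(frozen=True)
class Hit:
    """A successful lookup: 1-based unitig id, 0-based offset of the
    canonical k-mer occurrence, and the orientation of that occurrence
    relative to the *queried* form (True = the query reads forward)."""

    unitig_id: int
    offset: int
    forward: bool


def _window_ints(seq: str, w: int) -> np.ndarray:
    """Strand-canonical 2-bit integers of all w-mers of ``seq`` (vectorized)."""
    code = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
    nw = len(seq) - w + 1
    fw = np.zeros(nw, dtype=np.int64)
    for j in range(w):
        fw = (fw << 2) | code[j:j + nw]
    rcode = 3 - code
    rw = np.zeros(nw, dtype=np.int64)
    for j in range(w - 1, -1, -1):
        rw = (rw << 2) | rcode[j:j + nw]
    return np.minimum(fw, rw)


class KmerDictionary:
    def __init__(self, blob: str, starts: np.ndarray, k: int, w: int,
                 n: int, seed: int = DEFAULT_MINIMIZER_SEED) -> None:
        self.blob = blob
        self.starts = np.ascontiguousarray(starts, dtype=np.int64)
        self.k = k
        self.w = w
        self.n = n
        self.seed = seed
        self.m = len(starts) - 1
        self._build_minimizer_index()

    def _build_minimizer_index(self) -> None:
        keys_parts, pos_parts = [], []
        for i in range(self.m):
            s, e = int(self.starts[i]), int(self.starts[i + 1])
            if e - s >= self.w:
                keys_parts.append(_window_ints(self.blob[s:e], self.w))
                pos_parts.append(np.arange(s, e - self.w + 1, dtype=np.int64))
        if keys_parts:
            keys = np.concatenate(keys_parts)
            pos = np.concatenate(pos_parts)
            order = np.argsort(keys, kind="stable")
            keys, pos = keys[order], pos[order]
            uniq, first = np.unique(keys, return_index=True)
            bounds = np.append(first, len(keys))
            self.min_index = {int(kk): pos[bounds[t]:bounds[t + 1]]
                              for t, kk in enumerate(uniq)}
        else:
            self.min_index = {}

    # -- core lookup ----------------------------------------------------
    def _minimizer(self, xc: str) -> int:
        """Strand-canonical code of the minimum-hash w-mer of canonical ``xc``."""
        k, w = self.k, self.w
        mask = (1 << (2 * w)) - 1
        f = r = 0
        shift = 2 * (w - 1)
        best = None
        for i in range(k):
            c = CODE[xc[i]]
            f = ((f << 2) | c) & mask
            r = (r >> 2) | ((3 - c) << shift)
            if i >= w - 1:
                key = f if f < r else r
                h = mix64(key, self.seed)
                if best is None or h < best[0]:
                    best = (h, key)
        return best[1]

    def _locate(self, xc: str):
        """Site of canonical ``xc``: (unitig index 0-based, global pos, spells-xc)."""
        key = self._minimizer(xc)
        return self._verify(xc, key, self.min_index.get(key))

    def _verify(self, xc: str, key: int, cand):
        if cand is None:
            return None
        k, w = self.k, self.w
        rc = revcomp(xc)
        starts = self.starts
        blob = self.blob
        # offsets within xc where the chosen canonical w-mer occurs (either strand)
        offs_f = [i for i in range(k - w + 1)
                  if min(_enc(xc[i:i + w]), _enc_rc(xc[i:i + w])) == key]
        for p in cand:
            p = int(p)
            ui = int(np.searchsorted(starts, p, side="right")) - 1
            us, ue = int(starts[ui]), int(starts[ui + 1])
            for off in offs_f:
                q = p - off
                if q >= us and q + k <= ue and blob[q:q + k] == xc:
                    return ui, q, True
                qr = p - (k - w - off)
                if qr >= us and qr + k <= ue and blob[qr:qr + k] == rc:
                    return ui, qr, False
        return None

    def lookup(self, x: str):
        """Full (non-streaming) lookup; returns :class:`Hit` or None."""
        if len(x) != self.k:
            raise ValueError(f"query length {len(x)} != k={self.k}")
        xc, fx = _canon(x)
        site = self._locate(xc)
        if site is None:
            return None
        ui, q, fu = site
        return Hit(ui + 1, q - int(self.starts[ui]), fx == fu)

    # -- streaming ------------------------------------------------------
    def stream(self) -> "KmerStream":
        return KmerStream(self)

    def streaming_lookup(self, seq: str):
        """Per-position lookups over a query sequence.

        Returns ``(hits, cache_hits)`` where ``hits`` has one entry (Hit or
        None) per k-mer position; a sequence shorter than k yields ``([],
        0)`` (the "too short" case).
        """
        st = self.stream()
        hits = st.query(seq)
        return hits, st.cache_hits


def _enc(s: str) -> int:
    v = 0
    for ch in s:
        v = (v << 2) | CODE[ch]
    return v


def _enc_rc(s: str) -> int:
    v = 0
    for ch in reversed(s):
        v = (v << 2) | (3 - CODE[ch])
    return v


class KmerStream:
    """Streaming state over one query sequence at a time.

    ``cache_hits`` counts k-mers resolved by extending the cached unitig
    position; ``lookups`` counts falls back to full minimizer search. State
    is cleared at the start of every query sequence.
    """

    def __init__(self, d: KmerDictionary) -> None:
        self.d = d
        self.cache_hits = 0
        self.lookups = 0
        self._reset()

    def _reset(self) -> None:
        self._site = None  # (q global, read-forward, us, ue, unitig index)
        self._minimizer = None

    def query(self, seq: str) -> list:
        d = self.d
        k = d.k
        self._reset()
        if len(seq) < k:
            return []
        out = []
        blob = d.blob
        for i in range(len(seq) - k + 1):
            x = seq[i:i + k]
            hit = None
            site = self._site
            if site is not None:
                q, fwd_read, us, ue, ui = site
                if fwd_read:
                    q2 = q + 1
                    if q2 + k <= ue and blob[q2:q2 + k] == x:
                        hit = self._cache_hit(q2, True, us, ue, ui)
                else:
                    q2 = q - 1
                    if q2 >= us and blob[q2:q2 + k] == revcomp(x):
                        hit = self._cache_hit(q2, False, us, ue, ui)
            if hit is None:
                hit = self._full(x)
            out.append(hit)
        return out

    def _cache_hit(self, q: int, fwd_read: bool, us: int, ue: int, ui: int) -> Hit:
        # the site spells the query forward iff fwd_read, which is exactly
        # the orientation flag the Hit contract asks for
        self.cache_hits += 1
        self._site = (q, fwd_read, us, ue, ui)
        return Hit(ui + 1, q - us, fwd_read)

    def _full(self, x: str):
        d = self.d
        self.lookups += 1
        xc, fx = _canon(x)
        key = d._minimizer(xc)
        if self._minimizer is not None and self._minimizer[0] == key:
            cand = self._minimizer[1]
        else:
            cand = d.min_index.get(key)
            self._minimizer = (key, cand)
        site = d._verify(xc, key, cand)
        if site is None:
            self._site = None  # position cache only; minimizer cache kept
            return None
        ui, q, fu = site
        us, ue = int(d.starts[ui]), int(d.starts[ui + 1])
        fwd_read = fx == fu
        self._site = (q, fwd_read, us, ue, ui)
        return Hit(ui + 1, q - us, fwd_read)


def build_dictionary(ccdbg: CCDBG, w: int = 15,
                     seed: int = DEFAULT_MINIMIZER_SEED) -> KmerDictionary:
    """Build the dictionary over a ccdBG's color-sorted unitigs."""
    if w >= ccdbg.k:
        raise ValueError(f"minimizer length w={w} must be < k={ccdbg.k}")
    if w < 1:
        raise ValueError("w must be >= 1")
    blob = "".join(u.sequence for u in ccdbg.unitigs)
    starts = np.zeros(len(ccdbg.unitigs) + 1, dtype=np.int64)
    for i, u in enumerate(ccdbg.unitigs):
        starts[i + 1] = starts[i] + len(u.sequence)
    return KmerDictionary(blob, starts, ccdbg.k, w, ccdbg.n, seed)
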
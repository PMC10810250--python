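"""Compressed inverted index over the M distinct colors.

Each color C (a strictly increasing list of reference ids in [1..N]) is
routed by its density |C|/N to one of three representations:

* ``sparse``           (|C|/N < 1/4)  — Elias-delta code of the first id,
  then delta codes of the successive gaps;
* ``dense-complement`` (|C|/N > 3/4)  — the complement set [1..N] \\ C is
  encoded with the sparse scheme (the "complement trick"; a full color has
  an empty payload);
* ``bitvector``        (otherwise, boundaries included) — the characteristic
  bit-vector b[1..N].

Every color is stored as a 2-bit tag, a delta-coded count header (sparse:
the cardinality; dense-complement: the complement cardinality plus one;
bitvector: none), and the payload, concatenated into one ``sequences`` bit
stream. A monotone
``offsets`` directory (Elias-Fano encoded) records where each color begins.
Iterators over decoded colors expose Value/Next/Next-GEQ with the N+1
sentinel required by the leapfrog intersection.
"""

from __future__ import annotations

import struct
from bisect import bisect_left

import numpy as np

from .bits import BitReader, BitWriter

TAG_SPARSE = 0
TAG_DENSE = 1
TAG_BITVECTOR = 2
TAG_NAMES = {TAG_SPARSE: "sparse", TAG_DENSE: "dense-complement",
             TAG_BITVECTOR: "bitvector"}

#: dense-complement colors up to this cardinality are materialized per query
MATERIALIZE_THRESHOLD = 65536


def classify(size: int, N: int) -> int:
    """Density routing: strict 1/4 and 3/4 thresholds, boundaries -> bitvector."""
    if 4 * size < N:
        return TAG_SPARSE
    if 4 * size > 3 * N:
        return TAG_DENSE
    return TAG_BITVECTOR


def _check_color(C, N) -> None:
    if len(C) == 0:
        raise ValueError("a color is never empty")
    prev = 0
    for v in C:
        if v <= prev:
            raise ValueError("color must be strictly increasing")
        prev = v
    if prev > N:
        raise ValueError(f"reference id {prev} exceeds N={N}")


def _write_sparse_payload(bw: BitWriter, values) -> None:
    prev = 0
    for j, v in enumerate(values):
        bw.write_delta(v if j == 0 else v - prev)
        prev = v


def _read_sparse_payload(br: BitReader, size: int) -> list[int]:
    out = []
    cur = 0
    for _ in range(size):
        cur += br.read_delta()
        out.append(cur)
    return out


def write_color(bw: BitWriter, C, N: int) -> int:
    """Append tag + count header + payload for one color; returns the tag.

    The count header is the delta-coded number of *stored* elements: the
    cardinality for sparse colors, the complement cardinality plus one for
    dense-complement colors (so a full color costs a single header bit),
    and nothing for the bitvector representation, whose N payload bits are
    self-delimiting.
    """
    _check_color(C, N)
    tag = classify(len(C), N)
    bw.write(tag, 2)
    if tag == TAG_SPARSE:
        bw.write_delta(len(C))
        _write_sparse_payload(bw, C)
    elif tag == TAG_DENSE:
        members = set(C)
        comp = [j for j in range(1, N + 1) if j not in members]
        bw.write_delta(len(comp) + 1)
        _write_sparse_payload(bw, comp)
    else:
        v = 0
        for j in C:
            v |= 1 << (N - j)
        bw.write(v, N)
    return tag


def read_color(br: BitReader, N: int) -> list[int]:
    tag = br.read(2)
    if tag == TAG_SPARSE:
        return _read_sparse_payload(br, br.read_delta())
    if tag == TAG_DENSE:
        comp = set(_read_sparse_payload(br, br.read_delta() - 1))
        return [j for j in range(1, N + 1) if j not in comp]
    if tag == TAG_BITVECTOR:
        v = br.read(N)
        return [j for j in range(1, N + 1) if (v >> (N - j)) & 1]
    raise ValueError(f"bad representation tag {tag}")


def encode_color(C, N: int) -> tuple[str, str]:
    """Encode one color; returns ``(tag name, header+payload bit string)``.

    The bit string is everything after the 2-bit tag: the delta-coded
    count header (if the representation needs one) followed by the payload.
    """
    bw = BitWriter()
    tag = write_color(bw, C, N)
    return TAG_NAMES[tag], bw.bitstring()[2:]


def decode_color(tag: str, bits: str, N: int) -> list[int]:
    """Inverse of :func:`encode_color`."""
    code = {v: k for k, v in TAG_NAMES.items()}[tag]
    bw = BitWriter()
    bw.write(code, 2)
    for ch in bits:
        bw.write(int(ch), 1)
    return read_color(BitReader(bw.getvalue(), bw.nbits), N)


class EliasFano:
    """Quasi-succinct encoding of a strictly increasing sequence with O(1)-ish
    access; the high-bits select is a plain in-word scan (no select directory).
    """

    def __init__(self, values, universe: int) -> None:
        n = len(values)
        if n == 0:
            raise ValueError("empty sequence")
        prev = -1
        for v in values:
            if v <= prev:
                raise ValueError("sequence must be strictly increasing")
            prev = v
        if prev >= universe:
            raise ValueError("max value must be < universe")
        self.n = n
        self.u = universe
        self.l = max(0, (universe // n).bit_length() - 1)  # floor(log2(u/n))
        mask = (1 << self.l) - 1
        self.low = np.array([v & mask for v in values], dtype=np.uint64)
        nhigh = n + (universe >> self.l) + 1
        words = np.zeros((nhigh + 63) >> 6, dtype=np.uint64)
        for j, v in enumerate(values):
            p = (v >> self.l) + j
            words[p >> 6] |= np.uint64(1) << np.uint64(p & 63)
        self.high = words

    def access(self, j: int) -> int:
        """S[j], 1-based."""
        if not 1 <= j <= self.n:
            raise IndexError(f"index {j} out of [1, {self.n}]")
        # select the j-th set bit of the high bit-vector by scanning words
        remaining = j
        for w, word in enumerate(self.high):
            pc = int(word).bit_count()
            if pc >= remaining:
                word = int(word)
                pos = 0
                while True:
                    if (word >> pos) & 1:
                        remaining -= 1
                        if remaining == 0:
                            break
                    pos += 1
                p = (w << 6) + pos
                return ((p - (j - 1)) << self.l) | int(self.low[j - 1])
            remaining -= pc
        raise RuntimeError("select ran off the high bits")  # pragma: no cover

    def __len__(self) -> int:
        return self.n

    @property
    def bits(self) -> int:
        """Payload bits: n low parts of l bits plus the high bit-vector."""
        return self.n * self.l + self.n + (self.u >> self.l) + 1

    def to_bytes(self) -> bytes:
        bw = BitWriter()
        for v in self.low:
            bw.write(int(v), self.l)
        return (struct.pack("<QQQ", self.n, self.u, self.l)
                + bw.getvalue() + self.high.tobytes())

    @classmethod
    def from_bytes(cls, data: bytes) -> "EliasFano":
        n, u, l = struct.unpack_from("<QQQ", data, 0)
        off = 24
        nlow_bytes = (n * l + 7) // 8
        br = BitReader(data[off:off + nlow_bytes], n * l)
        obj = cls.__new__(cls)
        obj.n, obj.u, obj.l = n, u, l
        obj.low = np.array([br.read(l) for _ in range(n)], dtype=np.uint64)
        obj.high = np.frombuffer(data[off + nlow_bytes:], dtype=np.uint64).copy()
        return obj


class ColorIterator:
    """Cursor over one color; values strictly increase, exhaustion yields N+1."""

    N: int

    def value(self) -> int:
        raise NotImplementedError

    def next(self) -> int:
        raise NotImplementedError

    def next_geq(self, x: int) -> int:
        raise NotImplementedError


class _ListIterator(ColorIterator):
    def __init__(self, values: list[int], N: int) -> None:
        self.vals = values
        self.N = N
        self.i = 0

    def value(self) -> int:
        return self.vals[self.i] if self.i < len(self.vals) else self.N + 1

    def next(self) -> int:
        if self.i < len(self.vals):
            self.i += 1
        return self.value()

    def next_geq(self, x: int) -> int:
        if self.value() < x:
            self.i = bisect_left(self.vals, x, lo=self.i)
        return self.value()


class _ComplementIterator(ColorIterator):
    """Walks [1..N] minus a (decoded) complement list without materializing."""

    def __init__(self, comp: list[int], N: int) -> None:
        self.comp = comp
        self.N = N
        self.cur = 0
        self._advance(1)

    def _advance(self, x: int) -> None:
        ci = bisect_left(self.comp, x)
        y = x
        while ci < len(self.comp) and self.comp[ci] == y:
            ci += 1
            y += 1
        self.cur = y if y <= self.N else self.N + 1

    def value(self) -> int:
        return self.cur

    def next(self) -> int:
        if self.cur <= self.N:
            self._advance(self.cur + 1)
        return self.cur

    def next_geq(self, x: int) -> int:
        if self.cur < x:
            self._advance(x)
        return self.cur


class ColorStore:
    """The M distinct colors in one bit stream + Elias-Fano offset directory."""

    def __init__(self, colors, N: int,
                 materialize_threshold: int = MATERIALIZE_THRESHOLD) -> None:
        self.N = N
        self.M = len(colors)
        self.materialize_threshold = materialize_threshold
        bw = BitWriter()
        offsets = []
        for C in colors:
            offsets.append(bw.nbits)
            write_color(bw, C, N)
        self.data = bw.getvalue()
        self.nbits = bw.nbits
        self.offsets = EliasFano(offsets, max(self.nbits, 1)) if colors else None

    # -- directory -----------------------------------------------------
    def _check_id(self, color_id: int) -> None:
        if not 1 <= color_id <= self.M:
            raise IndexError(f"color id {color_id} out of [1, {self.M}]")

    def _reader_at(self, color_id: int) -> BitReader:
        br = BitReader(self.data, self.nbits)
        br.seek(self.offsets.access(color_id))
        return br

    def bit_length(self, color_id: int) -> int:
        """Encoded bits of one color (tag + cardinality + payload)."""
        self._check_id(color_id)
        start = self.offsets.access(color_id)
        end = self.offsets.access(color_id + 1) if color_id < self.M else self.nbits
        return end - start

    # -- per-color access ----------------------------------------------
    def tag(self, color_id: int) -> str:
        self._check_id(color_id)
        return TAG_NAMES[self._reader_at(color_id).read(2)]

    def cardinality(self, color_id: int) -> int:
        self._check_id(color_id)
        br = self._reader_at(color_id)
        tag = br.read(2)
        if tag == TAG_SPARSE:
            return br.read_delta()
        if tag == TAG_DENSE:
            return self.N - (br.read_delta() - 1)
        return br.read(self.N).bit_count()

    def color(self, color_id: int) -> list[int]:
        self._check_id(color_id)
        return read_color(self._reader_at(color_id), self.N)

    def iterator(self, color_id: int) -> ColorIterator:
        self._check_id(color_id)
        br = self._reader_at(color_id)
        tag = br.read(2)
        if tag == TAG_SPARSE:
            return _ListIterator(_read_sparse_payload(br, br.read_delta()),
                                 self.N)
        if tag == TAG_DENSE:
            comp = _read_sparse_payload(br, br.read_delta() - 1)
            if self.N - len(comp) <= self.materialize_threshold:
                cs = set(comp)
                return _ListIterator(
                    [j for j in range(1, self.N + 1) if j not in cs], self.N)
            return _ComplementIterator(comp, self.N)
        v = br.read(self.N)
        return _ListIterator(
            [j for j in range(1, self.N + 1) if (v >> (self.N - j)) & 1], self.N)

    # -- serialization --------------------------------------------------
    def to_bytes(self) -> bytes:
        ef = self.offsets.to_bytes() if self.offsets else b""
        return (struct.pack("<QQQQ", self.N, self.M, self.nbits, len(ef))
                + ef + self.data)

    @classmethod
    def from_bytes(cls, data: bytes,
                   materialize_threshold: int = MATERIALIZE_THRESHOLD) -> "ColorStore":
        N, M, nbits, eflen = struct.unpack_from("<QQQQ", data, 0)
        obj = cls.__new__(cls)
        obj.N, obj.M, obj.nbits = N, M, nbits
        obj.materialize_threshold = materialize_threshold
        obj.offsets = EliasFano.from_bytes(data[32:32 + eflen]) if eflen else None
        obj.data = data[32 + eflen:]
        return obj
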
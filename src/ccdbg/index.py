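"""The composed color index: dictionary + rank bit-vector + color store.

``ColorIndex`` answers Color(x) for any k-mer by composing

    Lookup(x) -> unitig id  ->  Rank1-based color id  ->  decoded color

and is what the pseudoalignment algorithms operate on. The on-disk format
is a little-endian sectioned container with per-section CRC32 checksums;
a checksum mismatch refuses to load.
"""

from __future__ import annotations

import json
import struct
import zlib
from pathlib import Path

import numpy as np

from .colorrank import ColorRank, build_color_rank
from .colorstore import ColorStore
from .dictionary import DEFAULT_MINIMIZER_SEED, KmerDictionary, build_dictionary
from .graph import CCDBG, ReferenceCollection, build_ccdbg

MAGIC = b"CCDX0001"


class IndexFormatError(Exception):
    pass


class ColorIndex:
    def __init__(self, dictionary: KmerDictionary, color_rank: ColorRank,
                 color_store: ColorStore, ref_names: list[str]) -> None:
        self.dictionary = dictionary
        self.color_rank = color_rank
        self.color_store = color_store
        self.ref_names = ref_names
        self.checksum = "-"  # CRC of the serialized image, set on save/load

    # -- basic facts ----------------------------------------------------
    @property
    def k(self) -> int:
        return self.dictionary.k

    @property
    def w(self) -> int:
        return self.dictionary.w

    @property
    def N(self) -> int:
        return self.color_store.N

    @property
    def n(self) -> int:
        return self.dictionary.n

    @property
    def m(self) -> int:
        return self.dictionary.m

    @property
    def M(self) -> int:
        return self.color_store.M

    @property
    def unitig_lengths(self) -> np.ndarray:
        return np.diff(self.dictionary.starts)

    # -- composed queries ------------------------------------------------
    def color_of_kmer(self, x: str) -> list[int]:
        """Color(x): sorted reference ids containing k-mer x ([] if absent)."""
        hit = self.dictionary.lookup(x)
        if hit is None:
            return []
        return self.color_store.color(self.color_rank.color_id(hit.unitig_id))

    def contains(self, x: str) -> bool:
        return self.dictionary.lookup(x) is not None

    # -- construction ----------------------------------------------------
    @classmethod
    def build(cls, refs: ReferenceCollection, w: int = 15,
              seed: int = DEFAULT_MINIMIZER_SEED) -> "ColorIndex":
        """Single pass over the color-grouped unitigs of the ccdBG."""
        ccdbg = build_ccdbg(refs)
        return cls.from_ccdbg(ccdbg, [name for name, _ in refs.refs], w, seed)

    @classmethod
    def from_ccdbg(cls, ccdbg: CCDBG, ref_names: list[str], w: int = 15,
                   seed: int = DEFAULT_MINIMIZER_SEED) -> "ColorIndex":
        dictionary = build_dictionary(ccdbg, w, seed)
        color_rank = build_color_rank(ccdbg.color_ids())
        color_store = ColorStore(ccdbg.colors, ccdbg.N)
        return cls(dictionary, color_rank, color_store, ref_names)

    # -- serialization ----------------------------------------------------
    def _sections(self) -> list[tuple[str, bytes]]:
        d = self.dictionary
        min_keys = np.array(sorted(d.min_index), dtype=np.int64)
        counts = np.array([len(d.min_index[int(k)]) for k in min_keys],
                          dtype=np.int64)
        pos = (np.concatenate([d.min_index[int(k)] for k in min_keys])
               if len(min_keys) else np.zeros(0, dtype=np.int64))
        return [
            ("names", "\n".join(self.ref_names).encode()),
            ("dict_starts", d.starts.tobytes()),
            ("dict_blob", d.blob.encode()),
            ("dict_min_keys", min_keys.tobytes()),
            ("dict_min_counts", counts.tobytes()),
            ("dict_min_pos", pos.tobytes()),
            ("rank_words", self.color_rank.words.tobytes()),
            ("colors", self.color_store.to_bytes()),
        ]

    def save(self, path) -> None:
        header = {
            "version": 1, "k": self.k, "w": self.w, "N": self.N,
            "m": self.m, "M": self.M, "n": self.n,
            "bit_order": "msb-first", "endian": "little",
            "minimizer_seed": self.dictionary.seed,
        }
        hj = json.dumps(header, sort_keys=True).encode()
        out = bytearray(MAGIC)
        out += struct.pack("<I", len(hj)) + hj
        for name, payload in self._sections():
            nb = name.encode()
            out += struct.pack("<H", len(nb)) + nb
            out += struct.pack("<QI", len(payload), zlib.crc32(payload))
            out += payload
        self.checksum = f"{zlib.crc32(bytes(out)):08x}"
        Path(path).write_bytes(bytes(out))

    @classmethod
    def load(cls, path) -> "ColorIndex":
        data = Path(path).read_bytes()
        if data[:8] != MAGIC:
            raise IndexFormatError("not a color index file (bad magic)")
        off = 8
        (hlen,) = struct.unpack_from("<I", data, off)
        off += 4
        header = json.loads(data[off:off + hlen])
        off += hlen
        sections: dict[str, bytes] = {}
        while off < len(data):
            (nlen,) = struct.unpack_from("<H", data, off)
            off += 2
            name = data[off:off + nlen].decode()
            off += nlen
            plen, crc = struct.unpack_from("<QI", data, off)
            off += 12
            payload = data[off:off + plen]
            off += plen
            if zlib.crc32(payload) != crc:
                raise IndexFormatError(f"checksum mismatch in section {name!r}")
            sections[name] = payload

        starts = np.frombuffer(sections["dict_starts"], dtype=np.int64)
        d = KmerDictionary.__new__(KmerDictionary)
        d.blob = sections["dict_blob"].decode()
        d.starts = starts
        d.k, d.w = header["k"], header["w"]
        d.n = header["n"]
        d.seed = header["minimizer_seed"]
        d.m = len(starts) - 1
        keys = np.frombuffer(sections["dict_min_keys"], dtype=np.int64)
        counts = np.frombuffer(sections["dict_min_counts"], dtype=np.int64)
        pos = np.frombuffer(sections["dict_min_pos"], dtype=np.int64)
        bounds = np.concatenate([[0], np.cumsum(counts)])
        d.min_index = {int(kk): pos[bounds[t]:bounds[t + 1]]
                       for t, kk in enumerate(keys)}

        rank = ColorRank(np.frombuffer(sections["rank_words"], dtype=np.uint64),
                         header["m"], header["M"])
        store = ColorStore.from_bytes(sections["colors"])
        idx = cls(d, rank, store, sections["names"].decode().split("\n"))
        idx.checksum = f"{zlib.crc32(data):08x}"
        return idx


def build_index(ref_path, k: int = 31, w: int = 15, out_path=None,
                seed: int = DEFAULT_MINIMIZER_SEED) -> ColorIndex:
    """Build from a FASTA / file-of-files path; optionally serialize."""
    from .io import load_references

    refs = ReferenceCollection(load_references(ref_path), k=k)
    idx = ColorIndex.build(refs, w=w, seed=seed)
    if out_path is not None:
        idx.save(out_path)
    return idx
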
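"""Low-level k-mer primitives: reverse complement, canonicalization, 2-bit codes.

A *canonical* k-mer is the lexicographic minimum of a k-mer and its reverse
complement. With odd k a k-mer can never equal its own reverse complement,
so the forward/reverse orientation of a canonical form is unambiguous.
"""

from __future__ import annotations

import re

_RC_TABLE = str.maketrans("ACGT", "TGCA")
_NON_ACGT = re.compile(r"[^ACGT]")

#: 2-bit code per nucleotide, A=0 C=1 G=2 T=3 (complement is 3 - code).
CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

_MASK64 = (1 << 64) - 1


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_RC_TABLE)[::-1]


def canonicalize(kmer: str) -> tuple[str, bool]:
    """Return ``(canonical form, is_forward)`` for a k-mer.

    The canonical form is ``min(kmer, revcomp(kmer))``; the flag is True
    iff the forward form is the minimum. Raises ``ValueError`` on symbols
    outside {A,C,G,T}.
    """
    if _NON_ACGT.search(kmer):
        raise ValueError(f"non-ACGT symbol in k-mer {kmer!r}")
    rc = revcomp(kmer)
    if kmer <= rc:
        return kmer, True
    return rc, False


def _canon(kmer: str) -> tuple[str, bool]:
    # validation-free hot path for sanitized internal sequences
    rc = kmer.translate(_RC_TABLE)[::-1]
    if kmer <= rc:
        return kmer, True
    return rc, False


def mix64(x: int, seed: int) -> int:
    """Seeded 64-bit finalizer (splitmix64 style) used for minimizer order."""
    x = (x ^ seed) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def encode2(seq: str) -> int:
    """Pack an A/C/G/T string into a 2-bit-per-base integer (MSB = first base)."""
    v = 0
    for ch in seq:
        v = (v << 2) | CODE[ch]
    return v
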
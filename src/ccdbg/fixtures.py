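"""Synthetic bacterial-pangenome fixtures and read simulation.

``generate_pangenome`` derives N references from one seeded random base
genome by independent point mutations and segment indels per reference.
Because every reference descends from the same base, k-mers from conserved
stretches are shared by most or all references (the >90%-dense colors the
complement trick targets), while mutation-induced k-mers are private or
nearly so — the resulting distinct colors span the full density spectrum.

``simulate_reads`` emits positive reads (substrings of chosen references
with substitution errors) and negative reads (seeded random sequences
rejection-sampled to share no canonical k-mer with the indexed set),
together with a ground-truth table.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .kmers import _canon

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FixtureSpec:
    """Pangenome + read-set parameters; identical specs give identical bytes."""

    n_refs: int = 50
    length: int = 20000  # base genome length
    mutation_rate: float = 0.005  # per-base substitution probability
    indel_rate: float = 0.0005  # per-base indel event probability
    indel_mean_length: float = 10.0  # geometric mean event length
    seed: int = 42
    read_count: int = 1000
    read_length: int = 150
    read_error_rate: float = 0.01
    positive_fraction: float = 0.5

    def __post_init__(self):
        if self.n_refs < 1 or self.length < 1:
            raise ValueError("n_refs and length must be positive")
        for r in (self.mutation_rate, self.indel_rate, self.read_error_rate):
            if not 0 <= r < 1:
                raise ValueError(f"rate {r} outside [0, 1)")
        if self.indel_mean_length < 1:
            raise ValueError("indel_mean_length must be >= 1")
        if not 0 <= self.positive_fraction <= 1:
            raise ValueError("positive_fraction must be in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        return cls(**json.loads(text))


def _random_seq(rng, length: int) -> str:
    return _ALPHABET[rng.integers(0, 4, size=length)].tobytes().decode()


def generate_pangenome(spec: FixtureSpec):
    """Return ``(refs, logs)``: N (name, sequence) pairs and per-reference
    mutation logs (lists of (kind, base-genome position, detail))."""
    rng = np.random.default_rng(spec.seed)
    base = rng.integers(0, 4, size=spec.length).astype(np.uint8)
    refs = []
    logs = []
    for i in range(1, spec.n_refs + 1):
        codes = base.copy()
        log = []
        # substitutions: masked positions move to one of the 3 other bases
        sub_mask = rng.random(spec.length) < spec.mutation_rate
        subs = np.flatnonzero(sub_mask)
        if len(subs):
            shift = rng.integers(1, 4, size=len(subs)).astype(np.uint8)
            codes[subs] = (codes[subs] + shift) % 4
            for p in subs:
                log.append(("sub", int(p), chr(_ALPHABET[codes[p]])))
        # indels: split at event positions, drop or insert segments
        ev = np.flatnonzero(rng.random(spec.length) < spec.indel_rate)
        pieces = []
        cursor = 0
        for p in ev:
            p = int(p)
            if p < cursor:
                continue  # swallowed by a previous deletion
            ln = int(rng.geometric(1.0 / spec.indel_mean_length))
            if rng.random() < 0.5:  # deletion of ln bases at p
                pieces.append(codes[cursor:p])
                cursor = min(p + ln, spec.length)
                log.append(("del", p, ln))
            else:  # insertion of ln random bases after p
                pieces.append(codes[cursor:p])
                pieces.append(rng.integers(0, 4, size=ln).astype(np.uint8))
                cursor = p
                log.append(("ins", p, ln))
        pieces.append(codes[cursor:])
        seq = _ALPHABET[np.concatenate(pieces)].tobytes().decode()
        refs.append((f"ref_{i:03d}", seq))
        logs.append(log)
    return refs, logs


def simulate_reads(refs, kmer_set, k: int, read_length: int = 150,
                   n_reads: int = 1000, positive_fraction: float = 0.5,
                   error_rate: float = 0.01, seed: int = 0,
                   max_rejections: int = 200):
    """Simulate reads against an indexed k-mer set.

    ``kmer_set`` is a container supporting ``in`` over canonical k-mers
    (e.g. the key set of ``extract_kmer_colors``). Returns ``(reads,
    truth)`` where truth rows are dicts with name, ``positive`` flag and
    1-based reference of origin (0 for negatives). Negative reads are
    *verified* to share no canonical k-mer with the index; exceeding
    ``max_rejections`` retries raises ``RuntimeError``.
    """
    if read_length < k:
        raise ValueError(f"read_length {read_length} < k={k}")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_reads * positive_fraction))
    reads, truth = [], []
    eligible = [i for i, (_, s) in enumerate(refs) if len(s) >= read_length]
    if n_pos and not eligible:
        raise ValueError("no reference long enough for positive reads")
    for t in range(n_reads):
        if t < n_pos:
            ri = int(eligible[rng.integers(0, len(eligible))])
            seq = refs[ri][1]
            start = int(rng.integers(0, len(seq) - read_length + 1))
            arr = np.frombuffer(seq[start:start + read_length].encode(),
                                dtype=np.uint8).copy()
            errs = np.flatnonzero(rng.random(read_length) < error_rate)
            if len(errs):
                lut = np.zeros(256, dtype=np.uint8)
                for j, b in enumerate(b"ACGT"):
                    lut[b] = j
                codes = lut[arr[errs]]
                arr[errs] = _ALPHABET[(codes + rng.integers(1, 4, size=len(errs))) % 4]
            read = arr.tobytes().decode()
            name = f"read_{t:05d}_pos_ref{ri + 1}"
            truth.append({"name": name, "positive": True, "origin": ri + 1})
        else:
            for attempt in range(max_rejections):
                read = _random_seq(rng, read_length)
                if all(_canon(read[i:i + k])[0] not in kmer_set
                       for i in range(read_length - k + 1)):
                    break
            else:
                raise RuntimeError("could not sample an index-disjoint negative read")
            name = f"read_{t:05d}_neg"
            truth.append({"name": name, "positive": False, "origin": 0})
        reads.append((name, read))
    return reads, truth
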
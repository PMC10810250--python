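"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (plain dicts, sliding windows,
linear scans) and shares no code path with the package internals beyond
the DNA alphabet itself.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(s: str) -> str:
    return "".join(_COMP[ch] for ch in reversed(s))


def canon(s: str) -> str:
    r = rc(s)
    return s if s <= r else r


def naive_kmer_colors(refs, k: int) -> dict[str, list[int]]:
    """Slide a window over each reference, canonicalize, accumulate ids."""
    out: dict[str, set[int]] = {}
    for rid, (_, seq) in enumerate(refs, start=1):
        for i in range(len(seq) - k + 1):
            out.setdefault(canon(seq[i:i + k]), set()).add(rid)
    return {x: sorted(s) for x, s in out.items()}


def cutpoint_unitigs(refs, k: int) -> set[str]:
    """Definitional unitig oracle: walk every reference, cut between
    consecutive k-mers at branches (degree != 1 at the junction), color
    changes, or reference-boundary sentinels; collect maximal uncut runs
    and deduplicate by canonical spelling."""
    colors = naive_kmer_colors(refs, k)
    nodes = set(colors)

    def outdeg(x: str) -> int:  # oriented k-mer as written
        return sum(canon(x[1:] + b) in nodes for b in "ACGT")

    def indeg(x: str) -> int:
        return sum(canon(b + x[:-1]) in nodes for b in "ACGT")

    # global sentinel marks: (canonical k-mer, side of its canonical form)
    marks: set[tuple[str, str]] = set()
    for _, seq in refs:
        if len(seq) < k:
            continue
        x = seq[:k]
        marks.add((canon(x), "L" if x == canon(x) else "R"))
        x = seq[-k:]
        marks.add((canon(x), "R" if x == canon(x) else "L"))

    def cut_between(x: str, y: str) -> bool:
        if colors[canon(x)] != colors[canon(y)]:
            return True
        if outdeg(x) != 1 or indeg(y) != 1:
            return True
        if (canon(x), "R" if x == canon(x) else "L") in marks:
            return True
        if (canon(y), "L" if y == canon(y) else "R") in marks:
            return True
        return False

    spells: set[str] = set()
    for _, seq in refs:
        if len(seq) < k:
            continue
        run_start = 0
        for i in range(len(seq) - k):
            if cut_between(seq[i:i + k], seq[i + 1:i + 1 + k]):
                spells.add(canon(seq[run_start:i + k]))
                run_start = i + 1
        spells.add(canon(seq[run_start:]))
    return spells


def delta_code_length(v: int) -> int:
    """Bit length of the Elias delta code of v >= 1, from the definition."""
    lb = math.floor(math.log2(v))
    llb = math.floor(math.log2(lb + 1))
    return 2 * llb + 1 + lb


def hybrid_payload_length(C, N: int) -> int:
    """Expected header+payload bit length of the hybrid color encoding."""
    size = len(C)

    def sparse_bits(vals):
        total = 0
        prev = 0
        for j, v in enumerate(vals):
            total += delta_code_length(v if j == 0 else v - prev)
            prev = v
        return total

    if 4 * size < N:
        return delta_code_length(size) + sparse_bits(C)
    if 4 * size > 3 * N:
        comp = [j for j in range(1, N + 1) if j not in set(C)]
        return delta_code_length(len(comp) + 1) + sparse_bits(comp)
    return N


def next_geq_oracle(C, x: int, N: int) -> int:
    """min{y in C : y >= x}, sentinel N+1 otherwise, by linear scan."""
    for y in C:
        if y >= x:
            return y
    return N + 1


def naive_full_intersection(kmer_colors, seq: str, k: int) -> list[int]:
    """Intersect Color(x) over every present k-mer of the read."""
    acc = None
    for i in range(len(seq) - k + 1):
        c = kmer_colors.get(canon(seq[i:i + k]))
        if c is not None:
            acc = set(c) if acc is None else acc & set(c)
    return sorted(acc) if acc else []


def naive_threshold_union(kmer_colors, seq: str, k: int, tau, s_mode) -> list[int]:
    """Tally reference occurrences over per-k-mer colors; keep refs with
    tally >= ceil(s * tau) using exact rational arithmetic."""
    from fractions import Fraction

    n_kmers = len(seq) - k + 1
    tally: dict[int, int] = {}
    n_pos = 0
    for i in range(n_kmers):
        c = kmer_colors.get(canon(seq[i:i + k]))
        if c is not None:
            n_pos += 1
            for r in c:
                tally[r] = tally.get(r, 0) + 1
    if n_pos == 0:
        return []
    s = n_pos if s_mode == "positive" else n_kmers
    frac = Fraction(tau).limit_denominator(10 ** 6)
    t = max(1, -((-s * frac.numerator) // frac.denominator))
    return sorted(r for r, cnt in tally.items() if cnt >= t)
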
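"""Colored compacted de Bruijn graph (ccdBG) construction.

Nodes of the node-centric de Bruijn graph are the distinct canonical k-mers
of a reference collection; each node carries a *color*, the sorted set of
reference ids containing it. Non-branching same-color paths are collapsed
into unitigs. Unitigs here are

* **maximal** — extension stops at a topological branch, at a color change,
  or at a *sentinel* boundary (a k-mer occurring at the start or end of a
  reference fragment terminates its unitig, which is what makes unitigs
  monochromatic in the first place);
* **monochromatic** — all k-mers of a unitig share one color;
* **a tiling** of every reference: gluing the per-reference sequence of
  unitig occurrences with (k-1)-overlaps re-spells the reference exactly.

The final layout groups unitigs by color id, the property the rank-based
unitig->color map (see :mod:`ccdbg.colorrank`) relies on.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from .kmers import _canon, revcomp

_SPLIT_NON_ACGT = re.compile(r"[^ACGT]+")

_BASES = "ACGT"


@dataclass
class ReferenceCollection:
    """The ordered references R_1..R_N and the k-mer length.

    Sequences are upper-cased on construction; runs of ambiguous (non-ACGT)
    symbols split a reference into sentinel-bounded fragments that keep the
    same reference id. Reference ids are 1..N in input order.
    """

    refs: list[tuple[str, str]]
    k: int = 31

    def __post_init__(self) -> None:
        if not self.refs:
            raise ValueError("empty reference collection")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"k must be a positive odd integer, got {self.k}")
        self.refs = [(name, seq.upper()) for name, seq in self.refs]

    @property
    def N(self) -> int:
        return len(self.refs)

    def fragments(self):
        """Yield ``(ref_id, fragment)`` with ref_id in 1..N, ACGT-only pieces."""
        for rid, (_, seq) in enumerate(self.refs, start=1):
            for frag in _SPLIT_NON_ACGT.split(seq):
                if frag:
                    yield rid, frag


@dataclass
class Unitig:
    id: int  # 1..m in the color-sorted layout
    sequence: str  # canonical spelling (min of the two strands), length >= k
    color_id: int  # 1..M


@dataclass
class CCDBG:
    """The compacted graph: color-sorted unitigs, distinct colors, tilings."""

    unitigs: list[Unitig]
    colors: list[tuple[int, ...]]  # colors[j-1] is color id j, sorted ref ids
    tilings: list[list[list[tuple[int, bool]]]]  # per ref, per fragment: (uid, fwd)
    n: int  # number of distinct canonical k-mers
    k: int
    N: int

    @property
    def m(self) -> int:
        return len(self.unitigs)

    @property
    def M(self) -> int:
        return len(self.colors)

    def color_ids(self) -> list[int]:
        return [u.color_id for u in self.unitigs]

    def reconstruct(self, ref_id: int) -> list[str]:
        """Re-spell the fragments of reference ``ref_id`` from its tiling."""
        out = []
        for occs in self.tilings[ref_id - 1]:
            s = ""
            for uid, fwd in occs:
                spell = self.unitigs[uid - 1].sequence
                if not fwd:
                    spell = revcomp(spell)
                s = spell if not s else s + spell[self.k - 1:]
            out.append(s)
        return out


def extract_kmer_colors(refs: ReferenceCollection) -> dict[str, list[int]]:
    """Map every distinct canonical k-mer to its sorted list of reference ids.

    A reference id appears at most once per color even if the k-mer occurs
    several times in that reference. Returns an empty map (with a warning)
    when no fragment reaches length k.
    """
    k = refs.k
    out: dict[str, set[int]] = {}
    any_kmer = False
    for rid, frag in refs.fragments():
        if len(frag) < k:
            continue
        any_kmer = True
        for i in range(len(frag) - k + 1):
            c, _ = _canon(frag[i:i + k])
            s = out.get(c)
            if s is None:
                out[c] = {rid}
            else:
                s.add(rid)
    if not any_kmer:
        warnings.warn(f"k={k} exceeds every reference length; empty k-mer map")
    return {x: sorted(s) for x, s in out.items()}


def _oriented(kmer: str, fwd: bool) -> str:
    return kmer if fwd else revcomp(kmer)


class _Compactor:
    """Greedy bidirected compaction over canonical k-mer nodes."""

    def __init__(self, color_of: dict[str, tuple[int, ...]], boundary: set, k: int):
        self.color_of = color_of
        self.boundary = boundary
        self.k = k
        self._succ: dict[str, list] = {}
        self._pred: dict[str, list] = {}

    def succ(self, c: str):
        s = self._succ.get(c)
        if s is None:
            s = []
            suf = c[1:]
            for b in _BASES:
                t, fwd = _canon(suf + b)
                if t in self.color_of:
                    s.append((t, fwd))
            self._succ[c] = s
        return s

    def pred(self, c: str):
        p = self._pred.get(c)
        if p is None:
            p = []
            pre = c[:-1]
            for b in _BASES:
                t, fwd = _canon(b + pre)
                if t in self.color_of:
                    p.append((t, fwd))
            self._pred[c] = p
        return p

    def right_cands(self, c: str, fwd: bool):
        if fwd:
            return self.succ(c)
        return [(t, not to) for (t, to) in self.pred(c)]

    def left_cands(self, c: str, fwd: bool):
        if fwd:
            return self.pred(c)
        return [(t, not to) for (t, to) in self.succ(c)]

    def extend_right(self, c: str, fwd: bool):
        """The unique admissible right extension of oriented node (c, fwd), or None."""
        if (c, "R" if fwd else "L") in self.boundary:
            return None
        rc_ = self.right_cands(c, fwd)
        if len(rc_) != 1:
            return None
        t, to = rc_[0]
        if t == c:
            return None  # self loop
        if (t, "L" if to else "R") in self.boundary:
            return None
        if len(self.left_cands(t, to)) != 1:
            return None
        if self.color_of[t] != self.color_of[c]:
            return None
        return t, to


def build_ccdbg(refs: ReferenceCollection) -> CCDBG:
    """Build the ccdBG: monochromatic maximal unitigs, colors, tilings.

    Deterministic layout: distinct colors are assigned ids 1..M sorted by
    (cardinality, lexicographic content); within a color id, unitigs are
    ordered by their canonical spelling.
    """
    k = refs.k
    colors_map = extract_kmer_colors(refs)
    color_of = {x: tuple(c) for x, c in colors_map.items()}
    if not color_of:
        return CCDBG([], [], [[] for _ in range(refs.N)], 0, k, refs.N)

    # sentinel boundary sides, in canonical-node coordinates
    boundary: set[tuple[str, str]] = set()
    for _, frag in refs.fragments():
        if len(frag) < k:
            continue
        c, fwd = _canon(frag[:k])
        boundary.add((c, "L" if fwd else "R"))
        c, fwd = _canon(frag[-k:])
        boundary.add((c, "R" if fwd else "L"))

    comp = _Compactor(color_of, boundary, k)
    visited: set[str] = set()
    spellings: list[str] = []
    for c in sorted(color_of):
        if c in visited:
            continue
        inpath = {c}
        # walk left of (c, fwd) == right of (c, rev)
        left = []
        cur, fwd = c, False
        while True:
            nxt = comp.extend_right(cur, fwd)
            if nxt is None or nxt[0] in inpath:
                break
            cur, fwd = nxt
            left.append(nxt)
            inpath.add(cur)
        chain = [(t, not to) for (t, to) in reversed(left)] + [(c, True)]
        cur, fwd = chain[-1]
        while True:
            nxt = comp.extend_right(cur, fwd)
            if nxt is None or nxt[0] in inpath:
                break
            cur, fwd = nxt
            chain.append(nxt)
            inpath.add(cur)
        visited |= inpath
        spell = _oriented(*chain[0])
        for t, to in chain[1:]:
            spell += _oriented(t, to)[-1]
        spellings.append(min(spell, revcomp(spell)))

    # deterministic color ids and color-grouped unitig layout
    unitig_color = []
    for s in spellings:
        c0, _ = _canon(s[:k])
        unitig_color.append(color_of[c0])
    distinct = sorted(set(unitig_color), key=lambda t: (len(t), t))
    cid_of = {t: j + 1 for j, t in enumerate(distinct)}
    order = sorted(range(len(spellings)),
                   key=lambda i: (cid_of[unitig_color[i]], spellings[i]))
    unitigs = [Unitig(j + 1, spellings[i], cid_of[unitig_color[i]])
               for j, i in enumerate(order)]

    # exact k-mer -> (unitig, offset, canonical-forward) map; totality check
    kmap: dict[str, tuple[int, int, bool]] = {}
    for u in unitigs:
        for off in range(len(u.sequence) - k + 1):
            c, fwd = _canon(u.sequence[off:off + k])
            if c in kmap:
                raise RuntimeError(f"k-mer assigned to two unitigs: {c}")
            kmap[c] = (u.id, off, fwd)
    if len(kmap) != len(color_of):
        missing = len(color_of) - len(kmap)
        raise RuntimeError(f"{missing} k-mers missing from the unitig set")

    # per-reference tilings: walk fragments, one entry per unitig occurrence
    tilings: list[list[list[tuple[int, bool]]]] = [[] for _ in range(refs.N)]
    for rid, frag in refs.fragments():
        if len(frag) < k:
            continue
        occs: list[tuple[int, bool]] = []
        pos = 0
        last = len(frag) - k
        while pos <= last:
            c, fx = _canon(frag[pos:pos + k])
            uid, off, fu = kmap[c]
            fwd = fx == fu  # unitig read in forward orientation here
            ulen = len(unitigs[uid - 1].sequence)
            span = (ulen - k - off + 1) if fwd else (off + 1)
            occs.append((uid, fwd))
            pos += span
        tilings[rid - 1].append(occs)

    return CCDBG(unitigs, distinct, tilings, len(color_of), k, refs.N)
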
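# Methods

## Model

The package solves the colored k-mer indexing problem: given references
R₁..R_N over {A,C,G,T}, retrieve Color(x) = {i | x ∈ Rᵢ} for any k-mer x.
K-mers are indexed *canonically* (the lexicographic minimum of a k-mer and
its reverse complement); k is required to be odd so a k-mer can never be
its own reverse complement and orientation is always well defined.

The node-centric de Bruijn graph over the distinct canonical k-mers is
compacted into **unitigs** under three cut conditions: a topological
branch (a junction whose in- or out-degree differs from one, counting all
four possible extensions against the node set), a color change, and a
**sentinel** boundary — a k-mer occurring at the start or end of a
reference fragment terminates its unitig. Sentinel termination is adopted
because monochromaticity of unitigs holds only under it; some tools omit
it, and we deliberately do not. The resulting unitigs partition the k-mer
set (Σ(|uᵢ|−k+1) = n), are monochromatic, and tile every reference:
gluing a reference's ordered unitig occurrences with (k−1)-overlaps
reproduces it byte-for-byte. Non-ACGT symbols split a reference into
sentinel-bounded fragments sharing its reference id, so no base is ever
invented; fragments shorter than k are recorded but contribute nothing.

Determinism of the layout is a contract, not an accident: distinct colors
get ids 1..M sorted by (cardinality, lexicographic content); within a
color id, unitigs are ordered by canonical spelling. Two builds of the
same input are byte-identical, including the serialized index.

## Index components

**Dictionary.** Unitig spellings are concatenated in the color-sorted
order (the order-preserving property that makes the rank mapping work).
Every w-mer occurrence is bucketed under its strand-canonical 2-bit code;
a query k-mer selects its minimizer — the w-mer minimizing a seeded
splitmix64-style hash of the canonical code — and verifies each candidate
site by direct string comparison, so lookup is exact regardless of bucket
collisions (no false positives or negatives). The hash seed is a fixed
constant stored in the index header. Streaming queries test the cached
(unitig, offset±1) position first — one string comparison — and only fall
back to minimizer search on a mismatch; a miss clears the position cache
but keeps the last minimizer bucket. The cache-hit counter is part of the
public surface because the streaming/batch equivalence tests rely on it.
There is no 2-bit packing of the text and no minimal perfect hashing: at
the scales this package targets, plain byte strings keep the code simple
and the contract identical.

**Unitig → color id.** A bit-vector B[1..m] with a bit at the last unitig
of each color group and at position m (so popcount(B) = M exactly);
Color-ID(uᵢ) = Rank₁(i,B) + 1 with Rank₁(i,B) counting ones in B[1,i).
Rank uses one absolute count per 512-bit superblock plus on-the-fly word
popcounts — O(1) with o(m) overhead. The API speaks the 1-based, half-open
convention of the formula even though arrays are 0-based internally.

**Color store.** Density routing with strict thresholds: |C|/N < 1/4 →
sparse (Elias-δ of the first id, then δ of gaps; ids start at 1 so no +1
shift is needed); |C|/N > 3/4 → the complement set, sparse-coded;
boundaries and the middle band → characteristic bit-vector of N bits. The
per-color header is the 2-bit tag plus a δ-coded count of the *stored*
elements: the cardinality for sparse colors, the complement cardinality
plus one for dense colors, and no count for bit-vectors (N payload bits
are self-delimiting). Counting stored rather than logical elements is a
deliberate choice: a δ-coded cardinality would cost ~11 bits on a
near-full color whose payload is a handful of bits, and at small N that
header overhead alone pushes the hybrid scheme past the M·N bits of an
all-bitvector encoding — defeating the point of the complement trick. With
this header a full color costs 3 bits total. Bit order is MSB-first within
bytes, fixed in the header, so serialization is bit-exact across
platforms. The offsets directory is Elias-Fano with ℓ = max(0,
⌊log₂(u/M)⌋) low bits and an in-word-scan select over the high bits (no
select directory; M is modest here). Dense-complement iterators
materialize the color when its cardinality is ≤ 65,536 (always, at desk
scale) and otherwise walk the complement lazily; both paths expose
identical Value/Next/Next-GEQ semantics and are exercised by tests via the
materialization threshold.

## Query algorithms

**Full-intersection** streams all k-mers, deduplicates unitig ids, maps
them to distinct color ids, and leapfrogs the iterators: the running
candidate advances via Next-GEQ and is emitted when all p iterators agree;
the loop aborts as soon as the candidate exceeds N.

**Threshold-union** scores each positive k-mer's unitig with 1, sums
scores of equal unitig ids and then of equal color ids, and keeps
references whose accumulated score reaches ⌈s·τ⌉, computed by exact
integer ceiling after converting τ to a rational
(`Fraction(tau).limit_denominator(10**6)`) — a float comparison would
mis-handle exact ties such as s = 5, τ = 0.8. s counts positive k-mers
(`positive`, the default) or all |Q|−k+1 k-mers (`all`); absent k-mers
contribute to neither s nor any score in `positive` mode. The union is a
heap merge over scored iterators. τ defaults to 0.8.

**Skipping heuristics.** A hit at (unitig u, offset j, orientation)
triggers a jump to the k-mer where u's occurrence on the read should end —
for a reverse-orientation hit the "end" of u is its beginning in unitig
coordinates — capped at the read end. On a jump that misses the index:
`query-next` advances one position past the landing; `back-off` halves the
jump iteratively (minimum step 1, at most `back_off_limit` attempts,
then falls through to query-next). On a landing in a different unitig:
`query-next`, `back-off`, or `aggressive-jump` (re-jump to the implied end
of the unexpected unitig). Two presets: `kallisto-like` = (query-next,
aggressive-jump) and `backoff-like` = (back-off, back-off, limit 4). Every
positive k-mer actually queried is *confirmed*, including unexpected-unitig
landings under back-off, and the result is exactly the intersection of the
colors of the distinct confirmed unitigs — an instrumented trace records
confirmed positions and the query count so this is testable. Per-read
memoization of query positions guarantees at most |Q|−k+1 dictionary
queries and termination under every policy. These presets implement the
scenario-level behaviors, not any external tool's exact source-level
rules, and may legitimately differ from full-intersection on multi-unitig
reads.

**Two-pass batch mode** computes each read's sorted distinct color-id
list (dictionary + rank only), collates identical lists in lexicographic
order, intersects each distinct non-empty list once, and fans results back
in input order. The output — including diagnostics — is identical to
single-pass full-intersection by construction; only the intersection count
changes (= the number of distinct non-empty lists). Empty lists never
reach pass 2. Lists are held in memory; there is no spill-to-disk.

## Synthetic data

`generate_pangenome` emulates a bacterial pangenome: a seeded random base
genome of length L; each of N references applies independent point
mutations (per-base probability μ) and indel events (per-base event
probability, geometric lengths), with ground-truth logs. Defaults — N =
50, L = 20,000, μ = 0.005, indel rate 5·10⁻⁴, mean indel length 10 —
give per-reference divergence of roughly 0.5%, typical of a
within-species bacterial collection, and produce colors across the full
density spectrum: conserved k-mers survive in ~0.995³¹ ≈ 86% of
references (dense, where the complement trick applies), mutation-induced
k-mers are private (sparse), and the binomial spread plus indel
boundaries populate the middle band. The representation census on the
seed-42 fixture confirms all three tags occur.

What the generator does **not** emulate: real gene content variation
(everything is a single-copy mutated clone, so there are no
horizontally-transferred segments or repeats beyond chance), realistic
base composition, structural rearrangements, or sequencing-quality
profiles (read errors are uniform substitutions). Passing tests therefore
demonstrate algorithmic correctness and the intended density-routing
behavior, not biological performance claims on real pangenomes. Negative
reads are seeded random sequences rejection-sampled (bounded retries) to
share no canonical k-mer with the index — disjointness is verified, not
assumed — standing in for reads from an unrelated genome.

Problem sizes used by the test suite — an 8-reference, 500 bp toy (k =
15) for the 1,000–5,000-read oracle batteries and the 50-reference,
20 kb collection (k = 31) for structural and space invariants — were
chosen so the whole suite completes in about a minute while still
exercising every representation and query path.

## Numerical and degenerate-input choices

* Ties in minimizer hashes break to the leftmost window; hash collisions
  are harmless (verification is exact).
* Colors at exactly 1/4 or 3/4 density use the bit-vector representation
  (the sparse/dense rules are strict inequalities).
* An empty reference collection is a hard error; k exceeding every
  reference yields an empty index plus a warning; reads shorter than k
  return the empty "too short" result; p = 0 iterators to `intersect` is
  an error (the callers decide the empty-query convention and return
  unmapped).
* Duplicate reference sequences keep distinct ids — real collections
  contain near-duplicates and deduplication would change colors.
* The index file is little-endian, sectioned, CRC32-checksummed per
  section; any mismatch refuses to load. Identical inputs produce
  byte-identical files.

## Known limitations

Construction is in-memory and single-threaded; the dictionary stores
plain byte strings, so its space is nowhere near succinct — space claims
here concern the color store and the rank mapping only. Locate
(position-reporting) queries, co-linearity constraints, and
similarity-based color compression (MST/clustering of colors) are out of
scope. The two-pass optimization applies to full-intersection only.
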
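# Methods

## Problem and model

fpsim searches collections of dense binary molecular fingerprints — fixed
length bit vectors such as 166-bit MACCS keys, 881-bit PubChem/CACTVS keys,
or 1024/2048-bit hashed circular fingerprints — for near neighbors of a
query fingerprint. Similarity is the Tanimoto (Jaccard) coefficient

    Tanimoto(fp1, fp2) = |fp1 ∩ fp2| / |fp1 ∪ fp2| = c / (A + B − c)

where `A` and `B` are the popcounts (numbers of set bits) of the two
fingerprints and `c` is the popcount of their intersection, or the Tversky
generalization

    Tversky(fp1, fp2; α, β) = c / (α(A − c) + β(B − c) + c)

in which `α` weights bits unique to the query and `β` bits unique to the
target; `α = β = 1` recovers the Tanimoto. Two all-zero fingerprints score
0 by convention (in both measures), and a fingerprint with itself scores
exactly 1.

Two search modes are supported: *threshold* search (all targets with score
≥ T) and *k-nearest* search (the k best-scoring targets, optionally above a
minimum threshold), in single-query, multiquery, streaming file-scan and
symmetric all-pairs (N×N, diagonal excluded) variants.

## Bit and byte conventions

Bit `k` of a fingerprint is bit `k mod 8` of byte `⌊k/8⌋` (little-endian
bytes, LSB-first within a byte). In the hex text encoding — two characters
per byte, bytes in order — "0100" has only bit 0 set, "2000" only bit 5,
and "c218" bits {1, 6, 7, 11, 12}. Fingerprint types whose length is not a
multiple of 8 (166, 881, 1021 bits) zero-pad the high bits of the last
byte.

## The arena and BitBound pruning

An *arena* stores all fingerprints in one contiguous block, one slot per
record, each slot zero-padded to a multiple of 8 bytes so the block can be
processed as 64-bit words. Sorted arenas order records by popcount and keep
a bin index of length `num_bits + 2`: records with popcount `b` occupy
indices `popcount_index[b] .. popcount_index[b+1] − 1` (empty bins have
equal boundaries). Sorting means the target popcount `B` is a per-bin
constant, so each comparison needs a single intersection popcount, and it
enables *BitBound* pruning: a hit at threshold `t` against a query of
popcount `A` must satisfy `A·t ≤ B ≤ A/t`, so whole bins outside that range
are skipped without being read.

Within the admitted bins, a candidate is accepted iff its intersection
popcount reaches the per-bin minimum

    c ≥ ⌈ T(A + B) / (1 + T) ⌉ ,

evaluated exactly (see below), which replaces the per-candidate division by
one integer comparison. Division is only used afterwards, to report scores.

k-nearest search visits bins in decreasing order of their best possible
score `min(A,B)/max(A,B)`, merging the two monotonically decreasing sides
below and above `A` in constant memory, and keeps the best k candidates in
a bounded min-heap keyed by exact rational score. It stops when the k-th
best score strictly exceeds the bound of the next unvisited bin; at
equality the bin is still visited, because it may contain an equal-scoring
candidate with a smaller index and the documented tie-break is ascending
target index. A counting-sort variant buckets hits by their exact score —
Tanimoto values are ratios of small integers, so few distinct values occur
— and has an identical result contract.

Unsorted arenas are supported (they preserve input order, e.g. for
aggregation files); searches on them fall back to a full linear scan with
the same exact decision rules.

## Exact arithmetic

Every accept/reject decision is made in integer arithmetic; floating point
appears only in reported scores. A threshold given as a double (or decimal
text, converted to its nearest double first — so a written-out
`0.7 + 1e-17` is indistinguishable from `0.7`) is decomposed into the exact
integer fraction `p/q` that every finite double is; the denominator is
capped at 2^62 (flooring, reachable only for subnormal-scale thresholds).
Because the fraction is exact, the rejection test `c·q ≥ p·(A + B − c)` is
also the acceptance test. The vectorized kernels evaluate the equivalent
per-bin bound `⌈p(A+B)/(p+q)⌉` with Python big integers and then compare in
int64, since `c·q` itself can exceed the int64 range.

Tversky weights are limited to [0, 10], scaled by 10,000 and rounded to
integers (a warning is issued beyond 4 decimal digits — there is no
chemical justification for more precision); the score is a single final
division of integers. This makes self-similarity exactly 1.0 and removes
the non-distributivity artifacts of IEEE arithmetic. Tversky search does
not use BitBound: the Tanimoto bin bounds are not valid for asymmetric
weights, so a linear scan with the exact integer test (the denominator is
linear in `c`, so the threshold inequality inverts to a per-bin bound on
`c`) is used — correctness over speed.

## File formats

*FPS* is a line-oriented text format: an optional `#FPS1` version line,
`#key=value` metadata lines (`num_bits`, `type`, `software`, `source`×N,
`date`; unknown keys are preserved, un-parseable `#` lines carried as
comments), then one record per line: lowercase hex fingerprint, a tab, the
id, and optional further tab-separated fields (preserved on pass-through).
Reading is validating — every line is checked and errors carry the line
number. gzip compression is detected by magic bytes or a `.gz` suffix.
`num_bits` absent is inferred as 8 × the first record's byte length.
Duplicate ids are legal; empty ids are rejected.

*FPB* is a chunked binary container for fast, lazy loading: an 8-byte
signature (`FPB1\r\n\0\0`) then chunks of (u64 length, 4-char tag,
payload) ending at `FEND`. META holds the FPS header lines verbatim; AREN
the contiguous fingerprint block (with a spacer aligning the first
fingerprint to 8 bytes, or 64 when the slot size is a multiple of 64, so a
memory-mapped load is word-aligned); POPC the popcount bin boundaries;
FPID the UTF-8 ids with a u32 cumulative offset table; HASH a classic cdb
two-level hash table mapping id → record indices (multi-valued, u32
values — hence a design ceiling of 2^31−1 records). Unknown chunks are
skipped. The byte-level encodings are this package's own dialect; no
wire compatibility with other FPB writers is claimed. Opening a file reads
only the chunk directory and META; fingerprints, ids and hash lookups
resolve against the memory map on demand, and lazy and eager loads give
identical search results.

`collated_write` builds an FPB file from a stream larger than memory: it
spills popcount-sorted runs of at most `memory_budget` bytes to temporary
FPB files and merges them bin by bin. The merged file is byte-compatible
with a direct write except that id order *within* one popcount bin follows
first-seen run order. Ids are held in memory during the merge (they are
small relative to the fingerprints, which dominate the budget).

## Synthetic data

The generator produces fingerprint sets of any size with three density
models, deterministically per seed:

* **uniform** — each bit set independently with probability `p`
  (popcounts Binomial). Defaults per length: 0.25 at 166 bits
  (MACCS-like), 0.12 at 881/1021 bits, 0.024 at 2048 bits (the measured
  density of ChEMBL Morgan fingerprints); other lengths default to 0.1.
* **histogram** — an explicit popcount histogram, realized exactly.
* **clustered** — records are per-bit mutations (default flip probability
  0.01) of a fixed pool of cluster centers. Real compound collections are
  heavily redundant — similar series and outright duplicate fingerprints —
  and that redundancy is what makes the nearest-neighbor similarity grow
  with collection size and k-nearest BitBound search scale sublinearly.
  Independent uniform fingerprints lack this structure entirely: under the
  uniform model the measured k = 1 scaling exponent is 1.0 (a full scan of
  the admitted bins), which is the expected behaviour, not a defect.
  Sublinearity is therefore demonstrated with the clustered model, with
  queries drawn from the same center pool, mirroring benchmark practice of
  sampling queries from the data set.

No de-duplication is performed anywhere; duplicate fingerprints occur
naturally and are searched as-is.

## Benchmark harness

The task suite mirrors common benchmarking practice: threshold search at
0.4 (sparse Morgan-like sets — everything above background similarity) or
0.7 (denser types — a typical "good similarity" search), and k-nearest for
k = 1 and k = 1000. Wall times are reported but never asserted (hardware
dependent); the asserted surface is the deterministic instrumentation: the
number of intersection-popcount (Tanimoto) evaluations surviving BitBound,
the number of candidates passing the integer rejection test (each needing
one division to report its score), and effective bytes examined
(evaluations × slot size). At threshold 1.0 the evaluation count equals the
size of each query's own popcount bin; at threshold 0 it equals
queries × targets.

## Problem sizes and test design

The test suite runs at desk scale, chosen once: the search-correctness
suite compares BitBound-pruned results against an independent big-integer
linear-scan oracle with exact rational scoring over 4 bit sizes
(166/881/1021/2048) × 100 queries × 1000 targets × three thresholds and
three k values (≈ 2.4 million query–target comparisons); the scaling check
uses clustered 166-bit sets of 10^4–10^5 records with 30 queries at k = 1
and asserts only that the fitted log–log slope is below 1. Property tests
(hypothesis, derandomized) cover codec round trips and format round trips;
the per-bit loop popcount kernel serves as the oracle for the word-chunked
default kernel.

## Numerical and design choices

* Threshold-mode hit order is ascending target index (file order for
  scans); k-nearest ties break by ascending index. Both are documented
  contracts so oracle tests can assert them exactly.
* Multiquery search may group execution by query popcount
  (`sort_queries=True`, better temporal cache locality) and may use
  threads; per-query results are bit-identical regardless of worker count
  or execution order, and output order always matches input order.
* The symmetric N×N threshold search computes the upper triangle only —
  for row i, the scan window starts at max(bin start, i+1) — and mirrors
  it; the diagonal is never computed. The result is a
  `scipy.sparse.csr_matrix` of scores.
* k-nearest file scans may stop reading (and therefore stop validating the
  remainder of the file) once every query has k exact matches; threshold
  scans always validate the whole file.
* A k-nearest `min_threshold` is applied as a hard filter before
  selection.
* The `--pubchem` convenience decoder in sdf2fps (base64 with a 4-byte
  big-endian bit-length prefix) is flagged experimental: the tag name is
  standard, its encoding is not formally specified here.

## Known limitations

* No CPU-specific popcount kernels (POPCNT/AVX2), no memory prefetching,
  and no Morton-order multiquery traversal; the kernel registry is the
  extension point. Absolute throughput is therefore not comparable to
  optimized C implementations, but candidate counts and result sets are.
* FPB files are not wire-compatible with other tools' FPB files.
* Tversky search is a linear scan (no pruning bounds).
* The synthetic models approximate real fingerprint ensembles only at the
  level of density and redundancy; they carry no bit-position correlations,
  so conclusions about sparse-method competitiveness or absolute pruning
  rates on real data should not be drawn from them.
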
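"""Popcount-sorted fingerprint arenas and BitBound-pruned similarity search.

A *fingerprint arena* stores equal-length fingerprints in one contiguous,
zero-padded memory block, usually sorted by popcount.  The popcount index
``popcount_index`` (length ``num_bits + 2``) records the bin boundaries:
fingerprints with popcount ``b`` occupy indices
``popcount_index[b] <= i < popcount_index[b+1]``, with empty bins having
equal adjacent boundaries.  Sorting buys two things: the target popcount
``B`` is known per bin without per-record storage, and the *BitBound*
pruning rule — a hit at threshold ``t`` against a query with popcount ``A``
must have ``A*t <= B <= A/t`` — skips whole bins.

Within a candidate bin, a division-free rejection test compares the
intersection popcount ``c`` against the minimum required popcount
``ceil(T*(A+B)/(1+T))``, evaluated with exact integer arithmetic from the
threshold's rational form.  Because the rational equals the double threshold
exactly, the rejection test is also the acceptance test; floating point is
used only to report scores.

k-nearest search walks the bins in decreasing order of their best-possible
score ``min(A,B)/max(A,B)``, merging the two monotonically decreasing sides
below and above ``A``, and stops once the k-th best score exceeds the bound
of the next unvisited bin.
"""

from __future__ import annotations

import dataclasses
import heapq
from concurrent.futures import ThreadPoolExecutor
from fractions import Fraction
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse

from .core import (
    FingerprintError,
    FingerprintMetadata,
    FingerprintRecord,
    RationalThreshold,
    TVERSKY_SCALE,
    _scale_weight,
    as_threshold,
)
from . import fps_io

__all__ = [
    "Arena",
    "SearchResult",
    "SearchCounters",
    "build_arena",
    "threshold_search",
    "knearest_search",
    "knearest_counting_sort",
    "multiquery_search",
    "symmetric_matrix_search",
    "fps_scan_search",
    "tversky_threshold_search",
    "tversky_knearest_search",
]

_ZERO_THRESHOLD = RationalThreshold(0, 1, 0.0)


@dataclasses.dataclass
class SearchCounters:
    """Instrumentation for one or more searches.

    ``evaluated`` counts intersection-popcount (Tanimoto) evaluations, i.e.
    candidates that survived BitBound bin pruning; ``confirmed`` counts
    candidates that passed the integer rejection test (each of which needs a
    division only to report its score); ``bytes_examined`` is
    ``evaluated * storage_size``.
    """

    evaluated: int = 0
    confirmed: int = 0
    bytes_examined: int = 0

    def add(self, evaluated: int, confirmed: int, storage_size: int) -> None:
        self.evaluated += int(evaluated)
        self.confirmed += int(confirmed)
        self.bytes_examined += int(evaluated) * storage_size


@dataclasses.dataclass
class SearchResult:
    """Hits for one query: a list of ``(target, score)`` pairs.

    ``target`` is an arena index for in-memory searches and a record id for
    file-scan searches.  Threshold results are in ascending target order
    (file order for scans); k-nearest results are in descending score order
    with ties broken by ascending target index.
    """

    hits: list[tuple]
    query_id: str | None = None

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    @property
    def targets(self) -> list:
        return [t for t, _ in self.hits]

    @property
    def scores(self) -> list[float]:
        return [s for _, s in self.hits]


# ---------------------------------------------------------------------------
# Arena


class _LazyIds(Sequence):
    """Sequence of ids resolved on demand from a backing loader."""

    def __init__(self, length: int, fetch):
        self._length = length
        self._fetch = fetch

    def __len__(self) -> int:
        return self._length

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(self._length))]
        if i < 0:
            i += self._length
        if not 0 <= i < self._length:
            raise IndexError(i)
        return self._fetch(i)


@dataclasses.dataclass
class Arena:
    """A contiguous block of equal-length fingerprints with search indexes."""

    metadata: FingerprintMetadata
    storage_size: int
    words: np.ndarray  # shape (n, storage_size // 8), dtype uint64
    popcounts: np.ndarray  # shape (n,), int64
    ids: Sequence[str]
    popcount_index: np.ndarray | None  # length num_bits + 2, or None (unsorted)
    id_hash: dict | None = None
    start_padding: int = 0
    _id_lookup: object = None  # callable fallback when id_hash is None

    def __len__(self) -> int:
        return self.words.shape[0]

    @property
    def sorted(self) -> bool:
        return self.popcount_index is not None

    def fingerprint(self, i: int) -> bytes:
        return self.words[i].tobytes()[: self.metadata.num_bytes]

    def record(self, i: int) -> FingerprintRecord:
        return FingerprintRecord(self.ids[i], self.fingerprint(i))

    def __iter__(self) -> Iterator[FingerprintRecord]:
        for i in range(len(self)):
            yield self.record(i)

    def lookup_id(self, record_id: str) -> list[int]:
        """All indices whose id equals ``record_id`` (ascending); [] if absent."""
        if self.id_hash is not None:
            return list(self.id_hash.get(record_id, ()))
        if self._id_lookup is not None:
            return self._id_lookup(record_id)
        return [i for i, rid in enumerate(self.ids) if rid == record_id]

    @property
    def block(self) -> bytes:
        return self.words.tobytes()


def _storage_size(num_bytes: int) -> int:
    return ((num_bytes + 7) // 8) * 8


def _popcount_rows(words: np.ndarray) -> np.ndarray:
    if words.size == 0:
        return np.zeros(words.shape[0], dtype=np.int64)
    return np.bitwise_count(words).sum(axis=1, dtype=np.int64)


def build_popcount_index(popcounts: np.ndarray, num_bits: int) -> np.ndarray:
    """Bin boundaries for popcount-sorted ``popcounts`` (length num_bits+2)."""
    return np.searchsorted(popcounts, np.arange(num_bits + 2), side="left").astype(
        np.int64
    )


def build_arena(
    records: Iterable[FingerprintRecord],
    metadata: FingerprintMetadata | None = None,
    sort: bool = True,
    alignment: int = 8,
) -> Arena:
    """Build an arena from fingerprint records.

    With ``sort=True`` (the default) the fingerprints are ordered by
    popcount and the bin index is built; unsorted arenas preserve the input
    order and carry no popcount index.  ``alignment`` is recorded for file
    writers; the in-memory block is always 8-byte padded per slot.
    """
    records = list(records)
    if metadata is None:
        if not records:
            raise FingerprintError("cannot infer metadata from an empty record set")
        metadata = FingerprintMetadata(num_bits=len(records[0].fingerprint) * 8)
    num_bytes = metadata.num_bytes
    storage = _storage_size(num_bytes)
    n = len(records)
    raw = np.zeros((n, storage), dtype=np.uint8)
    ids = []
    for row, record in enumerate(records):
        if len(record.fingerprint) != num_bytes:
            raise FingerprintError(
                f"record {record.id!r}: fingerprint is "
                f"{len(record.fingerprint)} bytes, expected {num_bytes}"
            )
        raw[row, :num_bytes] = np.frombuffer(record.fingerprint, dtype=np.uint8)
        ids.append(record.id)
    words = raw.view(np.uint64)
    popcounts = _popcount_rows(words)

    index = None
    if sort:
        order = np.argsort(popcounts, kind="stable")
        words = np.ascontiguousarray(words[order])
        popcounts = popcounts[order]
        ids = [ids[i] for i in order]
        index = build_popcount_index(popcounts, metadata.num_bits)

    id_hash: dict[str, list[int]] = {}
    for i, rid in enumerate(ids):
        id_hash.setdefault(rid, []).append(i)

    return Arena(
        metadata=metadata,
        storage_size=storage,
        words=words,
        popcounts=popcounts,
        ids=ids,
        popcount_index=index,
        id_hash=id_hash,
    )


def _query_words(arena: Arena, query: bytes) -> tuple[np.ndarray, int]:
    num_bytes = arena.metadata.num_bytes
    if len(query) not in (num_bytes, arena.storage_size):
        raise FingerprintError(
            f"query is {len(query)} bytes, expected {num_bytes}"
        )
    buf = np.zeros(arena.storage_size, dtype=np.uint8)
    buf[: len(query)] = np.frombuffer(query, dtype=np.uint8)
    qw = buf.view(np.uint64)
    return qw, int(np.bitwise_count(qw).sum())


def _bitbound_bins(t: RationalThreshold, a: int, num_bits: int) -> tuple[int, int]:
    """Inclusive popcount bin range [low, high] admitted by BitBound."""
    low = -((-a * t.p) // t.q)  # ceil(A * t)
    high = (a * t.q) // t.p  # floor(A / t)
    return max(low, 0), min(high, num_bits)


def _min_intersect_table(t: RationalThreshold, a: int, lowb: int, highb: int) -> np.ndarray:
    """min_required_popcount(t, a, b) for each b in [lowb, highb]."""
    return np.array(
        [t.min_intersect(a, b) for b in range(lowb, highb + 1)], dtype=np.int64
    )


# ---------------------------------------------------------------------------
# Threshold search


def threshold_search(
    arena: Arena,
    query: bytes,
    threshold,
    counters: SearchCounters | None = None,
) -> SearchResult:
    """All targets with Tanimoto >= threshold, in ascending index order."""
    t = as_threshold(threshold)
    qw, a = _query_words(arena, query)
    n = len(arena)
    hits: list[tuple[int, float]] = []

    if n == 0:
        return SearchResult(hits)

    if arena.popcount_index is None or t.p == 0:
        # Unsorted arena, or threshold 0 (matches everything): linear scan.
        c = _popcount_rows(arena.words & qw)
        b = arena.popcounts
        d = a + b - c
        if t.p == 0:
            mask = np.ones(n, dtype=bool)
        else:
            # Exact per-candidate test via the per-popcount minimum bound.
            minc = np.array(
                [t.min_intersect(a, int(bv)) for bv in b], dtype=np.int64
            )
            mask = c >= minc
        if counters is not None:
            counters.add(n, mask.sum(), arena.storage_size)
        scores = np.where(d > 0, c / np.maximum(d, 1), 0.0)
        for i in np.nonzero(mask)[0]:
            hits.append((int(i), float(scores[i])))
        return SearchResult(hits)

    if a == 0:
        # Zero-popcount query scores 0 with everything; t > 0 means no hits.
        return SearchResult(hits)

    num_bits = arena.metadata.num_bits
    lowb, highb = _bitbound_bins(t, a, num_bits)
    if lowb > highb:
        return SearchResult(hits)
    index = arena.popcount_index
    lo_i, hi_i = int(index[lowb]), int(index[highb + 1])
    if lo_i == hi_i:
        return SearchResult(hits)

    c = _popcount_rows(arena.words[lo_i:hi_i] & qw)
    b = arena.popcounts[lo_i:hi_i]
    minc_table = _min_intersect_table(t, a, lowb, highb)
    mask = c >= minc_table[b - lowb]
    if counters is not None:
        counters.add(hi_i - lo_i, mask.sum(), arena.storage_size)
    picked = np.nonzero(mask)[0]
    d = a + b[picked] - c[picked]
    scores = c[picked] / d
    for off, score in zip(picked, scores):
        hits.append((lo_i + int(off), float(score)))
    return SearchResult(hits)


# ---------------------------------------------------------------------------
# k-nearest search


def _knearest_bin_order(
    a: int, num_bits: int, lowb: int, highb: int
) -> Iterator[tuple[int, Fraction]]:
    """Yield (bin, best-possible score) in decreasing-bound merge order.

    The two sides below and above the query popcount ``a`` each have
    monotonically decreasing bounds ``min(A,B)/max(A,B)``; they are merged
    in constant memory.
    """
    down = min(a, highb, num_bits)
    up = max(a + 1, lowb)
    while down >= lowb or up <= highb:
        if down >= lowb and (up > highb or down * up >= a * a):
            # bound(down) = down/a >= a/up = bound(up)
            yield down, Fraction(down, a)
            down -= 1
        else:
            yield up, Fraction(a, up)
            up += 1


def _bin_candidates(
    arena: Arena,
    qw: np.ndarray,
    a: int,
    b: int,
    min_threshold: RationalThreshold,
    counters: SearchCounters | None,
) -> list[tuple[int, int, int]]:
    """Surviving candidates ``(c, d, index)`` of popcount bin ``b``.

    Candidates failing the ``min_threshold`` rejection test are filtered.
    """
    index = arena.popcount_index
    s, e = int(index[b]), int(index[b + 1])
    if s == e:
        return []
    c = _popcount_rows(arena.words[s:e] & qw)
    if min_threshold.p > 0:
        minc = min_threshold.min_intersect(a, b)
        mask = c >= minc
    else:
        mask = np.ones(e - s, dtype=bool)
    if counters is not None:
        counters.add(e - s, mask.sum(), arena.storage_size)
    return [
        (int(cv), a + b - int(cv), s + int(off))
        for off, cv in zip(np.nonzero(mask)[0], c[mask])
    ]


def _score_fraction(c: int, d: int) -> Fraction:
    return Fraction(c, d) if d else Fraction(0)


def knearest_search(
    arena: Arena,
    query: bytes,
    k: int,
    min_threshold=0.0,
    counters: SearchCounters | None = None,
) -> SearchResult:
    """The k highest-scoring targets, descending score, ties by index.

    ``min_threshold`` is applied as a hard filter before selection.  Uses a
    bounded heap over exact rational scores; identical result contract as
    :func:`knearest_counting_sort`.
    """
    if k < 1:
        raise FingerprintError(f"k must be >= 1, got {k}")
    t = as_threshold(min_threshold)
    qw, a = _query_words(arena, query)
    n = len(arena)
    if n == 0:
        return SearchResult([])

    if arena.popcount_index is None or a == 0:
        # Unsorted arena, or all-zero query (every score is 0): brute pass.
        c = _popcount_rows(arena.words & qw)
        b = arena.popcounts
        cand = []
        for i in range(n):
            ci, bi = int(c[i]), int(b[i])
            if t.p > 0 and not t.passes(ci, a, bi):
                continue
            cand.append((ci, a + bi - ci, i))
        if counters is not None:
            counters.add(n, len(cand), arena.storage_size)
        cand.sort(key=lambda x: (-_score_fraction(x[0], x[1]), x[2]))
        top = cand[:k]
        return SearchResult(
            [(i, float(c / d) if d else 0.0) for c, d, i in top]
        )

    # Min-heap of the current best k; heap[0] is the worst kept entry.
    # Key (score, -index) so that among equal scores the largest index is
    # evicted first, implementing the ascending-index tie-break.
    heap: list[tuple[Fraction, int, int, int]] = []  # (score, -i, c, d)
    num_bits = arena.metadata.num_bits
    if t.p > 0:
        lowb, highb = _bitbound_bins(t, a, num_bits)
    else:
        lowb, highb = 0, num_bits
    for b, bound in _knearest_bin_order(a, num_bits, lowb, highb):
        if len(heap) == k and heap[0][0] > bound:
            break
        for c, d, i in _bin_candidates(arena, qw, a, b, t, counters):
            key = (_score_fraction(c, d), -i, c, d)
            if len(heap) < k:
                heapq.heappush(heap, key)
            elif key > heap[0]:
                heapq.heapreplace(heap, key)
    result = sorted(heap, key=lambda x: (-x[0], -x[1]))
    return SearchResult(
        [(-neg_i, float(c / d) if d else 0.0) for _, neg_i, c, d in result]
    )


def knearest_counting_sort(
    arena: Arena,
    query: bytes,
    k: int,
    min_threshold=0.0,
    counters: SearchCounters | None = None,
) -> SearchResult:
    """k-nearest via score bucketing (counting sort).

    Tanimoto scores are ratios of small integers so relatively few distinct
    values occur; hits are bucketed by exact score instead of kept in a
    heap.  Result contract identical to :func:`knearest_search`.
    """
    if k < 1:
        raise FingerprintError(f"k must be >= 1, got {k}")
    t = as_threshold(min_threshold)
    qw, a = _query_words(arena, query)
    if len(arena) == 0:
        return SearchResult([])
    if arena.popcount_index is None or a == 0:
        return knearest_search(arena, query, k, min_threshold, counters)

    buckets: dict[Fraction, list[int]] = {}
    total = 0

    def kth_score() -> Fraction | None:
        if total < k:
            return None
        seen = 0
        for score in sorted(buckets, reverse=True):
            seen += len(buckets[score])
            if seen >= k:
                return score
        return None  # pragma: no cover

    num_bits = arena.metadata.num_bits
    if t.p > 0:
        lowb, highb = _bitbound_bins(t, a, num_bits)
    else:
        lowb, highb = 0, num_bits
    for b, bound in _knearest_bin_order(a, num_bits, lowb, highb):
        kth = kth_score()
        if kth is not None and kth > bound:
            break
        for c, d, i in _bin_candidates(arena, qw, a, b, t, counters):
            buckets.setdefault(_score_fraction(c, d), []).append(i)
            total += 1

    hits: list[tuple[int, float]] = []
    for score in sorted(buckets, reverse=True):
        for i in sorted(buckets[score]):
            hits.append((i, float(score)))
            if len(hits) == k:
                return SearchResult(hits)
    return SearchResult(hits)


# ---------------------------------------------------------------------------
# Tversky search (linear scan with exact integer tests; no BitBound pruning)


def _tversky_arrays(
    arena: Arena, qw: np.ndarray, a: int, alpha_s: int, beta_s: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-target (c, numerator-scale c, denominator) integer arrays."""
    c = _popcount_rows(arena.words & qw)
    b = arena.popcounts
    denom = alpha_s * (a - c) + beta_s * (b - c) + TVERSKY_SCALE * c
    return c, b, denom


def tversky_threshold_search(
    arena: Arena,
    query: bytes,
    threshold,
    alpha: float = 1.0,
    beta: float = 1.0,
    counters: SearchCounters | None = None,
) -> SearchResult:
    """All targets with Tversky(alpha, beta) >= threshold.

    Uses the integer-scaled weights (x10,000) and exact rational
    comparisons; a full linear scan is performed because the Tanimoto
    BitBound range is not valid for asymmetric weights.
    """
    t = as_threshold(threshold)
    alpha_s = _scale_weight(alpha, "alpha")
    beta_s = _scale_weight(beta, "beta")
    qw, a = _query_words(arena, query)
    n = len(arena)
    if n == 0:
        return SearchResult([])
    c, b, denom = _tversky_arrays(arena, qw, a, alpha_s, beta_s)
    hits = []
    confirmed = 0
    for i in range(n):
        ci, di = int(c[i]), int(denom[i])
        if di == 0:
            score_num, score_den = 0, 1
        else:
            score_num, score_den = TVERSKY_SCALE * ci, di
        # score >= p/q  <=>  q * num >= p * den   (den > 0)
        if score_num * t.q >= t.p * score_den:
            confirmed += 1
            hits.append((i, score_num / score_den if score_den else 0.0))
    if counters is not None:
        counters.add(n, confirmed, arena.storage_size)
    return SearchResult(hits)


def tversky_knearest_search(
    arena: Arena,
    query: bytes,
    k: int,
    min_threshold=0.0,
    alpha: float = 1.0,
    beta: float = 1.0,
    counters: SearchCounters | None = None,
) -> SearchResult:
    """k highest Tversky scores; linear scan with exact rational selection."""
    if k < 1:
        raise FingerprintError(f"k must be >= 1, got {k}")
    t = as_threshold(min_threshold)
    alpha_s = _scale_weight(alpha, "alpha")
    beta_s = _scale_weight(beta, "beta")
    qw, a = _query_words(arena, query)
    n = len(arena)
    if n == 0:
        return SearchResult([])
    c, b, denom = _tversky_arrays(arena, qw, a, alpha_s, beta_s)
    cand = []
    for i in range(n):
        ci, di = int(c[i]), int(denom[i])
        num = TVERSKY_SCALE * ci
        if di == 0:
            score = Fraction(0)
        else:
            score = Fraction(num, di)
        if t.p > 0 and not (num * t.q >= t.p * di and di > 0):
            continue
        cand.append((score, i))
    if counters is not None:
        counters.add(n, len(cand), arena.storage_size)
    cand.sort(key=lambda x: (-x[0], x[1]))
    return SearchResult([(i, float(s)) for s, i in cand[:k]])


# ---------------------------------------------------------------------------
# Multiquery and symmetric searches


def _extract_queries(queries) -> list[tuple[str | None, bytes]]:
    if isinstance(queries, Arena):
        return [(queries.ids[i], queries.fingerprint(i)) for i in range(len(queries))]
    out = []
    for q in queries:
        if isinstance(q, FingerprintRecord):
            out.append((q.id, q.fingerprint))
        elif isinstance(q, (bytes, bytearray)):
            out.append((None, bytes(q)))
        else:
            qid, fp = q
            out.append((qid, fp))
    return out


def _single_search(arena, fp, mode, params) -> SearchResult:
    if mode == "threshold":
        return threshold_search(arena, fp, params["threshold"], params.get("counters"))
    if mode == "knearest":
        return knearest_search(
            arena,
            fp,
            params["k"],
            params.get("min_threshold", 0.0),
            params.get("counters"),
        )
    raise FingerprintError(f"unknown search mode {mode!r}")


def multiquery_search(
    arena: Arena,
    queries,
    mode: str = "threshold",
    params: dict | None = None,
    workers: int = 1,
    sort_queries: bool = False,
) -> list[SearchResult]:
    """Run one search per query; output order always matches input order.

    ``sort_queries=True`` groups execution by query popcount (better cache
    temporal locality when parallel); results are identical and re-ordered
    back to the input order.  ``workers`` sets the thread count; per-query
    results are deterministic regardless.
    """
    if workers < 1:
        raise FingerprintError(f"workers must be >= 1, got {workers}")
    params = dict(params or {})
    pairs = _extract_queries(queries)
    order = list(range(len(pairs)))
    if sort_queries:
        from .core import popcount as _pc

        order.sort(key=lambda i: _pc(pairs[i][1]))

    results: list[SearchResult | None] = [None] * len(pairs)

    def run(i: int) -> None:
        qid, fp = pairs[i]
        res = _single_search(arena, fp, mode, params)
        res.query_id = qid
        results[i] = res

    if workers == 1 or len(pairs) <= 1:
        for i in order:
            run(i)
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            list(pool.map(run, order))
    return results  # type: ignore[return-value]


def symmetric_matrix_search(
    arena: Arena,
    mode: str = "threshold",
    params: dict | None = None,
    workers: int = 1,
):
    """All-pairs search of a sorted arena against itself, diagonal excluded.

    Threshold mode computes the upper triangle once (for row ``i`` only
    targets ``j > i`` are scanned, exploiting the popcount sort) and mirrors
    it, returning a symmetric ``scipy.sparse.csr_matrix`` of scores with an
    empty diagonal.  k-nearest mode returns one :class:`SearchResult` per
    row with the self-index excluded.
    """
    if workers < 1:
        raise FingerprintError(f"workers must be >= 1, got {workers}")
    if arena.popcount_index is None:
        raise FingerprintError("symmetric search requires a popcount-sorted arena")
    params = dict(params or {})
    n = len(arena)

    if mode == "threshold":
        t = as_threshold(params["threshold"])
        counters = params.get("counters")
        num_bits = arena.metadata.num_bits
        index = arena.popcount_index
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        for i in range(n):
            fp_words = arena.words[i]
            a = int(arena.popcounts[i])
            if t.p == 0:
                lo_i, hi_i = i + 1, n
                lowb = 0
            else:
                if a == 0:
                    continue
                lowb, highb = _bitbound_bins(t, a, num_bits)
                if lowb > highb:
                    continue
                lo_i = max(int(index[lowb]), i + 1)
                hi_i = int(index[highb + 1])
            if lo_i >= hi_i:
                continue
            c = _popcount_rows(arena.words[lo_i:hi_i] & fp_words)
            b = arena.popcounts[lo_i:hi_i]
            if t.p == 0:
                mask = np.ones(hi_i - lo_i, dtype=bool)
            else:
                minc_table = _min_intersect_table(t, a, lowb, int(b[-1]))
                mask = c >= minc_table[b - lowb]
            if counters is not None:
                counters.add(hi_i - lo_i, mask.sum(), arena.storage_size)
            picked = np.nonzero(mask)[0]
            d = a + b[picked] - c[picked]
            scores = np.where(d > 0, c[picked] / np.maximum(d, 1), 0.0)
            for off, s in zip(picked, scores):
                rows.append(i)
                cols.append(lo_i + int(off))
                vals.append(float(s))
        # Mirror the upper triangle into the lower one.
        mat = scipy.sparse.coo_matrix(
            (vals + vals, (rows + cols, cols + rows)), shape=(n, n)
        )
        return mat.tocsr()

    if mode == "knearest":
        k = params["k"]
        min_threshold = params.get("min_threshold", 0.0)
        counters = params.get("counters")
        results = []
        for i in range(n):
            res = knearest_search(
                arena, arena.fingerprint(i), k + 1, min_threshold, counters
            )
            hits = [(j, s) for j, s in res.hits if j != i][:k]
            results.append(SearchResult(hits, query_id=arena.ids[i]))
        return results

    raise FingerprintError(f"unknown search mode {mode!r}")


# ---------------------------------------------------------------------------
# FPS file scan search


def fps_scan_search(
    source,
    queries,
    mode: str = "threshold",
    threshold=0.0,
    k: int | None = None,
):
    """Search an FPS file directly, without building an arena.

    Scores are computed from the parsed hex text; record objects are never
    materialized.  Threshold mode validates every line of the file and
    returns hits as ``(id, score)`` in file order.  k-nearest mode may stop
    reading — and therefore stop validating — once every query has found
    ``k`` exact (score 1.0) matches.

    Returns a single :class:`SearchResult` when ``queries`` is one
    fingerprint, else a list in query order.
    """
    single = isinstance(queries, (bytes, bytearray))
    pairs = _extract_queries([queries] if single else queries)
    if mode not in ("threshold", "knearest"):
        raise FingerprintError(f"unknown search mode {mode!r}")
    if mode == "knearest":
        if k is None or k < 1:
            raise FingerprintError("k-nearest scan requires k >= 1")
    t = as_threshold(threshold)

    q_ints = [int.from_bytes(fp, "little") for _, fp in pairs]
    q_pops = [q.bit_count() for q in q_ints]
    num_bytes_q = len(pairs[0][1]) if pairs else None
    for _, fp in pairs:
        if len(fp) != num_bytes_q:
            raise FingerprintError("query fingerprints must share a length")

    # Per-query state: threshold hit lists, or k-nearest heaps + exact count.
    hit_lists: list[list[tuple[str, float]]] = [[] for _ in pairs]
    heaps: list[list] = [[] for _ in pairs]
    exact_counts = [0] * len(pairs)
    # cache of min-intersect bounds per (query, target popcount)
    minc_cache: list[dict[int, int]] = [{} for _ in pairs]

    reader = fps_io.read_fps(source)
    meta = reader.metadata
    if meta is not None and num_bytes_q is not None and meta.num_bytes != num_bytes_q:
        raise FingerprintError(
            f"query fingerprints are {num_bytes_q} bytes but the file holds "
            f"{meta.num_bytes}-byte fingerprints"
        )
    ordinal = 0
    for record in reader:
        t_int = int.from_bytes(record.fingerprint, "little")
        b = t_int.bit_count()
        for qi, (q_int, a) in enumerate(zip(q_ints, q_pops)):
            c = (q_int & t_int).bit_count()
            d = a + b - c
            if mode == "threshold":
                if t.p == 0:
                    hit_lists[qi].append((record.id, c / d if d else 0.0))
                    continue
                cache = minc_cache[qi]
                if b not in cache:
                    cache[b] = t.min_intersect(a, b)
                if c >= cache[b] and d > 0:
                    hit_lists[qi].append((record.id, c / d))
            else:
                if t.p > 0 and not (d > 0 and t.passes(c, a, b)):
                    continue
                score = _score_fraction(c, d)
                key = (score, -ordinal, record.id, c, d)
                heap = heaps[qi]
                if len(heap) < k:
                    heapq.heappush(heap, key)
                    if score == 1:
                        exact_counts[qi] += 1
                elif key > heap[0]:
                    dropped = heapq.heapreplace(heap, key)
                    if score == 1:
                        exact_counts[qi] += 1
                    if dropped[0] == 1:
                        exact_counts[qi] -= 1
        ordinal += 1
        if mode == "knearest" and all(e >= k for e in exact_counts):
            break  # early exit: every query already has k exact matches

    if mode == "threshold":
        results = [
            SearchResult(hits, query_id=pairs[i][0])
            for i, hits in enumerate(hit_lists)
        ]
    else:
        results = []
        for qi, heap in enumerate(heaps):
            ordered = sorted(heap, key=lambda x: (-x[0], -x[1]))
            results.append(
                SearchResult(
                    [(rid, float(c / d) if d else 0.0) for _, _, rid, c, d in ordered],
                    query_id=pairs[qi][0],
                )
            )
    return results[0] if single else results
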
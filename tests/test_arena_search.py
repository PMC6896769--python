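import io
from fractions import Fraction

import numpy as np
import pytest

from fpsim.core import FingerprintError, FingerprintMetadata, FingerprintRecord
from fpsim.arena_search import (
    SearchCounters,
    build_arena,
    fps_scan_search,
    knearest_counting_sort,
    knearest_search,
    multiquery_search,
    symmetric_matrix_search,
    threshold_search,
    tversky_knearest_search,
    tversky_threshold_search,
)
from fpsim import fps_io
from conftest import make_records
from oracles import brute_knearest, brute_threshold, tanimoto_fraction


def rec(rid, bits, num_bytes=2):
    from fpsim.core import fingerprint_from_bits

    return FingerprintRecord(rid, fingerprint_from_bits(bits, num_bytes))


@pytest.fixture(scope="module")
def medium():
    records = make_records(166, 400, seed=101)
    arena = build_arena(records)
    queries = [r.fingerprint for r in make_records(166, 50, seed=202)]
    targets = [arena.fingerprint(i) for i in range(len(arena))]
    return arena, targets, queries


class TestBuildArena:
    def test_bin_boundaries_hand_checked(self):
        records = [
            rec("a", [0, 1, 2, 3, 4]),   # popcount 5
            rec("b", []),                # popcount 0
            rec("c", [1, 2, 3]),         # popcount 3
            rec("d", [7, 8, 9]),         # popcount 3
        ]
        arena = build_arena(records, FingerprintMetadata(num_bits=16))
        assert list(arena.popcounts) == [0, 3, 3, 5]
        idx = arena.popcount_index
        # sorted popcounts [0,3,3,5]: bins 1..2 are empty (boundaries equal)
        assert idx[0] == 0
        assert list(idx[1:4]) == [1, 1, 1]
        assert idx[4] == 3 and idx[5] == 3  # bin 4 empty
        assert idx[6] == 4
        assert arena.ids == ["b", "c", "d", "a"]

    def test_single_record(self):
        arena = build_arena([rec("only", [0, 5])], FingerprintMetadata(num_bits=16))
        idx = arena.popcount_index
        assert idx[2] == 0 and idx[3] == 1
        assert len(arena) == 1

    def test_invariants_on_random_set(self):
        records = make_records(166, 2000, seed=303)
        arena = build_arena(records)
        pc = arena.popcounts
        assert np.all(np.diff(pc) >= 0)  # non-decreasing popcounts
        idx = arena.popcount_index
        assert idx[0] == 0 and idx[-1] == len(arena)
        for b in range(arena.metadata.num_bits + 1):
            s, e = int(idx[b]), int(idx[b + 1])
            assert np.all(pc[s:e] == b)
        # padding bytes beyond num_bytes are zero
        nb = arena.metadata.num_bytes
        raw = arena.words.view(np.uint8).reshape(len(arena), arena.storage_size)
        assert not raw[:, nb:].any()
        # id parallelism and hash completeness
        for rid, indices in arena.id_hash.items():
            assert all(arena.ids[i] == rid for i in indices)

    def test_unsorted_preserves_order(self):
        records = [rec("a", [0, 1]), rec("b", []), rec("c", [0])]
        arena = build_arena(records, FingerprintMetadata(num_bits=16), sort=False)
        assert arena.popcount_index is None
        assert arena.ids == ["a", "b", "c"]

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(FingerprintError):
            build_arena(
                [FingerprintRecord("a", b"\x00\x01"), FingerprintRecord("b", b"\x00")],
                FingerprintMetadata(num_bits=16),
            )


class TestThresholdSearch:
    def test_exact_match_threshold_one(self):
        records = [rec("a", [0, 1]), rec("b", [0, 1]), rec("c", [0, 2]), rec("d", [0, 1, 2])]
        arena = build_arena(records, FingerprintMetadata(num_bits=16))
        query = rec("q", [0, 1]).fingerprint
        res = threshold_search(arena, query, 1.0)
        assert sorted(arena.ids[i] for i, _ in res.hits) == ["a", "b"]
        assert all(s == 1.0 for _, s in res.hits)

    def test_zero_query_with_positive_threshold_finds_nothing(self, medium):
        arena, _, _ = medium
        assert threshold_search(arena, b"\x00" * 21, 0.2).hits == []

    def test_threshold_zero_returns_everything(self, medium):
        arena, _, _ = medium
        res = threshold_search(arena, b"\x00" * 21, 0.0)
        assert len(res) == len(arena)
        assert all(s == 0.0 for _, s in res.hits)

    def test_agrees_with_brute_force(self, medium):
        arena, targets, queries = medium
        for q in queries:
            for t in (0.4, 0.7, 0.9):
                got = [i for i, _ in threshold_search(arena, q, t).hits]
                assert got == brute_threshold(targets, q, t)

    def test_scores_are_ascending_index_and_exact(self, medium):
        arena, targets, queries = medium
        res = threshold_search(arena, queries[0], 0.4)
        indices = [i for i, _ in res.hits]
        assert indices == sorted(indices)
        for i, s in res.hits:
            assert s == pytest.approx(float(tanimoto_fraction(queries[0], targets[i])))

    def test_monotonicity_in_threshold(self, medium):
        arena, _, queries = medium
        for q in queries[:10]:
            prev = None
            for t in (0.9, 0.7, 0.5, 0.3, 0.0):
                hits = {i for i, _ in threshold_search(arena, q, t).hits}
                if prev is not None:
                    assert prev <= hits
                prev = hits

    def test_unsorted_arena_same_hits(self, medium):
        arena, targets, queries = medium
        unsorted = build_arena(
            [FingerprintRecord(f"r{i}", fp) for i, fp in enumerate(targets)],
            arena.metadata,
            sort=False,
        )
        for q in queries[:10]:
            got = [i for i, _ in threshold_search(unsorted, q, 0.6).hits]
            assert got == brute_threshold(targets, q, 0.6)

    def test_counters_exact_match_examines_own_bin_only(self, medium):
        arena, _, _ = medium
        q = arena.fingerprint(100)
        a = int(arena.popcounts[100])
        counters = SearchCounters()
        threshold_search(arena, q, 1.0, counters)
        idx = arena.popcount_index
        assert counters.evaluated == int(idx[a + 1] - idx[a])
        assert counters.bytes_examined == counters.evaluated * arena.storage_size

    def test_counters_threshold_zero_examines_all(self, medium):
        arena, _, _ = medium
        counters = SearchCounters()
        threshold_search(arena, arena.fingerprint(0), 0.0, counters)
        assert counters.evaluated == len(arena)


class TestKNearest:
    def test_k_of_n_is_full_ranking(self, medium):
        arena, targets, queries = medium
        q = queries[0]
        res = knearest_search(arena, q, len(arena) + 10)
        assert [i for i, _ in res.hits] == brute_knearest(targets, q, len(targets))
        scores = [s for _, s in res.hits]
        assert scores == sorted(scores, reverse=True)

    def test_identity_query_first_hit_is_duplicate_with_lowest_index(self):
        records = [rec("x", [0, 1]), rec("y", [0, 1]), rec("z", [5])]
        arena = build_arena(records, FingerprintMetadata(num_bits=16))
        res = knearest_search(arena, rec("q", [0, 1]).fingerprint, 1)
        i, s = res.hits[0]
        assert s == 1.0
        assert i == min(arena.lookup_id("x") + arena.lookup_id("y"))

    def test_agrees_with_brute_force(self, medium):
        arena, targets, queries = medium
        for q in queries:
            for k in (1, 10, 100):
                got = [i for i, _ in knearest_search(arena, q, k).hits]
                assert got == brute_knearest(targets, q, k)

    def test_prefix_property(self, medium):
        arena, _, queries = medium
        for q in queries[:10]:
            prev = [i for i, _ in knearest_search(arena, q, 5).hits]
            nxt = [i for i, _ in knearest_search(arena, q, 6).hits]
            assert nxt[:5] == prev

    def test_min_threshold_is_hard_filter(self, medium):
        arena, targets, queries = medium
        q = queries[3]
        res = knearest_search(arena, q, 50, min_threshold=0.5)
        expected = brute_knearest(targets, q, 50, min_threshold=0.5)
        assert [i for i, _ in res.hits] == expected
        assert all(tanimoto_fraction(q, targets[i]) >= Fraction(1, 2)
                   for i, _ in res.hits)

    def test_zero_query_returns_first_k_zero_scores(self, medium):
        arena, _, _ = medium
        res = knearest_search(arena, b"\x00" * 21, 4)
        assert res.hits == [(0, 0.0), (1, 0.0), (2, 0.0), (3, 0.0)]

    def test_k_below_one_rejected(self, medium):
        arena, _, _ = medium
        with pytest.raises(FingerprintError):
            knearest_search(arena, b"\x00" * 21, 0)


class TestCountingSort:
    def test_equivalent_to_heap_variant(self, medium):
        arena, _, queries = medium
        for q in queries[:20]:
            for k in (1, 25, 300):
                assert (
                    knearest_counting_sort(arena, q, k).hits
                    == knearest_search(arena, q, k).hits
                )

    def test_all_identical_targets_single_bucket(self):
        records = [rec(f"r{i}", [0, 3, 9]) for i in range(6)]
        arena = build_arena(records, FingerprintMetadata(num_bits=16))
        res = knearest_counting_sort(arena, rec("q", [0, 3, 9]).fingerprint, 4)
        assert res.hits == [(0, 1.0), (1, 1.0), (2, 1.0), (3, 1.0)]

    def test_distinct_score_count_bounds_buckets(self, medium):
        arena, targets, queries = medium
        q = queries[5]
        res = knearest_counting_sort(arena, q, len(arena))
        distinct_pairs = {tanimoto_fraction(q, t) for t in targets}
        assert len({s for _, s in res.hits}) <= len(distinct_pairs)


class TestMultiquery:
    def test_workers_and_query_order_do_not_change_results(self, medium):
        arena, _, queries = medium
        qrecs = [FingerprintRecord(f"q{i}", fp) for i, fp in enumerate(queries)]
        base = multiquery_search(arena, qrecs, "threshold", {"threshold": 0.5})
        par = multiquery_search(arena, qrecs, "threshold", {"threshold": 0.5},
                                workers=4)
        srt = multiquery_search(arena, qrecs, "threshold", {"threshold": 0.5},
                                sort_queries=True)
        assert [r.hits for r in base] == [r.hits for r in par] == [r.hits for r in srt]
        assert [r.query_id for r in base] == [f"q{i}" for i in range(len(queries))]

    def test_knearest_mode(self, medium):
        arena, targets, queries = medium
        results = multiquery_search(
            arena, queries[:5], "knearest", {"k": 3}, workers=2
        )
        for q, res in zip(queries[:5], results):
            assert [i for i, _ in res.hits] == brute_knearest(targets, q, 3)

    def test_empty_query_set(self, medium):
        arena, _, _ = medium
        assert multiquery_search(arena, [], "threshold", {"threshold": 0.5}) == []

    def test_bad_worker_count(self, medium):
        arena, _, queries = medium
        with pytest.raises(FingerprintError):
            multiquery_search(arena, queries, "threshold", {"threshold": 0.5},
                              workers=0)


class TestSymmetric:
    def test_three_identical_fingerprints(self):
        records = [rec(f"r{i}", [0, 2, 7]) for i in range(3)]
        arena = build_arena(records, FingerprintMetadata(num_bits=16))
        mat = symmetric_matrix_search(arena, "threshold", {"threshold": 0.9})
        assert mat.nnz == 6  # all off-diagonal pairs
        assert mat.diagonal().sum() == 0
        assert np.all(mat.data == 1.0)

    def test_matches_self_multiquery_minus_diagonal(self):
        records = make_records(166, 300, seed=404)
        arena = build_arena(records)
        mat = symmetric_matrix_search(arena, "threshold", {"threshold": 0.7})
        assert (mat != mat.T).nnz == 0  # symmetric
        assert mat.nnz % 2 == 0
        results = multiquery_search(arena, arena, "threshold", {"threshold": 0.7})
        for i, res in enumerate(results):
            expected = sorted(j for j, _ in res.hits if j != i)
            got = sorted(mat.getrow(i).indices)
            assert got == expected

    def test_knearest_mode_excludes_self(self):
        records = make_records(166, 200, seed=505)
        arena = build_arena(records)
        targets = [arena.fingerprint(i) for i in range(len(arena))]
        results = symmetric_matrix_search(arena, "knearest", {"k": 5})
        for i, res in enumerate(results):
            assert i not in [j for j, _ in res.hits]
            oracle = [j for j in brute_knearest(targets, targets[i], 6) if j != i][:5]
            assert [j for j, _ in res.hits] == oracle

    def test_requires_sorted_arena(self):
        records = make_records(166, 20, seed=606)
        arena = build_arena(records, sort=False)
        with pytest.raises(FingerprintError, match="sorted"):
            symmetric_matrix_search(arena, "threshold", {"threshold": 0.5})


class TestTverskySearch:
    def test_alpha_beta_one_matches_tanimoto_search(self, medium):
        arena, _, queries = medium
        for q in queries[:10]:
            t1 = threshold_search(arena, q, 0.6)
            t2 = tversky_threshold_search(arena, q, 0.6, 1, 1)
            assert sorted(t1.hits) == sorted(t2.hits)

    def test_asymmetric_weights_agree_with_fraction_oracle(self, medium):
        from fpsim.core import TVERSKY_SCALE
        from oracles import pair_stats

        arena, targets, queries = medium
        alpha, beta = 0.3, 0.7
        a_s, b_s = 3000, 7000
        for q in queries[:5]:
            got = {i for i, _ in
                   tversky_threshold_search(arena, q, 0.5, alpha, beta).hits}
            expected = set()
            for i, t in enumerate(targets):
                c, a, b = pair_stats(q, t)
                denom = a_s * (a - c) + b_s * (b - c) + TVERSKY_SCALE * c
                if denom and Fraction(TVERSKY_SCALE * c, denom) >= Fraction(1, 2):
                    expected.add(i)
            assert got == expected

    def test_knearest_self_hit_scores_one(self, medium):
        arena, _, _ = medium
        q = arena.fingerprint(42)
        res = tversky_knearest_search(arena, q, 1, alpha=0.3, beta=0.7)
        assert res.hits[0][1] == 1.0


class TestFpsScan:
    def write_fps_text(self, records, num_bits=166):
        buf = io.StringIO()
        fps_io.write_fps(FingerprintMetadata(num_bits=num_bits), records, buf)
        return buf.getvalue()

    def test_threshold_scan_equals_arena_search(self, medium, tmp_path):
        arena, targets, queries = medium
        records = [FingerprintRecord(f"r{i}", fp) for i, fp in enumerate(targets)]
        path = tmp_path / "targets.fps"
        path.write_text(self.write_fps_text(records))
        q = queries[0]
        scan = fps_scan_search(path, q, "threshold", threshold=0.5)
        mem = threshold_search(arena, q, 0.5)
        assert sorted(scan.hits) == sorted(
            (f"r{i}", s) for i, s in mem.hits
        )

    def test_knearest_scan_equals_arena_search(self, medium, tmp_path):
        arena, targets, queries = medium
        records = [FingerprintRecord(f"r{i}", fp) for i, fp in enumerate(targets)]
        path = tmp_path / "targets.fps"
        path.write_text(self.write_fps_text(records))
        q = queries[1]
        scan = fps_scan_search(path, q, "knearest", k=10)
        mem = knearest_search(arena, q, 10)
        assert sorted(s for _, s in scan.hits) == sorted(s for _, s in mem.hits)
        assert {tanimoto_fraction(q, targets[int(rid[1:])]) for rid, _ in scan.hits} \
            == {tanimoto_fraction(q, arena.fingerprint(i)) for i, _ in mem.hits}

    def test_knearest_early_exit_skips_later_corruption(self, tmp_path):
        text = (
            "#num_bits=16\n"
            "c218\tfirst\n"
            "XYZ-not-hex\tbroken\n"
        )
        path = tmp_path / "early.fps"
        path.write_text(text)
        from fpsim.core import hex_decode

        res = fps_scan_search(path, hex_decode("c218"), "knearest", k=1)
        assert res.hits == [("first", 1.0)]

    def test_threshold_scan_validates_whole_file(self, tmp_path):
        text = (
            "#num_bits=16\n"
            "c218\tfirst\n"
            "XYZ-not-hex\tbroken\n"
        )
        path = tmp_path / "bad.fps"
        path.write_text(text)
        from fpsim.core import hex_decode
        from fpsim.fps_io import FpsFormatError

        with pytest.raises(FpsFormatError, match="line 3"):
            fps_scan_search(path, hex_decode("c218"), "threshold", threshold=0.99)

    def test_multi_query_scan(self, medium, tmp_path):
        arena, targets, queries = medium
        records = [FingerprintRecord(f"r{i}", fp) for i, fp in enumerate(targets)]
        path = tmp_path / "targets.fps"
        path.write_text(self.write_fps_text(records))
        qpairs = [(f"q{i}", q) for i, q in enumerate(queries[:5])]
        results = fps_scan_search(path, qpairs, "threshold", threshold=0.6)
        assert [r.query_id for r in results] == [f"q{i}" for i in range(5)]
        for (qid, q), res in zip(qpairs, results):
            expected = brute_threshold(targets, q, 0.6)
            assert [int(rid[1:]) for rid, _ in res.hits] == expected


class TestSublinearity:
    def test_k1_candidate_counts_grow_sublinearly(self):
        """BitBound makes k=1 search examine a sublinearly growing slice.

        Uses the clustered synthetic model (queries share the center pool
        with the targets, like benchmark queries sampled from the data set)
        so the nearest-neighbor similarity rises with n; fits
        log(candidates) vs log(n) and requires an exponent < 1 (no
        specific value asserted).
        """
        from fpsim.synthetic import SyntheticSpec, generate_records

        def clustered(count, seed):
            return generate_records(SyntheticSpec(
                num_bits=166, count=count, density=0.25,
                n_centers=300, mutation=0.02, center_seed=7, seed=seed,
            ))

        sizes = [2000, 8000, 32000]
        queries = clustered(20, seed=777)
        counts = []
        for n in sizes:
            arena = build_arena(clustered(n, seed=888))
            counters = SearchCounters()
            for q in queries:
                knearest_search(arena, q.fingerprint, 1, counters=counters)
            counts.append(counters.evaluated)
        slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
        assert slope < 1.0
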
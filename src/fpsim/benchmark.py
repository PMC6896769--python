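"""Benchmark task suite for fingerprint similarity search.

The standard task set mirrors common practice: find all matches at or above
a threshold (0.4 for sparse Morgan-like fingerprints, where it selects
everything above background similarity; 0.7 for denser types, a typical
"good similarity" search), and find the k-nearest neighbors for k = 1 and
k = 1000.  Wall times are reported but hardware dependent; the asserted,
deterministic surface is the instrumentation: the number of Tanimoto
(intersection-popcount) evaluations that survived BitBound pruning, the
number of candidates that passed the integer rejection test and therefore
needed a division to report a score, and the effective bytes examined.
"""

from __future__ import annotations

import dataclasses
import json
import time
from typing import Iterable

from .core import FingerprintError
from .arena_search import (
    Arena,
    SearchCounters,
    build_arena,
    knearest_search,
    threshold_search,
)
from . import fps_io, fpb_io

__all__ = ["BenchmarkTask", "TaskReport", "standard_tasks", "run_benchmark"]


@dataclasses.dataclass(frozen=True)
class BenchmarkTask:
    """One benchmark task: a threshold search or a k-nearest search."""

    kind: str  # "threshold" | "knearest"
    threshold: float | None = None
    k: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "threshold":
            if self.threshold is None:
                raise FingerprintError("threshold task needs a threshold")
        elif self.kind == "knearest":
            if self.k is None or self.k < 1:
                raise FingerprintError("knearest task needs k >= 1")
        else:
            raise FingerprintError(f"unknown task kind {self.kind!r}")

    @property
    def label(self) -> str:
        if self.kind == "threshold":
            return f"T={self.threshold}"
        return f"k={self.k}"


def standard_tasks(morgan_like: bool = False) -> list[BenchmarkTask]:
    """The standard suite: one threshold task (0.4 for sparse Morgan-like
    sets, else 0.7) plus k = 1 and k = 1000 nearest-neighbor tasks."""
    threshold = 0.4 if morgan_like else 0.7
    return [
        BenchmarkTask("threshold", threshold=threshold),
        BenchmarkTask("knearest", k=1),
        BenchmarkTask("knearest", k=1000),
    ]


@dataclasses.dataclass
class TaskReport:
    task: str
    num_queries: int
    num_targets: int
    wall_time_s: float
    tanimoto_evaluations: int
    divisions: int
    bytes_examined: int
    total_hits: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_arena(source) -> Arena:
    if isinstance(source, Arena):
        return source
    path = str(source)
    if path.endswith(".fpb"):
        return fpb_io.read_fpb(path).arena
    with fps_io.read_fps(path) as reader:
        return build_arena(list(reader), reader.metadata)


def _load_queries(source) -> list[tuple[str, bytes]]:
    if isinstance(source, Arena):
        return [(source.ids[i], source.fingerprint(i)) for i in range(len(source))]
    if isinstance(source, (list, tuple)):
        return [(r.id, r.fingerprint) for r in source]
    with fps_io.read_fps(str(source)) as reader:
        return [(r.id, r.fingerprint) for r in reader]


def run_benchmark(
    targets,
    queries,
    tasks: Iterable[BenchmarkTask],
    repetitions: int = 1,
    report_path: str | None = None,
) -> list[TaskReport]:
    """Run the task suite; returns one report per task.

    ``targets`` may be an Arena or an FPS/FPB path; ``queries`` an Arena, a
    record list, or an FPS path.  Counts are deterministic for fixed
    inputs; only the wall times vary between repetitions (the minimum over
    repetitions is reported).
    """
    arena = _load_arena(targets)
    query_pairs = _load_queries(queries)
    if query_pairs and len(query_pairs[0][1]) != arena.metadata.num_bytes:
        raise FingerprintError(
            "query and target fingerprint lengths are incompatible"
        )

    reports = []
    for task in tasks:
        best_time = None
        for _ in range(max(1, repetitions)):
            counters = SearchCounters()
            hits = 0
            start = time.perf_counter()
            for _, fp in query_pairs:
                if task.kind == "threshold":
                    res = threshold_search(arena, fp, task.threshold, counters)
                else:
                    res = knearest_search(arena, fp, task.k, 0.0, counters)
                hits += len(res)
            elapsed = time.perf_counter() - start
            if best_time is None or elapsed < best_time:
                best_time = elapsed
        reports.append(
            TaskReport(
                task=task.label,
                num_queries=len(query_pairs),
                num_targets=len(arena),
                wall_time_s=best_time or 0.0,
                tanimoto_evaluations=counters.evaluated,
                divisions=counters.confirmed,
                bytes_examined=counters.bytes_examined,
                total_hits=hits,
            )
        )

    if report_path is not None:
        write_report(reports, report_path)
    return reports


def write_report(reports: list[TaskReport], path: str) -> None:
    """Write reports as TSV (``path``) and JSON (``path`` + ``.json``)."""
    fields = [f.name for f in dataclasses.fields(TaskReport)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(fields) + "\n")
        for report in reports:
            row = report.as_dict()
            fh.write("\t".join(str(row[name]) for name in fields) + "\n")
    with open(path + ".json", "w", encoding="utf-8") as fh:
        json.dump([r.as_dict() for r in reports], fh, indent=1)
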
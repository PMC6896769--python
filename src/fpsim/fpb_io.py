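"""Read and write the FPB chunked binary fingerprint format.

FPB is a FourCC-style container: an 8-byte signature followed by chunks,
each an 8-byte little-endian payload length, a 4-character ASCII tag, and
the payload.  Processing ends at the FEND chunk; unknown tags are skipped,
which is how the format stays extensible.  Six tags are defined:

========  ==================================================================
META      the FPS header lines, verbatim, including the leading '#' and
          newlines
AREN      the fingerprints as one contiguous block: u32 num_bytes,
          u32 storage_size, u8 spacer length, the zero spacer, then the
          fingerprint slots.  The spacer aligns the first fingerprint in
          the *file* so a memory-mapped load is word aligned (64-byte when
          the storage size is a multiple of 64, else 8-byte).
POPC      the popcount bin start indices (num_bits + 2 int64 values);
          present iff the arena is popcount-sorted
FPID      the record ids: u32 count, u32 cumulative byte offsets
          (count + 1 values), then the concatenated UTF-8 ids
HASH      id -> record indices, as a classic cdb two-level hash table with
          u32 record-index values; duplicate ids get multiple entries
FEND      end marker (empty payload)
========  ==================================================================

This is a self-consistent dialect: the chunk grammar follows the published
description but the byte-level encodings (signature, field widths, the cdb
table) are this package's own, so files are not claimed to be
wire-compatible with other FPB writers.  The design goal is lazy loading: a
reader materializes only the chunk directory and META, and resolves
fingerprints, ids and hash lookups against the (memory-mapped) file on
demand.
"""

from __future__ import annotations

import dataclasses
import mmap
import os
import struct
import tempfile
from typing import Iterable, Iterator

import numpy as np

from .core import FingerprintError, FingerprintMetadata, FingerprintRecord
from . import fps_io
from .arena_search import Arena, _LazyIds, build_arena

__all__ = [
    "FpbFormatError",
    "FpbFile",
    "SIGNATURE",
    "MAX_RECORDS",
    "write_fpb",
    "read_fpb",
    "lookup_id",
    "collated_write",
]

SIGNATURE = b"FPB1\r\n\x00\x00"
# The hash table stores u32 record indices, which caps the record count.
MAX_RECORDS = 2**31 - 1

_REQUIRED = ("META", "AREN")


class FpbFormatError(FingerprintError):
    """FPB container structure error."""


# ---------------------------------------------------------------------------
# cdb hash table (id -> record indices)


def _cdb_hash(key: bytes) -> int:
    h = 5381
    for byte in key:
        h = ((h * 33) ^ byte) & 0xFFFFFFFF
    return h


def _build_cdb(entries: Iterable[tuple[bytes, int]]) -> bytes:
    """Build a cdb payload from (key, u32 value) pairs; multi-valued."""
    tables: list[list[tuple[int, bytes, int]]] = [[] for _ in range(256)]
    for key, value in entries:
        h = _cdb_hash(key)
        tables[h & 0xFF].append((h, key, value))

    records = bytearray()
    rec_pos: list[list[tuple[int, int]]] = [[] for _ in range(256)]  # (hash, pos)
    base = 2048  # the 256-entry pointer table comes first
    for tnum, table in enumerate(tables):
        for h, key, value in table:
            pos = base + len(records)
            records += struct.pack("<II", len(key), 4)
            records += key
            records += struct.pack("<I", value)
            rec_pos[tnum].append((h, pos))

    header = bytearray()
    slot_blob = bytearray()
    slots_base = base + len(records)
    for tnum in range(256):
        entries_t = rec_pos[tnum]
        nslots = 2 * len(entries_t)
        header += struct.pack("<II", slots_base + len(slot_blob), nslots)
        if nslots == 0:
            continue
        slots: list[tuple[int, int]] = [(0, 0)] * nslots
        for h, pos in entries_t:
            s = (h >> 8) % nslots
            while slots[s][1] != 0:
                s = (s + 1) % nslots
            slots[s] = (h, pos)
        for h, pos in slots:
            slot_blob += struct.pack("<II", h, pos)
    return bytes(header) + bytes(records) + bytes(slot_blob)


def _cdb_lookup(buf, key: bytes) -> list[int]:
    h = _cdb_hash(key)
    tnum = h & 0xFF
    table_pos, nslots = struct.unpack_from("<II", buf, tnum * 8)
    if nslots == 0:
        return []
    out = []
    start = (h >> 8) % nslots
    for probe in range(nslots):
        s = (start + probe) % nslots
        slot_hash, rec = struct.unpack_from("<II", buf, table_pos + s * 8)
        if rec == 0:
            break
        if slot_hash == h:
            klen, vlen = struct.unpack_from("<II", buf, rec)
            if bytes(buf[rec + 8 : rec + 8 + klen]) == key:
                (value,) = struct.unpack_from("<I", buf, rec + 8 + klen)
                out.append(value)
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Writing


def _alignment_for(storage_size: int) -> int:
    return 64 if storage_size % 64 == 0 else 8


def _write_stream(
    sink,
    metadata: FingerprintMetadata,
    n: int,
    storage_size: int,
    fingerprint_chunks: Iterable[bytes],
    popcount_index: np.ndarray | None,
    ids: list[str],
) -> int:
    """Emit signature + chunks; fingerprints arrive as streamed byte chunks."""
    if n == 0:
        raise FpbFormatError("refusing to write an empty fingerprint set")
    if n > MAX_RECORDS:
        raise FpbFormatError(
            f"{n} records exceeds the 32-bit hash-table design limit of "
            f"{MAX_RECORDS}"
        )
    try:
        id_blobs = [rid.encode("utf-8") for rid in ids]
    except UnicodeEncodeError as exc:
        raise FpbFormatError(f"record id is not UTF-8 encodable: {exc}") from exc

    own = False
    if isinstance(sink, (str, os.PathLike)):
        stream = open(os.fspath(sink), "wb")
        own = True
    else:
        stream = sink

    total = 0

    def emit(data: bytes) -> None:
        nonlocal total
        stream.write(data)
        total += len(data)

    def emit_chunk_header(tag: str, length: int) -> None:
        emit(struct.pack("<Q", length) + tag.encode("ascii"))

    try:
        emit(SIGNATURE)
        meta_payload = (
            "".join(
                line + "\n" for line in fps_io.format_header_lines(metadata)
            ).encode("utf-8")
        )
        emit_chunk_header("META", len(meta_payload))
        emit(meta_payload)

        align = _alignment_for(storage_size)
        data_start = total + 12 + 9  # chunk header + AREN fixed fields
        spacer = (-data_start) % align
        aren_len = 9 + spacer + n * storage_size
        emit_chunk_header("AREN", aren_len)
        emit(struct.pack("<IIB", metadata.num_bytes, storage_size, spacer))
        emit(b"\x00" * spacer)
        written = 0
        for chunk in fingerprint_chunks:
            emit(chunk)
            written += len(chunk)
        if written != n * storage_size:
            raise FpbFormatError(
                f"fingerprint block is {written} bytes, expected {n * storage_size}"
            )

        if popcount_index is not None:
            payload = np.asarray(popcount_index, dtype="<i8").tobytes()
            emit_chunk_header("POPC", len(payload))
            emit(payload)

        offsets = np.zeros(n + 1, dtype="<u4")
        if id_blobs:
            offsets[1:] = np.cumsum([len(blob) for blob in id_blobs])
        fpid_payload = struct.pack("<I", n) + offsets.tobytes() + b"".join(id_blobs)
        emit_chunk_header("FPID", len(fpid_payload))
        emit(fpid_payload)

        hash_payload = _build_cdb(
            (blob, i) for i, blob in enumerate(id_blobs)
        )
        emit_chunk_header("HASH", len(hash_payload))
        emit(hash_payload)

        emit_chunk_header("FEND", 0)
    finally:
        if own:
            stream.close()
    return total


def write_fpb(arena: Arena, sink, metadata: FingerprintMetadata | None = None) -> int:
    """Write an arena as an FPB file; returns the byte count written."""
    if metadata is None:
        metadata = arena.metadata
    n = len(arena)

    def chunks() -> Iterator[bytes]:
        # stream in slabs to bound peak memory for large arenas
        slab = max(1, (1 << 22) // max(arena.storage_size, 1))
        for start in range(0, n, slab):
            yield arena.words[start : start + slab].tobytes()

    return _write_stream(
        sink,
        metadata,
        n,
        arena.storage_size,
        chunks(),
        arena.popcount_index,
        list(arena.ids),
    )


# ---------------------------------------------------------------------------
# Reading


@dataclasses.dataclass
class FpbChunk:
    tag: str
    offset: int  # payload offset within the file
    length: int


class FpbFile:
    """A parsed FPB container with lazy, random-access loading.

    Opening reads only the chunk directory and the META chunk.  The arena
    block, the id table and the id hash are resolved against the backing
    buffer (a memory map for ``lazy=True``) on first use.
    """

    def __init__(self, source, lazy: bool = True):
        self._path = os.fspath(source) if isinstance(source, (str, os.PathLike)) else None
        if self._path is None:
            raise FpbFormatError("read_fpb requires a file path")
        self._file = open(self._path, "rb")
        if lazy:
            self._buf = mmap.mmap(self._file.fileno(), 0, access=mmap.ACCESS_READ)
        else:
            self._buf = self._file.read()
        self.lazy = lazy
        self.chunks: list[FpbChunk] = []
        self._chunk_by_tag: dict[str, FpbChunk] = {}
        self._walk()
        self.metadata = self._parse_meta()
        self._arena: Arena | None = None
        self._ids_cache: dict[int, str] = {}

    # -- container structure

    def _walk(self) -> None:
        buf = self._buf
        size = len(buf)
        if size < 8 or bytes(buf[:8]) != SIGNATURE:
            raise FpbFormatError("bad FPB signature")
        pos = 8
        saw_fend = False
        while pos < size:
            if pos + 12 > size:
                raise FpbFormatError(f"truncated chunk header at offset {pos}")
            (length,) = struct.unpack_from("<Q", buf, pos)
            tag = bytes(buf[pos + 8 : pos + 12]).decode("ascii", "replace")
            payload_off = pos + 12
            if payload_off + length > size:
                raise FpbFormatError(
                    f"truncated chunk {tag!r}: payload of {length} bytes "
                    f"extends past end of file"
                )
            chunk = FpbChunk(tag, payload_off, length)
            self.chunks.append(chunk)
            self._chunk_by_tag.setdefault(tag, chunk)
            pos = payload_off + length
            if tag == "FEND":
                saw_fend = True
                break
        if not saw_fend:
            raise FpbFormatError("missing FEND chunk")
        for tag in _REQUIRED:
            if tag not in self._chunk_by_tag:
                raise FpbFormatError(f"missing required chunk {tag!r}")

    def _payload(self, tag: str) -> memoryview:
        chunk = self._chunk_by_tag[tag]
        return memoryview(self._buf)[chunk.offset : chunk.offset + chunk.length]

    def _parse_meta(self) -> FingerprintMetadata:
        text = bytes(self._payload("META")).decode("utf-8")
        lines = [line for line in text.split("\n") if line]
        header = fps_io.parse_header_lines(lines)
        if header.metadata is None:
            raise FpbFormatError("META chunk lacks a num_bits line")
        return header.metadata

    # -- record count / ids

    @property
    def num_records(self) -> int:
        chunk = self._chunk_by_tag["AREN"]
        _, storage, spacer = struct.unpack_from("<IIB", self._buf, chunk.offset)
        return (chunk.length - 9 - spacer) // storage

    def _fpid_views(self):
        payload = self._payload("FPID")
        (n,) = struct.unpack_from("<I", payload, 0)
        offsets = np.frombuffer(payload, dtype="<u4", count=n + 1, offset=4)
        blob_start = 4 + 4 * (n + 1)
        return n, offsets, payload[blob_start:]

    def id_at(self, i: int) -> str:
        if i in self._ids_cache:
            return self._ids_cache[i]
        n, offsets, blob = self._fpid_views()
        if not 0 <= i < n:
            raise IndexError(i)
        value = bytes(blob[int(offsets[i]) : int(offsets[i + 1])]).decode("utf-8")
        self._ids_cache[i] = value
        return value

    def lookup_id(self, record_id: str) -> list[int]:
        """All record indices with this id (ascending); [] when absent."""
        if "HASH" not in self._chunk_by_tag:
            raise FpbFormatError("missing required chunk 'HASH'")
        return _cdb_lookup(self._payload("HASH"), record_id.encode("utf-8"))

    # -- arena

    @property
    def arena(self) -> Arena:
        if self._arena is None:
            self._arena = self._load_arena()
        return self._arena

    def _load_arena(self) -> Arena:
        chunk = self._chunk_by_tag["AREN"]
        num_bytes, storage, spacer = struct.unpack_from(
            "<IIB", self._buf, chunk.offset
        )
        if num_bytes != self.metadata.num_bytes:
            raise FpbFormatError(
                f"AREN num_bytes {num_bytes} does not match metadata "
                f"num_bytes {self.metadata.num_bytes}"
            )
        data_off = chunk.offset + 9 + spacer
        n = (chunk.length - 9 - spacer) // storage
        words = np.frombuffer(
            self._buf, dtype=np.uint8, count=n * storage, offset=data_off
        ).reshape(n, storage).view(np.uint64)

        index = None
        if "POPC" in self._chunk_by_tag:
            index = np.frombuffer(self._payload("POPC"), dtype="<i8").astype(np.int64)
            if len(index) != self.metadata.num_bits + 2:
                raise FpbFormatError(
                    f"POPC chunk has {len(index)} entries, expected "
                    f"{self.metadata.num_bits + 2}"
                )
            counts = np.diff(index)
            popcounts = np.repeat(np.arange(len(counts), dtype=np.int64), counts)
        else:
            popcounts = (
                np.bitwise_count(words).sum(axis=1, dtype=np.int64)
                if n
                else np.zeros(0, dtype=np.int64)
            )

        if self.lazy:
            ids: object = _LazyIds(n, self.id_at)
            id_hash = None
        else:
            ids = [self.id_at(i) for i in range(n)]
            id_hash = {}
            for i, rid in enumerate(ids):
                id_hash.setdefault(rid, []).append(i)

        return Arena(
            metadata=self.metadata,
            storage_size=storage,
            words=words,
            popcounts=popcounts,
            ids=ids,  # type: ignore[arg-type]
            popcount_index=index,
            id_hash=id_hash,
            start_padding=spacer,
            _id_lookup=self.lookup_id if self.lazy else None,
        )

    def close(self) -> None:
        if isinstance(self._buf, mmap.mmap):
            try:
                self._buf.close()
            except BufferError:
                # numpy views of the map are still alive; the map is freed
                # when they are garbage collected
                pass
        self._file.close()

    def __enter__(self) -> "FpbFile":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def read_fpb(source, lazy: bool = True) -> FpbFile:
    """Open an FPB file; ``lazy=True`` memory-maps and defers payloads."""
    return FpbFile(source, lazy=lazy)


def lookup_id(fpb: FpbFile, record_id: str) -> list[int]:
    """Record indices whose id equals ``record_id``, via the HASH chunk."""
    return fpb.lookup_id(record_id)


# ---------------------------------------------------------------------------
# Collated (memory-bounded) writing


def collated_write(
    record_stream: Iterable[FingerprintRecord],
    sink,
    memory_budget: int,
    metadata: FingerprintMetadata | None = None,
) -> int:
    """Write an FPB file from a stream that may not fit in memory.

    Records are accumulated into sorted runs of at most ``memory_budget``
    bytes (fingerprint storage + id text), each spilled to a temporary FPB
    file; the runs are then merged popcount bin by popcount bin into the
    final file.  The output is byte-compatible with :func:`write_fpb` for
    the same logical content, except that the order of ids *within* one
    popcount bin follows first-seen run order.
    """
    if memory_budget < 1:
        raise FpbFormatError("memory budget must be positive")
    run_paths: list[str] = []
    run: list[FingerprintRecord] = []
    run_bytes = 0
    storage = None
    tmpdir = tempfile.mkdtemp(prefix="fpsim-collate-")

    def record_cost(record: FingerprintRecord) -> int:
        slot = ((len(record.fingerprint) + 7) // 8) * 8
        return slot + len(record.id.encode("utf-8")) + 24

    def flush() -> None:
        nonlocal run, run_bytes
        if not run:
            return
        arena = build_arena(run, metadata, sort=True)
        path = os.path.join(tmpdir, f"run-{len(run_paths)}.fpb")
        write_fpb(arena, path)
        run_paths.append(path)
        run = []
        run_bytes = 0

    try:
        for record in record_stream:
            cost = record_cost(record)
            if cost > memory_budget:
                raise FpbFormatError(
                    f"memory budget of {memory_budget} bytes cannot hold even "
                    f"one record ({cost} bytes)"
                )
            if run_bytes + cost > memory_budget and run:
                flush()
            run.append(record)
            run_bytes += cost

        if not run_paths:
            # Everything fit in one run: identical path to write_fpb.
            arena = build_arena(run, metadata, sort=True)
            return write_fpb(arena, sink)
        flush()

        readers = [read_fpb(path, lazy=True) for path in run_paths]
        try:
            meta = metadata or readers[0].metadata
            num_bits = meta.num_bits
            arenas = [r.arena for r in readers]
            if storage is None:
                storage = arenas[0].storage_size
            n_total = sum(len(a) for a in arenas)

            bin_counts = np.zeros(num_bits + 1, dtype=np.int64)
            for a in arenas:
                bin_counts += np.diff(a.popcount_index)
            index = np.zeros(num_bits + 2, dtype=np.int64)
            np.cumsum(bin_counts, out=index[1:])

            ids: list[str] = []
            for b in range(num_bits + 1):
                for a in arenas:
                    s, e = int(a.popcount_index[b]), int(a.popcount_index[b + 1])
                    ids.extend(a.ids[s:e])

            def fingerprint_chunks() -> Iterator[bytes]:
                for b in range(num_bits + 1):
                    for a in arenas:
                        s, e = int(a.popcount_index[b]), int(a.popcount_index[b + 1])
                        if s != e:
                            yield a.words[s:e].tobytes()

            return _write_stream(
                sink, meta, n_total, storage, fingerprint_chunks(), index, ids
            )
        finally:
            for r in readers:
                r.close()
    finally:
        for path in run_paths:
            try:
                os.unlink(path)
            except OSError:
                pass
        try:
            os.rmdir(tmpdir)
        except OSError:
            pass
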
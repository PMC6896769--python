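"""Read and write the FPS line-oriented fingerprint text format.

An FPS file has an optional header of '#'-prefixed lines — an optional
version line (``#FPS1``) followed by ``#key=value`` metadata lines — and
then one record per line with two or more tab-separated fields: the
hex-encoded fingerprint and the record id.  Fields beyond the id are
unspecified and preserved verbatim on pass-through.  Files may be gzip
compressed; compression is detected from the magic bytes or a ``.gz``
suffix.

Validation is total: every line of the file is checked and errors carry the
1-based line number, so an FPS reader doubles as an FPS validator.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
import os
from typing import IO, Iterable, Iterator

from .core import (
    FingerprintError,
    FingerprintMetadata,
    FingerprintRecord,
    HexFormatError,
    RationalThreshold,
    hex_decode,
    hex_encode,
)

__all__ = [
    "FpsFormatError",
    "FpsHeader",
    "FpsReader",
    "read_fps",
    "write_fps",
    "format_header_lines",
    "parse_header_lines",
    "parse_type_string",
    "format_type_string",
    "parse_threshold",
]

FPS_VERSION_LINE = "#FPS1"

_KNOWN_KEYS = ("num_bits", "type", "software", "source", "date")


class FpsFormatError(FingerprintError):
    """FPS parse error carrying the offending 1-based line number."""

    def __init__(self, message: str, lineno: int | None = None):
        self.lineno = lineno
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)


@dataclasses.dataclass
class FpsHeader:
    version: str | None = None
    metadata: FingerprintMetadata | None = None
    comments: list[str] = dataclasses.field(default_factory=list)


# ---------------------------------------------------------------------------
# Header parsing / formatting


def parse_header_lines(lines: Iterable[str], start_lineno: int = 1) -> FpsHeader:
    """Parse '#'-prefixed header lines (leading '#', no newline)."""
    header = FpsHeader()
    fields: dict = {"sources": [], "extra_lines": []}
    num_bits = None
    for offset, line in enumerate(lines):
        lineno = start_lineno + offset
        if not line.startswith("#"):
            raise FpsFormatError("header line must start with '#'", lineno)
        body = line[1:]
        if offset == 0 and body.startswith("FPS") and "=" not in body:
            header.version = line
            continue
        if "=" not in body:
            # Unparseable '#' line: carried as an opaque comment.
            header.comments.append(line)
            continue
        key, value = body.split("=", 1)
        if key == "num_bits":
            try:
                num_bits = int(value)
            except ValueError:
                raise FpsFormatError(f"invalid num_bits value {value!r}", lineno)
            if num_bits < 1:
                raise FpsFormatError(f"num_bits must be positive, got {num_bits}", lineno)
        elif key == "type":
            fields["type"] = value
        elif key == "software":
            fields["software"] = value
        elif key == "source":
            fields["sources"].append(value)
        elif key == "date":
            fields["date"] = value
        else:
            fields["extra_lines"].append((key, value))
    header.metadata = None
    header._fields = fields  # type: ignore[attr-defined]
    header._num_bits = num_bits  # type: ignore[attr-defined]
    if num_bits is not None:
        header.metadata = FingerprintMetadata(num_bits=num_bits, **fields)
    return header


def format_header_lines(
    metadata: FingerprintMetadata, version: str | None = FPS_VERSION_LINE
) -> list[str]:
    """Canonical FPS header lines (leading '#', no trailing newline)."""
    lines = []
    if version:
        lines.append(version)
    lines.append(f"#num_bits={metadata.num_bits}")
    if metadata.type is not None:
        lines.append(f"#type={metadata.type}")
    if metadata.software is not None:
        lines.append(f"#software={metadata.software}")
    for source in metadata.sources:
        lines.append(f"#source={source}")
    if metadata.date is not None:
        lines.append(f"#date={metadata.date}")
    for key, value in metadata.extra_lines:
        lines.append(f"#{key}={value}")
    return lines


# ---------------------------------------------------------------------------
# Reading


def _open_source(source, gzip_auto: bool = True) -> IO[str]:
    if isinstance(source, (str, os.PathLike)):
        path = os.fspath(source)
        raw: IO[bytes] = open(path, "rb")
    elif isinstance(source, io.TextIOBase):
        return source
    else:
        raw = source
    if gzip_auto:
        if not raw.seekable():
            raw = io.BufferedReader(raw)  # type: ignore[arg-type]
        if isinstance(raw, io.BufferedReader):
            head = raw.peek(2)[:2]
        else:
            head = raw.read(2)
            raw.seek(-len(head), os.SEEK_CUR)
        if head == b"\x1f\x8b":
            return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8")
    return io.TextIOWrapper(raw, encoding="utf-8")


class FpsReader:
    """Streaming FPS reader.

    Iterating yields :class:`FingerprintRecord` objects in file order.  The
    parsed :class:`FpsHeader` is available as ``.header`` immediately; when
    the header lacks a ``num_bits`` line the bit length is inferred as
    ``8 * num_bytes`` from the first record.
    """

    def __init__(self, source, gzip_auto: bool = True):
        self._stream = _open_source(source, gzip_auto)
        self._lineno = 0
        self._pending: FingerprintRecord | None = None
        self._num_bytes: int | None = None
        self.header = self._parse_header()
        if self.header.metadata is None:
            # Infer num_bits from the first record, if any.
            first = self._next_record()
            if first is not None:
                self._pending = first
                num_bits = len(first.fingerprint) * 8
            else:
                num_bits = None
            fields = getattr(self.header, "_fields", {"sources": [], "extra_lines": []})
            if num_bits is not None:
                self.header.metadata = FingerprintMetadata(num_bits=num_bits, **fields)

    @property
    def metadata(self) -> FingerprintMetadata | None:
        return self.header.metadata

    def _readline(self) -> str | None:
        line = self._stream.readline()
        if line == "":
            return None
        self._lineno += 1
        return line

    def _parse_header(self) -> FpsHeader:
        header_lines: list[str] = []
        while True:
            pos_line = self._readline()
            if pos_line is None:
                self._first_record_line = None
                break
            stripped = pos_line.rstrip("\n").rstrip("\r")
            if stripped.startswith("#"):
                header_lines.append(stripped)
            else:
                self._first_record_line = (self._lineno, stripped)
                break
        header = parse_header_lines(header_lines)
        if header.metadata is not None:
            self._num_bytes = header.metadata.num_bytes
        return header

    def _parse_record_line(self, lineno: int, line: str) -> FingerprintRecord:
        if line.startswith("#"):
            raise FpsFormatError("header line after first record", lineno)
        fields = line.split("\t")
        if len(fields) < 2:
            raise FpsFormatError(
                "record needs at least two tab-separated fields "
                "(hex fingerprint and id)",
                lineno,
            )
        hex_fp, record_id = fields[0], fields[1]
        try:
            fp = hex_decode(hex_fp)
        except HexFormatError as exc:
            raise FpsFormatError(f"bad fingerprint field: {exc}", lineno) from exc
        if not record_id:
            raise FpsFormatError("empty record id", lineno)
        if self._num_bytes is None:
            self._num_bytes = len(fp)
        elif len(fp) != self._num_bytes:
            raise FpsFormatError(
                f"fingerprint is {len(fp)} bytes but expected {self._num_bytes}",
                lineno,
            )
        return FingerprintRecord(record_id, fp, tuple(fields[2:]))

    def _next_record(self) -> FingerprintRecord | None:
        if self._first_record_line is not None:
            lineno, line = self._first_record_line
            self._first_record_line = None
            return self._parse_record_line(lineno, line)
        raw = self._readline()
        if raw is None:
            return None
        line = raw.rstrip("\n").rstrip("\r")
        if line == "":
            raise FpsFormatError("blank line", self._lineno)
        return self._parse_record_line(self._lineno, line)

    def __iter__(self) -> Iterator[FingerprintRecord]:
        while True:
            if self._pending is not None:
                record, self._pending = self._pending, None
            else:
                record = self._next_record()
                if record is None:
                    return
            yield record

    def close(self) -> None:
        self._stream.close()

    def __enter__(self) -> "FpsReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def read_fps(source, gzip_auto: bool = True) -> FpsReader:
    """Open an FPS file (optionally gzip compressed) for streaming reads."""
    return FpsReader(source, gzip_auto=gzip_auto)


# ---------------------------------------------------------------------------
# Writing


def write_fps(
    header,
    records: Iterable[FingerprintRecord],
    sink,
    compress: bool | None = None,
) -> int:
    """Write an FPS file; returns the number of records written.

    ``header`` may be an :class:`FpsHeader` or a bare
    :class:`FingerprintMetadata`.  ``compress=None`` gzips when the sink
    path ends in ``.gz``.
    """
    if isinstance(header, FingerprintMetadata):
        metadata = header
        version = FPS_VERSION_LINE
    else:
        metadata = header.metadata
        version = header.version or FPS_VERSION_LINE
    if metadata is None:
        raise FingerprintError("cannot write FPS without metadata")

    own = False
    if isinstance(sink, (str, os.PathLike)):
        path = os.fspath(sink)
        if compress is None:
            compress = path.endswith(".gz")
        if compress:
            stream: IO[str] = io.TextIOWrapper(
                gzip.open(path, "wb"), encoding="utf-8", newline="\n"
            )
        else:
            stream = open(path, "w", encoding="utf-8", newline="\n")
        own = True
    else:
        stream = sink

    count = 0
    try:
        for line in format_header_lines(metadata, version):
            stream.write(line + "\n")
        num_bytes = metadata.num_bytes
        for record in records:
            if len(record.fingerprint) != num_bytes:
                raise FingerprintError(
                    f"record {record.id!r}: fingerprint is "
                    f"{len(record.fingerprint)} bytes, expected {num_bytes}"
                )
            fields = [hex_encode(record.fingerprint), record.id]
            fields.extend(record.extra)
            stream.write("\t".join(fields) + "\n")
            count += 1
    finally:
        if own:
            stream.close()
    return count


# ---------------------------------------------------------------------------
# Type strings


def parse_type_string(type_string: str):
    """Split a fingerprint type string into (family, version, parameters).

    The first space-separated term is ``family[/version]``; every remaining
    term must be a ``key=value`` pair.  Two canonical type strings describe
    the same fingerprint type if and only if they are string-equal.
    """
    terms = type_string.split(" ")
    if not terms or not terms[0]:
        raise FingerprintError(f"empty fingerprint type string: {type_string!r}")
    first = terms[0]
    if "/" in first:
        family, version = first.split("/", 1)
    else:
        family, version = first, None
    parameters: list[tuple[str, str]] = []
    for term in terms[1:]:
        if "=" not in term:
            raise FingerprintError(
                f"type string term {term!r} is not a key=value pair"
            )
        key, value = term.split("=", 1)
        parameters.append((key, value))
    return family, version, parameters


def format_type_string(family: str, version: str | None, parameters) -> str:
    first = family if version is None else f"{family}/{version}"
    return " ".join([first] + [f"{k}={v}" for k, v in parameters])


def parse_threshold(text: str) -> RationalThreshold:
    """Parse a plain decimal similarity threshold in [0, 1].

    The decimal is converted to its nearest double and then to an exact
    rational, so e.g. the written-out decimal expansion of 0.7 + 1e-17
    produces the identical threshold as "0.7".
    """
    return RationalThreshold.from_string(text)
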
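"""Fundamental fingerprint types, codecs and similarity kernels.

A *fingerprint* is a fixed-length binary bit vector describing a molecule,
stored as a byte string.  The bit convention throughout this package is the
FPS one: bit ``k`` of the fingerprint is bit ``k mod 8`` of byte
``floor(k / 8)`` — bytes are little-endian, bits within a byte are numbered
from the least significant bit.  In the two-characters-per-byte hex
representation the nibbles therefore appear in "1032" order.

Similarity between fingerprints is measured with the Tanimoto (Jaccard)
coefficient ``c / (A + B - c)`` where ``A`` and ``B`` are the two popcounts
and ``c`` the intersection popcount, or with the asymmetric Tversky
generalization ``c / (alpha*(A-c) + beta*(B-c) + c)``.  Two all-zero
fingerprints have a similarity of 0 by convention.

All accept/reject decisions in this package are made with exact integer
arithmetic; floating point appears only in reported scores.  The
:class:`RationalThreshold` type carries a similarity threshold as an exact
integer fraction for that purpose.
"""

from __future__ import annotations

import dataclasses
import math
import re
import warnings
from fractions import Fraction
from typing import Callable, NamedTuple

__all__ = [
    "FingerprintError",
    "HexFormatError",
    "FingerprintMetadata",
    "FingerprintRecord",
    "RationalThreshold",
    "PopcountKernel",
    "register_kernel",
    "get_kernel",
    "list_kernels",
    "hex_decode",
    "hex_encode",
    "bit_indices",
    "fingerprint_from_bits",
    "popcount",
    "intersect_popcount",
    "tanimoto",
    "tversky",
    "min_required_popcount",
    "as_threshold",
    "TVERSKY_SCALE",
    "TVERSKY_MAX_WEIGHT",
]


class FingerprintError(ValueError):
    """Base class for fingerprint data errors."""


class HexFormatError(FingerprintError):
    """A hex-encoded fingerprint is malformed."""


# ---------------------------------------------------------------------------
# Domain types


@dataclasses.dataclass
class FingerprintMetadata:
    """Describes a fingerprint type: its length and provenance.

    ``num_bits`` is the true bit length (166 for MACCS keys, 881 for
    PubChem/CACTVS keys, ...).  When it is not a multiple of 8 the trailing
    bits of the last byte must be zero-padded.  The remaining fields mirror
    the FPS header metadata lines.
    """

    num_bits: int
    type: str | None = None
    software: str | None = None
    sources: list[str] = dataclasses.field(default_factory=list)
    date: str | None = None
    extra_lines: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if not isinstance(self.num_bits, int) or self.num_bits < 1:
            raise FingerprintError(
                f"num_bits must be a positive integer, got {self.num_bits!r}"
            )

    @property
    def num_bytes(self) -> int:
        return (self.num_bits + 7) // 8

    def check_fingerprint(self, fp: bytes) -> None:
        """Validate a fingerprint byte string against this metadata."""
        if len(fp) != self.num_bytes:
            raise FingerprintError(
                f"fingerprint is {len(fp)} bytes, expected {self.num_bytes}"
            )
        extra = self.num_bytes * 8 - self.num_bits
        if extra and fp[-1] >> (8 - extra):
            raise FingerprintError(
                f"bits at index >= num_bits={self.num_bits} must be zero"
            )


class FingerprintRecord(NamedTuple):
    """An identified fingerprint: ``(id, fingerprint, extra)``.

    ``extra`` carries any additional tab-separated FPS record fields; it is
    preserved on pass-through but otherwise ignored by the API.
    """

    id: str
    fingerprint: bytes
    extra: tuple[str, ...] = ()


_MAX_DENOMINATOR = 2**62


@dataclasses.dataclass(frozen=True)
class RationalThreshold:
    """A similarity threshold as an exact integer fraction p/q <= original.

    Every finite double is exactly an integer over a power of two, so for
    thresholds representable in int64-denominator range the fraction equals
    the double exactly, which makes the division-free rejection test
    ``c*q >= p*(A+B-c)`` also the final acceptance test.
    """

    p: int
    q: int
    original: float

    @classmethod
    def from_float(cls, value: float) -> "RationalThreshold":
        value = float(value)
        if math.isnan(value) or not 0.0 <= value <= 1.0:
            raise FingerprintError(f"threshold must be in [0, 1], got {value!r}")
        frac = Fraction(value)
        if frac.denominator > _MAX_DENOMINATOR:
            # Only reachable for subnormal-scale thresholds; round down so
            # p/q <= value still holds.
            frac = Fraction(math.floor(value * _MAX_DENOMINATOR), _MAX_DENOMINATOR)
        return cls(p=frac.numerator, q=frac.denominator, original=value)

    _DECIMAL_RE = re.compile(r"^[+]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")

    @classmethod
    def from_string(cls, text: str) -> "RationalThreshold":
        """Parse a plain decimal threshold (no arithmetic expressions).

        The text is converted to the nearest double first, so any decimal
        whose nearest double equals that of "0.7" behaves identically to a
        threshold of 0.7.
        """
        text = text.strip()
        if not cls._DECIMAL_RE.match(text):
            raise FingerprintError(f"not a plain decimal threshold: {text!r}")
        return cls.from_float(float(text))

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.p, self.q)

    def passes(self, c: int, a: int, b: int) -> bool:
        """Exact test for similarity(c, a, b) >= threshold."""
        return c * self.q >= self.p * (a + b - c)

    def min_intersect(self, a: int, b: int) -> int:
        """Minimum intersection popcount for Tanimoto(A=a, B=b) >= threshold.

        Computed as ``ceil(p*(a+b) / (p+q))``, which is ``ceil(T(A+B)/(1+T))``
        evaluated without floating-point error.
        """
        return -((-self.p * (a + b)) // (self.p + self.q))


def as_threshold(value) -> RationalThreshold:
    """Coerce a float, decimal string or RationalThreshold."""
    if isinstance(value, RationalThreshold):
        return value
    if isinstance(value, str):
        return RationalThreshold.from_string(value)
    return RationalThreshold.from_float(value)


# ---------------------------------------------------------------------------
# Hex codec

_HEX_CHARS = frozenset("0123456789abcdefABCDEF")


def hex_decode(hex_text: str) -> bytes:
    """Decode a hex-encoded fingerprint to its byte string.

    The encoding is two hex characters per byte, bytes in little-endian
    bit order: "0100" has only bit 0 set, "2000" only bit 5, "c218" bits
    {1, 6, 7, 11, 12}.
    """
    if not hex_text:
        raise HexFormatError("empty hex fingerprint")
    if len(hex_text) % 2:
        raise HexFormatError(
            f"hex fingerprint length {len(hex_text)} is odd; must be a multiple of 2"
        )
    try:
        return bytes.fromhex(hex_text)
    except ValueError:
        for pos, ch in enumerate(hex_text):
            if ch not in _HEX_CHARS:
                raise HexFormatError(
                    f"non-hex character {ch!r} at position {pos}"
                ) from None
        raise  # pragma: no cover


def hex_encode(fp: bytes) -> str:
    """Encode a fingerprint byte string as lowercase hex."""
    if not fp:
        raise HexFormatError("empty fingerprint")
    return fp.hex()


def bit_indices(fp: bytes) -> list[int]:
    """Indices of the set bits, under the package bit convention."""
    out = []
    for byte_i, byte in enumerate(fp):
        base = byte_i * 8
        while byte:
            low = byte & -byte
            out.append(base + low.bit_length() - 1)
            byte ^= low
    return out


def fingerprint_from_bits(bits, num_bytes: int) -> bytes:
    """Build a fingerprint byte string with the given bit indices set."""
    value = 0
    for b in bits:
        if not 0 <= b < num_bytes * 8:
            raise FingerprintError(f"bit index {b} out of range for {num_bytes} bytes")
        value |= 1 << b
    return value.to_bytes(num_bytes, "little")


# ---------------------------------------------------------------------------
# Popcount kernels


@dataclasses.dataclass(frozen=True)
class PopcountKernel:
    """A pluggable popcount implementation.

    Kernel choice is a performance detail only: every registered kernel
    must return identical values on identical inputs.
    """

    name: str
    word_size: int
    popcount: Callable[[bytes], int]
    intersect_popcount: Callable[[bytes, bytes], int]


def _popcount_words(fp: bytes) -> int:
    return int.from_bytes(fp, "little").bit_count()


def _intersect_words(fp1: bytes, fp2: bytes) -> int:
    return (int.from_bytes(fp1, "little") & int.from_bytes(fp2, "little")).bit_count()


def _popcount_bitloop(fp: bytes) -> int:
    total = 0
    for byte in fp:
        for k in range(8):
            total += (byte >> k) & 1
    return total


def _intersect_bitloop(fp1: bytes, fp2: bytes) -> int:
    total = 0
    for b1, b2 in zip(fp1, fp2):
        both = b1 & b2
        for k in range(8):
            total += (both >> k) & 1
    return total


_KERNELS: dict[str, PopcountKernel] = {}


def register_kernel(kernel: PopcountKernel) -> None:
    _KERNELS[kernel.name] = kernel


def get_kernel(name: str | None = None) -> PopcountKernel:
    if name is None:
        name = "word"
    try:
        return _KERNELS[name]
    except KeyError:
        raise KeyError(f"unknown popcount kernel {name!r}; known: {sorted(_KERNELS)}")


def list_kernels() -> list[str]:
    return sorted(_KERNELS)


register_kernel(PopcountKernel("word", 8, _popcount_words, _intersect_words))
# per-bit loop: slow reference oracle
register_kernel(PopcountKernel("bitloop", 1, _popcount_bitloop, _intersect_bitloop))


def popcount(fp: bytes, kernel: str | None = None) -> int:
    """Number of set bits in the fingerprint."""
    return get_kernel(kernel).popcount(fp)


def intersect_popcount(fp1: bytes, fp2: bytes, kernel: str | None = None) -> int:
    """popcount(fp1 AND fp2); the single popcount needed per comparison."""
    if len(fp1) != len(fp2):
        raise FingerprintError(
            f"fingerprint length mismatch: {len(fp1)} != {len(fp2)}"
        )
    return get_kernel(kernel).intersect_popcount(fp1, fp2)


# ---------------------------------------------------------------------------
# Similarity


def tanimoto(fp1: bytes, fp2: bytes) -> float:
    """Tanimoto similarity c / (A + B - c); 0 if both fingerprints are empty."""
    c = intersect_popcount(fp1, fp2)
    a = popcount(fp1)
    b = popcount(fp2)
    d = a + b - c
    if d == 0:
        return 0.0
    return c / d


TVERSKY_SCALE = 10_000
TVERSKY_MAX_WEIGHT = 10.0


def _scale_weight(value: float, name: str) -> int:
    if not 0.0 <= value <= TVERSKY_MAX_WEIGHT:
        raise FingerprintError(
            f"{name} must be in [0, {TVERSKY_MAX_WEIGHT}], got {value!r}"
        )
    scaled = round(value * TVERSKY_SCALE)
    if abs(value * TVERSKY_SCALE - scaled) > 1e-6:
        warnings.warn(
            f"{name}={value!r} has more than 4 decimal digits; "
            f"rounded to {scaled / TVERSKY_SCALE}",
            stacklevel=3,
        )
    return scaled


def tversky(fp1: bytes, fp2: bytes, alpha: float = 1.0, beta: float = 1.0) -> float:
    """Tversky similarity c / (alpha*(A-c) + beta*(B-c) + c).

    ``alpha`` weights the bits unique to ``fp1`` and ``beta`` those unique
    to ``fp2``; ``alpha == beta == 1`` reduces to the Tanimoto.  Computed
    with integer arithmetic (weights scaled by 10,000 and rounded) and a
    single final division, so self-similarity is exactly 1.0 — the
    floating-point failure mode where it comes out slightly below 1 cannot
    occur.  Returns 0 when both fingerprints are all-zero.
    """
    a_scaled = _scale_weight(alpha, "alpha")
    b_scaled = _scale_weight(beta, "beta")
    c = intersect_popcount(fp1, fp2)
    a = popcount(fp1)
    b = popcount(fp2)
    denom = a_scaled * (a - c) + b_scaled * (b - c) + TVERSKY_SCALE * c
    if denom == 0:
        return 0.0
    return (TVERSKY_SCALE * c) / denom


def min_required_popcount(threshold, a: int, b: int) -> int:
    """Minimum intersection popcount so that Tanimoto(A=a, B=b) >= T.

    This is ``ceil(T*(A+B)/(1+T))`` computed exactly with the threshold's
    integer fraction; any pair with an intersection popcount at or above the
    returned value satisfies the threshold, and no smaller intersection does.
    A threshold of 0 is rejected — threshold-0 searches match everything and
    bypass this bound entirely.
    """
    t = as_threshold(threshold)
    if t.p == 0:
        raise FingerprintError("min_required_popcount requires a threshold > 0")
    if a < 0 or b < 0:
        raise FingerprintError("popcounts must be non-negative")
    return t.min_intersect(a, b)
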
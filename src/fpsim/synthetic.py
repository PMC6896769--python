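"""Synthetic fingerprint data sets with controlled size and bit density.

Real benchmark sets for similarity search are million-scale samples of
ChEMBL/PubChem fingerprints; this module generates stand-ins of arbitrary
size with a controllable popcount profile so that search behaviour can be
studied without any external download.  Two density models are supported:

* ``uniform`` — every bit is set independently with probability ``p``
  (density).  Popcounts then follow a Binomial(num_bits, p), which is a
  reasonable first-order emulation of hashed fingerprints.
* ``histogram`` — an explicit popcount histogram ``{popcount: count}``; the
  realized bin histogram equals the request exactly, which is useful for
  stress-testing the popcount-binned search paths.
* ``clustered`` — records are per-bit mutations of a fixed pool of cluster
  centers.  Real compound collections are heavily redundant (similar series,
  outright duplicate fingerprints), and that redundancy is what makes the
  nearest-neighbor similarity rise with data set size and BitBound k-nearest
  search scale sublinearly; independent uniform fingerprints lack it.
  Queries drawn from the same centers (same ``center_seed``) behave like
  queries sampled from the data set.

Typical realistic defaults: 2048-bit Morgan-like fingerprints are sparse
(density ~0.024 for ChEMBL), 166-bit MACCS-like keys are dense (~0.25),
and most other types fall above 0.1.  Duplicate fingerprints occur
naturally and are not removed.  Output is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import FingerprintError, FingerprintMetadata, FingerprintRecord
from . import fps_io

__all__ = ["SyntheticSpec", "DEFAULT_DENSITIES", "generate_records", "generate_fps"]

# density defaults per common fingerprint length
DEFAULT_DENSITIES = {166: 0.25, 881: 0.12, 1021: 0.12, 2048: 0.024}


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of one synthetic fingerprint set."""

    num_bits: int
    count: int
    density: float | None = None  # uniform per-bit model
    popcount_hist: dict[int, int] | None = None  # exact histogram model
    n_centers: int | None = None  # clustered model: size of the center pool
    mutation: float = 0.01  # clustered model: per-bit flip probability
    center_seed: int | None = None  # shared center pool across specs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise FingerprintError("count must be >= 1")
        if self.num_bits < 1:
            raise FingerprintError("num_bits must be >= 1")
        if self.density is None and self.popcount_hist is None:
            self.density = DEFAULT_DENSITIES.get(self.num_bits, 0.1)
        if self.density is not None and not 0.0 < self.density < 1.0:
            raise FingerprintError(
                f"density must be inside (0, 1), got {self.density!r}"
            )
        if self.popcount_hist is not None:
            if sum(self.popcount_hist.values()) != self.count:
                raise FingerprintError("popcount histogram must sum to count")
            for b in self.popcount_hist:
                if not 0 <= b <= self.num_bits:
                    raise FingerprintError(f"popcount {b} out of range")
        if self.n_centers is not None:
            if self.n_centers < 1:
                raise FingerprintError("n_centers must be >= 1")
            if not 0.0 <= self.mutation < 0.5:
                raise FingerprintError("mutation must be in [0, 0.5)")
        if self.center_seed is None:
            self.center_seed = self.seed

    @property
    def metadata(self) -> FingerprintMetadata:
        if self.popcount_hist is not None:
            model = "model=histogram"
        elif self.n_centers is not None:
            model = (
                f"model=clustered density={self.density} "
                f"n_centers={self.n_centers} mutation={self.mutation} "
                f"center_seed={self.center_seed}"
            )
        else:
            model = f"model=uniform density={self.density}"
        return FingerprintMetadata(
            num_bits=self.num_bits,
            type=f"Synthetic/1 {model} seed={self.seed}",
            software=f"fpsim-synthetic num_bits={self.num_bits}",
        )


def _pack_rows(bits: np.ndarray, num_bits: int) -> np.ndarray:
    """Pack a boolean (n, num_bits) array into FPS byte order."""
    return np.packbits(bits, axis=1, bitorder="little")


def generate_records(spec: SyntheticSpec) -> list[FingerprintRecord]:
    """Generate the fingerprint records for a spec (deterministic by seed)."""
    rng = np.random.default_rng(spec.seed)
    n, nb = spec.count, spec.num_bits
    num_bytes = (nb + 7) // 8

    if spec.n_centers is not None:
        center_rng = np.random.default_rng(spec.center_seed)
        centers = center_rng.random((spec.n_centers, nb)) < spec.density
        assign = rng.integers(spec.n_centers, size=n)
        chunks = []
        chunk_rows = max(1, (1 << 24) // nb)
        for start in range(0, n, chunk_rows):
            stop = min(start + chunk_rows, n)
            bits = centers[assign[start:stop]] ^ (
                rng.random((stop - start, nb)) < spec.mutation
            )
            chunks.append(_pack_rows(bits, nb))
        packed = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
    elif spec.popcount_hist is not None:
        rows = np.zeros((n, nb), dtype=bool)
        row = 0
        for b in sorted(spec.popcount_hist):
            for _ in range(spec.popcount_hist[b]):
                if b:
                    rows[row, rng.choice(nb, size=b, replace=False)] = True
                row += 1
        rng.shuffle(rows, axis=0)
        packed = _pack_rows(rows, nb)
    else:
        # chunked so large sets do not hold the full boolean matrix
        chunks = []
        chunk_rows = max(1, (1 << 24) // nb)
        for start in range(0, n, chunk_rows):
            stop = min(start + chunk_rows, n)
            bits = rng.random((stop - start, nb)) < spec.density
            chunks.append(_pack_rows(bits, nb))
        packed = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]

    width = len(str(n))
    return [
        FingerprintRecord(f"SYN{i:0{width}d}", packed[i, :num_bytes].tobytes())
        for i in range(n)
    ]


def generate_fps(spec: SyntheticSpec, sink) -> int:
    """Write a synthetic set as an FPS file; returns the record count."""
    return fps_io.write_fps(spec.metadata, generate_records(spec), sink)
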
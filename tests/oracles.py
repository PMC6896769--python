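"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's numpy search paths: fingerprints are
Python big integers, similarity decisions use exact Fraction comparisons,
and every target is visited (no BitBound pruning).
"""

from fractions import Fraction


def fp_int(fp: bytes) -> int:
    return int.from_bytes(fp, "little")


def pair_stats(query: bytes, target: bytes):
    q, t = fp_int(query), fp_int(target)
    c = (q & t).bit_count()
    return c, q.bit_count(), t.bit_count()


def tanimoto_fraction(query: bytes, target: bytes) -> Fraction:
    c, a, b = pair_stats(query, target)
    d = a + b - c
    return Fraction(c, d) if d else Fraction(0)


def brute_threshold(targets: list[bytes], query: bytes, threshold) -> list[int]:
    """Indices of all targets with exact Tanimoto >= threshold."""
    t = Fraction(float(threshold))
    return [
        i for i, fp in enumerate(targets) if tanimoto_fraction(query, fp) >= t
    ]


def brute_knearest(targets: list[bytes], query: bytes, k: int,
                   min_threshold=0.0) -> list[int]:
    """Top-k target indices by exact score, ties broken by ascending index."""
    t = Fraction(float(min_threshold))
    scored = []
    for i, fp in enumerate(targets):
        s = tanimoto_fraction(query, fp)
        if t > 0 and s < t:
            continue
        scored.append((s, i))
    scored.sort(key=lambda x: (-x[0], x[1]))
    return [i for _, i in scored[:k]]
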
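"""Shared low-level helpers: base encoding, exact fraction thresholds,
coordinate conversions.

Bases are stored internally as uint8 codes 0..3 (A,C,G,T); -1 / 255 never
appear in valid genotype data.  All genomic coordinates in the package are
1-based inclusive (VCF convention); BED output is the only 0-based,
half-open surface and every conversion goes through :func:`to_bed_interval`.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
CODE_TO_BASE = np.frombuffer(BASES.encode(), dtype=np.uint8)

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_TO_CODE.items():
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def encode_seq(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string to uint8 codes 0..3."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"non-ACGT base {bad!r} in sequence")
    return codes


def decode_seq(codes: np.ndarray) -> str:
    """Decode uint8 codes 0..3 back to an A/C/G/T string."""
    return CODE_TO_BASE[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def as_fraction(x: float | int | str | Fraction) -> Fraction:
    """Represent a threshold exactly, via its decimal literal.

    ``as_fraction(0.95) == Fraction(19, 20)`` — so strict comparisons such
    as "strictly more than 95% of reads" are exact in integer arithmetic
    and 19 alt reads out of 20 never pass through float rounding.
    """
    if isinstance(x, Fraction):
        return x
    return Fraction(str(x))


def exceeds_fraction(count, total, threshold: Fraction):
    """Elementwise ``count / total > threshold`` in exact integer arithmetic.

    Works on scalars or numpy integer arrays; ``total`` may contain zeros
    (a zero denominator never exceeds a nonnegative threshold).
    """
    count = np.asarray(count, dtype=np.int64)
    total = np.asarray(total, dtype=np.int64)
    return count * threshold.denominator > total * threshold.numerator


def to_bed_interval(position: int) -> tuple[int, int]:
    """Convert a 1-based inclusive site to a 0-based half-open BED interval."""
    if position < 1:
        raise ValueError(f"1-based position must be >= 1, got {position}")
    return position - 1, position


REVCOMP = str.maketrans("ACGTRYKMBVDHSWN", "TGCAYRMKVBHDSWN")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-degeneracy aware."""
    return seq.translate(REVCOMP)[::-1]
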
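"""Low-level DNA string utilities shared across the package.

Sequences are plain upper-case strings over the alphabet ACGTN.  For the
alignment kernels they are encoded as ``int8`` arrays with A,C,G,T -> 0..3
and every other symbol (including N) -> 4.  Code 4 never matches anything,
so assembly gaps cannot create spurious alignment columns.
"""

from __future__ import annotations

import numpy as np

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CODES = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _CODES[ord(_c)] = _i
    _CODES[ord(_c.lower())] = _i

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

VALID = set("ACGTNacgtn")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_RC)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODES[raw]


def decode(codes: np.ndarray) -> str:
    return _BASES[np.asarray(codes, dtype=np.int64)].tobytes().decode("ascii")


def check_dna(seq: str, name: str = "sequence") -> None:
    """Raise ValueError if *seq* contains symbols outside ACGTN."""
    bad = set(seq) - VALID
    if bad:
        raise ValueError(f"{name} contains non-ACGTN characters: {sorted(bad)!r}")


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string of length *n*."""
    return decode(rng.integers(0, 4, size=n))


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit k-mer codes of an encoded sequence.

    Returns ``(kcodes, valid)`` of length ``len(codes) - k + 1`` where
    ``valid`` is False for windows containing an ambiguous base.
    """
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    kcodes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    c = codes.astype(np.int64)
    for i in range(k):
        window = c[i : i + n]
        kcodes = kcodes * 4 + np.where(window < 4, window, 0)
        valid &= window < 4
    return kcodes, valid
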
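"""Small DNA helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

BASES = "ACGT"

# uint8 codes for vectorised consensus: A=0 C=1 G=2 T=3 N=4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode DNA to uint8 codes (A=0,C=1,G=2,T=3, anything else=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def is_dna(seq: str, allow_n: bool = False) -> bool:
    alphabet = set("ACGTN" if allow_n else "ACGT")
    return len(seq) > 0 and set(seq) <= alphabet
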
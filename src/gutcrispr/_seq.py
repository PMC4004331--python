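"""Low-level DNA sequence helpers shared across the package.

All sequences are upper-case strings over the alphabet {A, C, G, T, N}.
``N`` never counts as a match in any comparison, which makes every
mismatch count conservative with respect to ambiguous bases.
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# numeric encoding used by the vectorised scanners; N gets its own code
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
N_CODE = 4

_ENCODE_TABLE = np.full(256, N_CODE, dtype=np.uint8)
for _base, _c in _CODE.items():
    _ENCODE_TABLE[ord(_base)] = _c
    _ENCODE_TABLE[ord(_base.lower())] = _c


def revcomp(seq: str) -> str:
    """Reverse complement; an involution on {A,C,G,T,N} strings."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Strand-insensitive representative: min(seq, revcomp(seq))."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def hamming(a: str, b: str) -> int:
    """Ungapped mismatch count between equal-length strings; N never matches."""
    if len(a) != len(b):
        raise ValueError(f"hamming() needs equal lengths, got {len(a)} and {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def mismatch_profile(window_codes: np.ndarray, query_codes: np.ndarray) -> np.ndarray:
    """Vectorised per-window mismatch counts; N (code 4) on either side mismatches."""
    neq = window_codes != query_codes
    is_n = (window_codes == N_CODE) | (query_codes == N_CODE)
    return (neq | is_n).sum(axis=-1)


def validate_dna(seq: str, *, strict: bool = True) -> str:
    """Upper-case and validate a sequence; map illegal characters to N when not strict."""
    s = seq.upper()
    if set(s) <= DNA_ALPHABET:
        return s
    if strict:
        bad = sorted(set(s) - DNA_ALPHABET)
        raise ValueError(f"illegal DNA characters: {bad}")
    return "".join(c if c in DNA_ALPHABET else "N" for c in s)
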
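"""Nucleotide encoding helpers shared by the simulator, mapper and paralog search.

Sequences are held as uint8 arrays: A,C,G,T -> 0..3, N -> 4, anything else -> 5.
Codes >= 4 never match anything (including themselves), so an N in a read or a
target always counts as a mismatch.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_ENC = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_ENC[ord("N")] = 4
_ENC[ord("n")] = 4

# complement for codes 0..5 (N -> N, other -> other)
_COMP = np.array([3, 2, 1, 0, 4, 5], dtype=np.uint8)

_DEC = np.frombuffer(b"ACGTNX", dtype=np.uint8)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into a uint8 code array."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def comp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(COMPLEMENT)[::-1]


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Mismatch count between equal-length code arrays; codes >= 4 never match."""
    return int(np.count_nonzero((a != b) | (a >= 4)))


def mismatch_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a != b) | (a >= 4) | (b >= 4)


def kmer_keys(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer integer keys over a code array.

    Returns (keys, valid) where valid marks windows free of non-ACGT codes.
    Keys are base-4 packed into int64.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = ~np.any(win >= 4, axis=1)
    pows = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    keys = win.astype(np.int64) @ pows
    return keys, valid
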
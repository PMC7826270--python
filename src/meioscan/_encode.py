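"""2-bit nucleotide codes and k-mer packing shared by the simulators and the mapper.

Bases A,C,G,T are coded 0..3; the value ``SENTINEL`` (4) is used to pad
between chromosomes in concatenated genome arrays so that no window of
real sequence ever crosses a chromosome boundary. Sentinel positions are
never k-mer indexed and mismatch every read base.
"""

from __future__ import annotations

import numpy as np

SENTINEL = np.uint8(4)

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

_LUT = np.full(256, SENTINEL, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


def encode(seq: str | bytes | bytearray) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes (non-ACGT -> SENTINEL)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    raw = np.frombuffer(bytes(seq), dtype=np.uint8)
    return _LUT[raw]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back into a nucleotide string (SENTINEL -> N)."""
    return _BASES[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array (codes must be < 4)."""
    return (3 - codes[::-1]).astype(np.uint8)


def pack_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every rolling k-mer of ``codes`` into a uint64 (2 bits/base).

    ``codes`` must contain only values < 4 and k <= 31.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    c = codes.astype(np.uint64)
    for j in range(k):
        out <<= np.uint64(2)
        out |= c[j : j + n]
    return out


def pack_columns(mat: np.ndarray, start: int, k: int) -> np.ndarray:
    """Pack columns [start, start+k) of a (N, L) read matrix into uint64 k-mers."""
    out = np.zeros(mat.shape[0], dtype=np.uint64)
    m = mat.astype(np.uint64, copy=False)
    for j in range(start, start + k):
        out <<= np.uint64(2)
        out |= m[:, j]
    return out
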
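"""Low-level nucleotide encoding helpers.

Bases are encoded as uint8 codes A=0, C=1, G=2, T=3 throughout the package;
strings appear only at file-format boundaries.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_OF[ord(_b)] = _i
    _CODE_OF[ord(_b.lower())] = _i

_CHAR_OF = np.frombuffer(BASES.encode(), dtype=np.uint8)

# complement: A<->T, C<->G
COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string to uint8 codes; rejects other characters."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE_OF[raw]
    if codes.max(initial=0) > 3:
        bad = chr(int(raw[codes > 3][0]))
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return _CHAR_OF[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT[codes[::-1]]


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    if a.shape != b.shape:
        raise ValueError("length mismatch in hamming()")
    return int(np.count_nonzero(a != b))


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-mer (base-4 rolling encoding), length n-k+1."""
    n = codes.size
    if n < k:
        return np.zeros(0, dtype=np.int64)
    out = np.zeros(n - k + 1, dtype=np.int64)
    for i in range(k):
        out += codes[i : n - k + 1 + i].astype(np.int64) << (2 * (k - 1 - i))
    return out


def run_length_runs(codes: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Half-open [start, end) intervals of same-base runs with length >= min_len."""
    n = codes.size
    if n == 0:
        return []
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    keep = (ends - starts) >= min_len
    return list(zip(starts[keep].tolist(), ends[keep].tolist()))
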
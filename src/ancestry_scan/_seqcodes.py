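"""Low-level 2-bit sequence encoding and k-mer code arrays.

All heavy per-base work in the package funnels through these helpers so the
rest of the code can stay in numpy. Bases are encoded A=0, C=1, G=2, T=3;
anything else (N) gets code 4 and poisons every k-mer covering it.
"""
from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (N and unknowns -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Exact uint64 code of every k-mer (2 bits/base, first base most
    significant). Positions whose k-mer covers an N get code 2**63 (an
    impossible value for k <= 31) so they never match a real k-mer.

    Returns an array of length ``len(codes) - k + 1`` (empty if shorter).
    """
    if k > 31:
        raise ValueError("k must be <= 31 for exact 2-bit codes")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    valid = codes < 4
    base = np.where(valid, codes, 0).astype(np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | base[j : j + n]
    # poison any window containing an N
    bad = ~valid
    if bad.any():
        # prefix sums of bad flags -> windows with >=1 bad base
        cs = np.concatenate(([0], np.cumsum(bad)))
        poisoned = (cs[k:] - cs[:-k]) > 0
        out[poisoned] = np.uint64(1) << np.uint64(63)
    return out


def canonical_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Per-position canonical k-mer code: min(forward, reverse-complement)."""
    fwd = kmer_codes(codes, k)
    rc = kmer_codes(revcomp_codes(codes), k)[::-1]
    out = np.minimum(fwd, rc)
    poison = np.uint64(1) << np.uint64(63)
    out[(fwd == poison) | (rc == poison)] = poison
    return out


POISON = np.uint64(1) << np.uint64(63)
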
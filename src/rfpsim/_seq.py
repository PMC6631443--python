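"""Low-level sequence encodings shared across the package.

Sequences are held as ``numpy.uint8`` arrays with the 2-bit alphabet
A=0, C=1, G=2, T=3 and N=4.  All coordinates are 0-based half-open
internally; 1-based coordinates appear only in emitted SAM/VCF/TSV.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

# complement: A<->T, C<->G, N->N
_COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into a uint8 code array (upper/lowercase accepted)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][::-1]


def revcomp_rows(mat: np.ndarray) -> np.ndarray:
    """Reverse-complement every row of a (n_reads, read_len) code matrix."""
    return _COMPLEMENT[mat][:, ::-1]


def random_sequence(length: int, gc_content: float, rng: np.random.Generator) -> np.ndarray:
    """Random sequence with the requested GC fraction (positions i.i.d.)."""
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    return rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at]).astype(np.uint8)


def kmer_values(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-mer of a code array into an int64 (base-4); k-mers
    containing N are returned as -1.  Requires k <= 31."""
    if k > 31:
        raise ValueError("k must be <= 31 to fit an int64")
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    vals = codes.astype(np.int64)
    bad = vals >= 4
    vals = np.where(bad, 0, vals)
    # rolling pack via cumulative polynomial evaluation
    out = np.zeros(n, dtype=np.int64)
    for i in range(k):
        out = out * 4 + vals[i : i + n] if i else vals[:n].copy()
    # mark windows containing N
    if bad.any():
        bad_win = np.convolve(bad.astype(np.int64), np.ones(k, dtype=np.int64), "valid") > 0
        out[bad_win] = -1
    return out


def kmer_values_at(mat: np.ndarray, offset: int, k: int) -> np.ndarray:
    """Packed k-mer starting at a fixed column offset for every row of a
    (n, read_len) code matrix; rows whose window contains N get -1."""
    window = mat[:, offset : offset + k].astype(np.int64)
    bad = (window >= 4).any(axis=1)
    window = np.where(window >= 4, 0, window)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    out = window @ powers
    out[bad] = -1
    return out


_MASK64 = (1 << 64) - 1


def splitmix64(x: int) -> int:
    """One step of the splitmix64 mixing function (counter-based RNG core)."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def tie_break_index(master_seed: int, round_index: int, read_id: int, n: int) -> int:
    """Deterministic uniform draw in [0, n) keyed on (seed, round, read).

    Counter-based, so rounds and reads are independent of execution order.
    """
    h = splitmix64(splitmix64(splitmix64(master_seed) ^ round_index) ^ read_id)
    return int(h % n)


def derive_seed(master_seed: int, *parts: int) -> int:
    """Derive a child seed (< 2**31) from a master seed and integer labels."""
    h = splitmix64(master_seed)
    for p in parts:
        h = splitmix64(h ^ (p & _MASK64))
    return int(h % (2**31 - 1))
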
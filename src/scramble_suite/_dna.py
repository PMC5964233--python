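"""Low-level DNA sequence utilities shared across the package.

Sequences are handled as ``numpy.uint8`` arrays of ASCII codes (upper-case
``ACGTN``); this keeps read simulation, alignment and rendering vectorised.
"""

from __future__ import annotations

import numpy as np

#: Default 34-bp symmetric (palindromic) Cre recombination site.  Both 13-bp
#: arms are mutual reverse complements and the 8-bp spacer is itself a
#: palindrome, so the whole motif equals its own reverse complement.  This is
#: a configurable default, not hard-coded ground truth: every operation that
#: needs the motif takes it as a parameter.
LOXPSYM = b"ATAACTTCGTATAATGTACATTATACGAAGTTAT"

#: Default 34-bp asymmetric Cre site (the reporter-cassette flavour).  Its
#: spacer is directional, which is what makes it orthogonal to the symmetric
#: site above.
LOXP = b"ATAACTTCGTATAATGTATGCTATACGAAGTTAT"

_COMP = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMP[_a] = _b

# 2-bit base codes; anything outside ACGT (case-insensitive) maps to 255.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _a in enumerate(b"ACGT"):
    _CODE[_a] = _i
for _i, _a in enumerate(b"acgt"):
    _CODE[_a] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def as_array(seq) -> np.ndarray:
    """Coerce ``str``/``bytes``/array DNA into an upper-case uint8 array."""
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8, copy=False)
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    arr = np.frombuffer(bytes(seq), dtype=np.uint8).copy()
    # normalise case
    lower = (arr >= 97) & (arr <= 122)
    arr[lower] -= 32
    return arr


def to_bytes(arr: np.ndarray) -> bytes:
    return as_array(arr).tobytes()


def to_str(arr: np.ndarray) -> str:
    return to_bytes(arr).decode("ascii")


def complement(arr: np.ndarray) -> np.ndarray:
    return _COMP[as_array(arr)]


def revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMP[as_array(arr)][::-1]


def revcomp_bytes(seq: bytes) -> bytes:
    return revcomp(as_array(seq)).tobytes()


def is_palindrome(seq) -> bool:
    arr = as_array(seq)
    return len(arr) % 2 == 0 and bool(np.array_equal(revcomp(arr), arr))


def random_dna(n: int, rng: np.random.Generator) -> np.ndarray:
    return _DECODE[rng.integers(0, 4, size=n)]


def base_codes(arr: np.ndarray) -> np.ndarray:
    """Map ASCII bases to 2-bit codes (255 for non-ACGT)."""
    return _CODE[as_array(arr)]


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Polynomial 2-bit codes for every k-mer; -1 where a window holds non-ACGT.

    Exact (no hashing collisions) for k <= 31.
    """
    codes = base_codes(arr).astype(np.int64)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    bad = codes == 255
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    weights = 4 ** np.arange(k, dtype=np.int64)
    out = win @ weights
    if bad.any():
        badwin = np.lib.stride_tricks.sliding_window_view(bad, k).any(axis=1)
        out[badwin] = -1
    return out


def kmer_code(arr: np.ndarray, k: int | None = None) -> int:
    """Code of a single k-mer (whole array); -1 if it holds non-ACGT bases."""
    codes = base_codes(arr).astype(np.int64)
    if k is not None:
        codes = codes[:k]
    if (codes == 255).any():
        return -1
    return int(codes @ (4 ** np.arange(len(codes), dtype=np.int64)))


def find_all(haystack: bytes, needle: bytes) -> list[int]:
    """All (possibly overlapping) start offsets of ``needle`` in ``haystack``."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits
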
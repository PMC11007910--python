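"""Low-level canonical k-mer machinery shared by sketching, binning and spectra.

K-mers are packed into 64-bit integers, two bits per base (A=0, C=1, G=2,
T=3), which limits k to 32.  The canonical form of a k-mer is the smaller of
its packed code and the packed code of its reverse complement, so a sequence
and its reverse complement always yield the same multiset of canonical codes.
Windows containing a non-ACGT character are skipped.
"""

from __future__ import annotations

import numpy as np

# base -> 2-bit code; everything else maps to 4 (invalid sentinel)
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _BASE_CODE[_b] = _c
    _BASE_CODE[ord(chr(_b).lower())] = _c

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "a": "t", "c": "g", "g": "c", "t": "a", "n": "n"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return "".join(_COMP.get(ch, "N") for ch in reversed(seq))


def encode_bases(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes 0..3, with 4 marking non-ACGT."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def canonical_codes(seq: str, k: int) -> np.ndarray:
    """Packed canonical k-mer codes for every valid window of *seq*.

    Returns a uint64 array with one entry per window whose k bases are all
    ACGT; windows touching an ambiguous base are dropped.  Empty array when
    the sequence is shorter than k.
    """
    if not 1 <= k <= 32:
        raise ValueError(f"k must be in 1..32, got {k}")
    codes = encode_bases(seq)
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    valid = codes < 4
    b = codes.astype(np.uint64)
    nw = n - k + 1
    fwd = np.zeros(nw, dtype=np.uint64)
    rev = np.zeros(nw, dtype=np.uint64)
    for j in range(k):
        w = b[j:j + nw]
        fwd |= w << np.uint64(2 * (k - 1 - j))
        rev |= (np.uint64(3) ^ w) << np.uint64(2 * j)
    ok = np.ones(nw, dtype=bool)
    bad = ~valid
    if bad.any():
        # window is valid iff no invalid base falls inside it
        cum = np.concatenate(([0], np.cumsum(bad)))
        ok = (cum[k:] - cum[:-k]) == 0
    return np.minimum(fwd[ok], rev[ok])


def code_to_kmer(code: int, k: int) -> str:
    """Unpack a 2-bit k-mer code back into its DNA string."""
    bases = "ACGT"
    out = []
    for j in range(k):
        out.append(bases[(int(code) >> (2 * (k - 1 - j))) & 3])
    return "".join(out)


_SPLITMIX_SEED = np.uint64(0x5851F42D4C957F2D)  # fixed hash seed constant


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Deterministic 64-bit finalizer used for MinHash sketching."""
    z = x.astype(np.uint64) + (np.uint64(0x9E3779B97F4B7C15) ^ _SPLITMIX_SEED)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))
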
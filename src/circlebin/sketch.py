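"""MinHash sketching and Mash distance.

Used to compare multi-megabase circular paths cheaply: keep the *s* smallest
64-bit hash values over a path's canonical k-mers and estimate the Jaccard
index of two k-mer sets from the merged bottom sketch.  The Mash distance
``-(1/k) * ln(2j / (1+j))`` approximates 1 - ANI for close genomes; a
distance of 0.05 roughly corresponds to the 95% ANI species boundary.

Hashing is splitmix64 with a fixed seed constant: sketches are deterministic
within this package but intentionally not byte-compatible with other tools.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Union

import numpy as np

from ._kmer import canonical_codes, splitmix64


class SketchError(ValueError):
    pass


@dataclass(frozen=True)
class SketchParams:
    k: int = 21
    s: int = 1000

    def __post_init__(self):
        if not 1 <= self.k <= 32:
            raise ValueError("k must be in 1..32")
        if self.s < 1:
            raise ValueError("sketch size must be >= 1")


@dataclass
class MinHashSketch:
    params: SketchParams
    hashes: np.ndarray  # sorted, strictly increasing uint64
    n_kmers: int  # distinct canonical k-mers hashed

    def __post_init__(self):
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)


def sketch(seqs: Union[str, Sequence[str]], params: SketchParams = SketchParams()) -> MinHashSketch:
    """Bottom-s MinHash sketch of one or more pooled DNA sequences.

    Multiple sequences (e.g. the contigs of one circular path) contribute to
    a single sketch.  K-mers containing non-ACGT characters are skipped.
    """
    if isinstance(seqs, str):
        seqs = [seqs]
    chunks = [canonical_codes(s, params.k) for s in seqs]
    codes = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
    if codes.size == 0:
        raise SketchError(f"no valid {params.k}-mers (total sequence shorter than k?)")
    distinct = np.unique(codes)
    hashes = np.unique(splitmix64(distinct))
    return MinHashSketch(params, hashes[: params.s], int(distinct.size))


def mash_distance(a: MinHashSketch, b: MinHashSketch) -> float:
    """Mash distance from the bottom-s Jaccard estimate; clamped to [0, 1]."""
    if a.params != b.params:
        raise SketchError(f"sketch parameter mismatch: {a.params} vs {b.params}")
    s = a.params.s
    union = np.union1d(a.hashes, b.hashes)[:s]
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    n_shared = int(np.isin(union, shared, assume_unique=True).sum())
    denom = union.size
    j = n_shared / denom if denom else 0.0
    return jaccard_to_mash(j, a.params.k)


def jaccard_to_mash(j: float, k: int) -> float:
    """Convert a Jaccard index to Mash distance, clamped to [0, 1]."""
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    d = -math.log(2.0 * j / (1.0 + j)) / k
    return min(max(d, 0.0), 1.0)


def exact_jaccard_distance(x: Union[str, Sequence[str]], y: Union[str, Sequence[str]],
                           k: int = 21) -> float:
    """Mash distance from the exact Jaccard index over all canonical k-mers.

    Brute-force companion to :func:`mash_distance` for sequences small enough
    to enumerate; also the convergence limit of the sketch estimate as the
    sketch size grows past the number of distinct k-mers.
    """
    if isinstance(x, str):
        x = [x]
    if isinstance(y, str):
        y = [y]
    xs = np.unique(np.concatenate([canonical_codes(s, k) for s in x]))
    ys = np.unique(np.concatenate([canonical_codes(s, k) for s in y]))
    inter = np.intersect1d(xs, ys, assume_unique=True).size
    union = xs.size + ys.size - inter
    j = inter / union if union else 0.0
    return jaccard_to_mash(j, k)


def dump_sketch(sk: MinHashSketch, path) -> None:
    with open(path, "w") as fh:
        json.dump({"k": sk.params.k, "s": sk.params.s,
                   "n_kmers": sk.n_kmers,
                   "hashes": [int(h) for h in sk.hashes]}, fh)


def load_sketch(path) -> MinHashSketch:
    with open(path) as fh:
        d = json.load(fh)
    return MinHashSketch(SketchParams(d["k"], d["s"]),
                         np.array(d["hashes"], dtype=np.uint64), d["n_kmers"])
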
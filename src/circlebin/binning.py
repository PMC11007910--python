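"""Composition/coverage binning of contigs left out of circle rescue.

Each candidate contig is summarised by 512 canonical 5-mer frequencies plus
log10 read coverage (513 features), column-standardised, embedded to 2-D
with Barnes-Hut t-SNE, and grouped by a radius heuristic seeded from the
longest contigs.  Final bins are the union of rescued circles, big circular
contigs, and the clusters found here.

t-SNE coordinates carry an arbitrary scale, so the embedding is rescaled to
unit root-mean-square distance from its centroid before the fixed clustering
radius ``r1`` is applied; without this normalisation a radius in absolute
units would be meaningless.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
from sklearn.manifold import TSNE

from ._kmer import canonical_codes
from .graph import AssemblyGraph
from .rescue import CircularPath


@dataclass(frozen=True)
class BinningParams:
    min_candidate_len: int = 100_000
    big_circular_len: int = 1_000_000
    singleton_min_len: int = 500_000
    r1: float = 0.1
    fallback_shrink: float = 0.8
    fallback_reach: float = 1.6
    perplexity: float = 30.0
    kmer_size: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.r1 <= 0:
            raise ValueError("r1 must be positive")
        if not 0 < self.fallback_shrink < 1 < self.fallback_reach:
            raise ValueError("need 0 < fallback_shrink < 1 < fallback_reach")


@dataclass
class Bin:
    id: str
    members: Set[str]
    kind: str  # circular_contig | rescued_circle | multi_contig | single_contig

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"bin {self.id}: empty member set")
        if self.kind in ("circular_contig", "single_contig") and len(self.members) != 1:
            raise ValueError(f"bin {self.id}: kind {self.kind} must have 1 member")


def _canonical_index(k: int) -> np.ndarray:
    """Sorted packed codes of all canonical k-mers (512 entries for k=5)."""
    from ._kmer import canonical_codes as _cc  # noqa: F401 (doc aid)
    codes = np.arange(4 ** k, dtype=np.uint64)
    rc = np.zeros_like(codes)
    for j in range(k):
        rc |= (np.uint64(3) ^ ((codes >> np.uint64(2 * (k - 1 - j))) & np.uint64(3))) << np.uint64(2 * j)
    return np.unique(np.minimum(codes, rc))


_INDEX_CACHE: Dict[int, np.ndarray] = {}


def canonical_kmer_count(k: int = 5) -> int:
    """Number of canonical k-mers (512 for k=5)."""
    return canonical_index(k).size


def canonical_index(k: int = 5) -> np.ndarray:
    if k not in _INDEX_CACHE:
        _INDEX_CACHE[k] = _canonical_index(k)
    return _INDEX_CACHE[k]


def canonical_kmer_profile(seq: str, k: int = 5) -> np.ndarray:
    """Frequencies over all canonical k-mers (sorted code order), summing to 1.

    Windows containing non-ACGT bases are skipped; identical for a sequence
    and its reverse complement.
    """
    codes = canonical_codes(seq, k)
    if codes.size == 0:
        raise ValueError(f"sequence shorter than k={k} (or no valid window)")
    index = canonical_index(k)
    pos = np.searchsorted(index, codes)
    counts = np.bincount(pos, minlength=index.size).astype(float)
    return counts / counts.sum()


def select_candidates(graph: AssemblyGraph, circles: Sequence[CircularPath],
                      params: BinningParams = BinningParams()) -> List[str]:
    """Contigs eligible for composition binning.

    Keep a contig iff it is (1) at least ``min_candidate_len`` long, (2) not a
    member of any rescued circle, and (3) not both circular and longer than
    ``big_circular_len`` (those become single-contig bins directly).
    """
    used = set().union(*(c.members for c in circles)) if circles else set()
    out = []
    for seg in graph.segments.values():
        if seg.length < params.min_candidate_len:
            continue
        if seg.id in used:
            continue
        if seg.is_circular and seg.length > params.big_circular_len:
            continue
        out.append(seg.id)
    return sorted(out)


def build_feature_matrix(candidates: Sequence[str], sequences: Dict[str, str],
                         coverages: Dict[str, float],
                         k: int = 5) -> np.ndarray:
    """Candidates x (canonical k-mer frequencies + log10 coverage), z-scored.

    Zero-variance columns standardise to all-zeros rather than dividing by
    zero.  Coverage must be strictly positive (log10 is taken).
    """
    rows = []
    for cid in candidates:
        if cid not in sequences:
            raise KeyError(f"no sequence for candidate {cid!r}")
        cov = coverages.get(cid)
        if cov is None:
            raise KeyError(f"no coverage for candidate {cid!r}")
        if cov <= 0:
            raise ValueError(f"coverage must be > 0 for {cid!r} (log10)")
        rows.append(np.concatenate([canonical_kmer_profile(sequences[cid], k),
                                    [np.log10(cov)]]))
    mat = np.asarray(rows, dtype=float)
    mean = mat.mean(axis=0)
    std = mat.std(axis=0)
    std[std == 0] = 1.0  # zero-variance guard: column becomes all zeros
    return (mat - mean) / std


def embed(matrix: np.ndarray, params: BinningParams = BinningParams()) -> np.ndarray:
    """Barnes-Hut t-SNE to 2-D, rescaled to unit RMS distance from centroid.

    Deterministic for a fixed ``params.seed``.  Perplexity is clamped below
    the sample count as the optimisation requires.
    """
    n = matrix.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows to embed")
    perp = min(params.perplexity, (n - 1) / 3.0)
    ts = TSNE(n_components=2, perplexity=perp, random_state=params.seed,
              init="pca", method="barnes_hut")
    coords = ts.fit_transform(matrix)
    coords = coords - coords.mean(axis=0)
    rms = np.sqrt((coords ** 2).sum(axis=1).mean())
    if rms > 0:
        coords = coords / rms
    return coords


def radius_cluster(coords: np.ndarray, ids: Sequence[str],
                   lengths: Dict[str, int],
                   params: BinningParams = BinningParams(),
                   n_angles: int = 360) -> List[Bin]:
    """Radius-seeded clustering on the embedded plane.

    Seeds are visited in decreasing contig length (ties by id).  For each
    unblocked seed:

    1. if any unblocked point lies within ``r1``, bin the seed with all
       unblocked points within ``r1``;
    2. otherwise, if there are unblocked points within ``fallback_reach*r1``
       and some circle of radius ``fallback_shrink*r1`` whose boundary passes
       through the seed covers them all, bin the seed with those points
       (feasibility tested over ``n_angles`` candidate centres);
    3. otherwise the seed becomes a single-contig bin iff it is longer than
       ``singleton_min_len``; shorter seeds stay unbinned.
    """
    ids = list(ids)
    pos = {cid: coords[i] for i, cid in enumerate(ids)}
    order = sorted(ids, key=lambda c: (-lengths[c], c))
    blocked: Set[str] = set()
    bins: List[Bin] = []
    r1 = params.r1
    for seed in order:
        if seed in blocked:
            continue
        p = pos[seed]
        free = [c for c in ids if c not in blocked and c != seed]
        d = {c: float(np.hypot(*(pos[c] - p))) for c in free}
        near = [c for c in free if d[c] <= r1]
        if near:
            members = {seed, *near}
        else:
            reach = [c for c in free if d[c] <= params.fallback_reach * r1]
            if reach and _fallback_circle_exists(p, [pos[c] for c in reach],
                                                 params.fallback_shrink * r1,
                                                 n_angles):
                members = {seed, *reach}
            elif lengths[seed] > params.singleton_min_len:
                members = {seed}
            else:
                continue  # unbinned; may still join a later seed's bin
        kind = "multi_contig" if len(members) > 1 else "single_contig"
        bins.append(Bin(f"bin{len(bins) + 1:04d}", members, kind))
        blocked |= members
    return bins


def _fallback_circle_exists(seed_xy: np.ndarray, pts: List[np.ndarray],
                            rho: float, n_angles: int) -> bool:
    """Is there a circle of radius *rho* through the seed covering all *pts*?

    Centres lie at distance rho from the seed; a discrete sweep of angles
    stands in for the continuous feasibility test.
    """
    pts = np.asarray(pts)
    angles = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    centres = seed_xy + rho * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    dist = np.sqrt(((pts[None, :, :] - centres[:, None, :]) ** 2).sum(axis=2))
    return bool((dist <= rho + 1e-12).all(axis=1).any())


def assemble_final_bins(big_circular_contigs: Sequence[str],
                        rescued_circles: Sequence[CircularPath],
                        clustered_bins: Sequence[Bin]) -> List[Bin]:
    """Merge the three disjoint bin sources into the final bin list."""
    bins: List[Bin] = []
    for i, cid in enumerate(big_circular_contigs, 1):
        bins.append(Bin(f"circ{i:04d}", {cid}, "circular_contig"))
    for i, circ in enumerate(rescued_circles, 1):
        bins.append(Bin(f"rescue{i:04d}", set(circ.members), "rescued_circle"))
    for b in clustered_bins:
        bins.append(Bin(b.id, set(b.members), b.kind))
    seen: Set[str] = set()
    for b in bins:
        dup = b.members & seen
        if dup:
            raise ValueError(f"contig(s) {sorted(dup)} appear in multiple bins")
        seen |= b.members
    return bins


def bin_contigs(graph: AssemblyGraph, circles: Sequence[CircularPath],
                params: BinningParams = BinningParams()) -> List[Bin]:
    """End-to-end binning: candidates -> features -> t-SNE -> radius bins,
    merged with big circular contigs and rescued circles."""
    big_circ = sorted(s.id for s in graph.segments.values()
                      if s.is_circular and s.length >= params.big_circular_len)
    in_circles = set().union(*(c.members for c in circles)) if circles else set()
    big_circ = [c for c in big_circ if c not in in_circles]
    candidates = select_candidates(graph, circles, params)
    lengths = {cid: graph.segments[cid].length for cid in candidates}
    if len(candidates) >= 3:
        seqs = {cid: graph.segments[cid].sequence for cid in candidates}
        covs = {cid: graph.segments[cid].coverage for cid in candidates}
        mat = build_feature_matrix(candidates, seqs, covs, params.kmer_size)
        coords = embed(mat, params)
        clustered = radius_cluster(coords, candidates, lengths, params)
    else:
        # too few points to embed: bin long contigs singly, drop the rest
        clustered = [Bin(f"bin{i + 1:04d}", {cid}, "single_contig")
                     for i, cid in enumerate(c for c in candidates
                                             if lengths[c] >= params.singleton_min_len)]
    return assemble_final_bins(big_circ, circles, clustered)
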
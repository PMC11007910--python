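"""Stacked k-mer spectrum: reference-free assembly completeness bands.

For input reads and an assembly of those reads, let M[c][x] count the
distinct canonical k-mers occurring x times in the reads and c times in the
assembly.  The right-accumulated counts

    N^(c)_x = sum_{y >= x} M[c][y]        N_x = sum_c N^(c)_x

turn the noisy per-multiplicity histogram into stacked fractions
N^(c)_x / N_x: the c=0 band is read content absent from the assembly (high
at x=1 from sequencing errors; a large 0-band at high x means abundant
genomes were not assembled), c=1 is content represented exactly once, and
c>=2 indicates duplicated assembly content.  A complete non-redundant
assembly of distinct genomes puts the 1x band at ~1 across the plot.

The same joint count table drives extraction of high-multiplicity intervals:
contig stretches whose k-mers are moderately repeated in the assembly but
extremely abundant in reads (mobile elements, rRNA/tRNA operons).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ._kmer import canonical_codes


@dataclass
class KmerCountTable:
    """Canonical k-mer -> occurrence count, stored as parallel sorted arrays."""

    k: int
    keys: np.ndarray  # sorted uint64 packed canonical k-mers
    counts: np.ndarray  # int64, >= 1

    def __len__(self) -> int:
        return int(self.keys.size)

    def get(self, code: int) -> int:
        i = np.searchsorted(self.keys, np.uint64(code))
        if i < self.keys.size and self.keys[i] == np.uint64(code):
            return int(self.counts[i])
        return 0

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        """Vectorised count lookup; absent k-mers give 0."""
        idx = np.searchsorted(self.keys, codes)
        idx = np.clip(idx, 0, max(self.keys.size - 1, 0))
        out = np.zeros(codes.size, dtype=np.int64)
        if self.keys.size:
            hit = self.keys[idx] == codes
            out[hit] = self.counts[idx[hit]]
        return out


def count_kmers(seqs: Iterable[str], k: int) -> KmerCountTable:
    """Canonical k-mer counting over a stream of sequences (k <= 32)."""
    chunks = [canonical_codes(s, k) for s in seqs]
    chunks = [c for c in chunks if c.size]
    if not chunks:
        return KmerCountTable(k, np.empty(0, dtype=np.uint64),
                              np.empty(0, dtype=np.int64))
    keys, counts = np.unique(np.concatenate(chunks), return_counts=True)
    return KmerCountTable(k, keys, counts.astype(np.int64))


def joint_spectrum(reads: KmerCountTable, asm: KmerCountTable,
                   c_max: int = 4) -> np.ndarray:
    """M[c][x]: distinct k-mers with read count x and assembly count c.

    Rows are assembly copy numbers 0..c_max (the last row aggregates all
    counts >= c_max); columns are read multiplicities 0..max(x), with the
    x=0 column always zero (only k-mers seen in reads are considered).
    """
    if reads.k != asm.k:
        raise ValueError(f"k mismatch: reads k={reads.k}, assembly k={asm.k}")
    if len(reads) == 0:
        return np.zeros((c_max + 1, 1), dtype=np.int64)
    x = reads.counts
    c = np.minimum(asm.lookup(reads.keys), c_max)
    x_max = int(x.max())
    M = np.zeros((c_max + 1, x_max + 1), dtype=np.int64)
    np.add.at(M, (c, x), 1)
    return M


@dataclass
class SpectrumBands:
    """Stacked band fractions N^(c)_x / N_x for x = 1..x_t."""

    x_axis: np.ndarray  # read multiplicities 1..x_t
    bands: np.ndarray  # (c_max+1, len(x_axis)) fractions, columns sum to 1
    n_x: np.ndarray  # N_x per x

    @property
    def c_max(self) -> int:
        return self.bands.shape[0] - 1


def cumulative_bands(M: np.ndarray,
                     truncation_threshold: float = 1e6) -> SpectrumBands:
    """Right-accumulate M and stack fractions, truncating at the smallest x
    where N_x drops below *truncation_threshold* (and where N_x hits 0)."""
    if M.shape[1] <= 1 or M.sum() == 0:
        return SpectrumBands(np.empty(0, dtype=int),
                             np.empty((M.shape[0], 0)), np.empty(0, dtype=np.int64))
    # N[c][x] = sum_{y>=x} M[c][y], for x >= 1
    N = np.flip(np.cumsum(np.flip(M[:, 1:], axis=1), axis=1), axis=1)
    n_x = N.sum(axis=0)
    x_axis = np.arange(1, M.shape[1])
    below = np.nonzero(n_x < truncation_threshold)[0]
    x_t = int(below[0]) + 1 if below.size else int(x_axis[-1])
    keep = (x_axis <= x_t) & (n_x > 0)
    N, n_x, x_axis = N[:, keep], n_x[keep], x_axis[keep]
    return SpectrumBands(x_axis, N / n_x, n_x)


def spectrum_from_sequences(reads: Iterable[str], contigs: Iterable[str],
                            k: int = 31, c_max: int = 4,
                            truncation_threshold: float = 1e6) -> SpectrumBands:
    """Convenience: count, joint spectrum, and bands in one call."""
    rt = count_kmers(reads, k)
    at = count_kmers(contigs, k)
    return cumulative_bands(joint_spectrum(rt, at, c_max), truncation_threshold)


@dataclass(frozen=True)
class MultiplicityInterval:
    contig: str
    start: int  # 0-based, half-open
    end: int
    sequence: str = ""


def high_multiplicity_intervals(reads: KmerCountTable, asm: KmerCountTable,
                                contigs: Dict[str, str],
                                a_min: int = 2, a_max: int = 15,
                                r_min: int = 800) -> List[MultiplicityInterval]:
    """Contig intervals covered by k-mers with assembly multiplicity in
    [a_min, a_max] and read multiplicity >= r_min.

    Each qualifying k-mer occurrence marks a k-base span; overlapping or
    book-ended spans are merged per contig and the merged sequences dumped.
    """
    if reads.k != asm.k:
        raise ValueError("k mismatch between read and assembly tables")
    k = reads.k
    out: List[MultiplicityInterval] = []
    for cid in sorted(contigs):
        seq = contigs[cid]
        codes = canonical_codes(seq, k)
        if codes.size == 0:
            continue
        # positions of valid windows (ambiguity gaps shift window indices)
        pos = _valid_window_positions(seq, k)
        a_counts = asm.lookup(codes)
        r_counts = reads.lookup(codes)
        hit = (a_counts >= a_min) & (a_counts <= a_max) & (r_counts >= r_min)
        for start, end in _merge_spans(pos[hit], k):
            out.append(MultiplicityInterval(cid, start, end, seq[start:end]))
    return out


def _valid_window_positions(seq: str, k: int) -> np.ndarray:
    from ._kmer import encode_bases
    codes = encode_bases(seq)
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    bad = (codes >= 4).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(bad)))
    ok = (cum[k:] - cum[:-k]) == 0
    return np.nonzero(ok)[0]


def _merge_spans(starts: np.ndarray, k: int) -> List[Tuple[int, int]]:
    if starts.size == 0:
        return []
    merged = []
    lo = hi = None
    for s in starts:
        s = int(s)
        if lo is None:
            lo, hi = s, s + k
        elif s <= hi:  # overlapping or adjacent spans
            hi = max(hi, s + k)
        else:
            merged.append((lo, hi))
            lo, hi = s, s + k
    merged.append((lo, hi))
    return merged


def plot_bands(bands: SpectrumBands, path=None, ax=None,
               band_labels: Optional[Sequence[str]] = None):
    """Stacked-area plot of the spectrum bands with the N_x guide line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if band_labels is None:
        band_labels = [f"{c}x" for c in range(bands.c_max)] + [f">={bands.c_max}x"]
    ax.stackplot(bands.x_axis, bands.bands, labels=band_labels)
    ax2 = ax.twinx()
    ax2.plot(bands.x_axis, bands.n_x, "w--", lw=1)
    ax2.set_yscale("log")
    ax2.set_ylabel("N_x")
    ax.set_xlabel("read multiplicity x")
    ax.set_ylabel("fraction of k-mers")
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
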
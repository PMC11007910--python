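"""MAG quality categories and external-binner bin post-processing.

Quality follows the CheckM completeness/contamination convention:

* near-complete: completeness >= 90% and contamination < 5%
* high-quality:  completeness >= 70% and contamination < 10% (not NC)
* medium-quality: completeness >= 50% and quality score >= 50 (not NC/HQ)
* failed: everything else

with quality score = completeness - 5 x contamination.

Post-processing of bins from composition binners pulls >= 1 Mb circular
contigs out into their own single-contig bins (strain-aware assemblers leave
complete circular chromosomes that such binners tend to lump with strain
siblings, inflating contamination).  Merging combines those bins with
rescued circles, discarding mid-sized bins that largely duplicate a circle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set

import pandas as pd

from .binning import Bin
from .rescue import CircularPath

QUALITY_CATEGORIES = ("near_complete", "high_quality", "medium_quality", "failed")


@dataclass(frozen=True)
class MagQuality:
    completeness: float  # percent, 0..100
    contamination: float  # percent, >= 0

    def __post_init__(self):
        if not 0 <= self.completeness <= 100:
            raise ValueError("completeness must be in [0, 100]")
        if self.contamination < 0:
            raise ValueError("contamination must be >= 0")


def quality_score(q: MagQuality) -> float:
    return q.completeness - 5.0 * q.contamination


def classify_quality(q: MagQuality) -> str:
    if q.completeness >= 90 and q.contamination < 5:
        return "near_complete"
    if q.completeness >= 70 and q.contamination < 10:
        return "high_quality"
    if q.completeness >= 50 and quality_score(q) >= 50:
        return "medium_quality"
    return "failed"


@dataclass
class ExternalBin:
    id: str
    members: Set[str]
    total_bp: int = 0

    @classmethod
    def from_lengths(cls, id: str, members: Iterable[str],
                     lengths: Dict[str, int]) -> "ExternalBin":
        members = set(members)
        return cls(id, members, sum(lengths[m] for m in members))


def postprocess_external_bins(bins: Sequence[ExternalBin],
                              lengths: Dict[str, int],
                              circular: Set[str],
                              big_len: int = 1_000_000) -> List[ExternalBin]:
    """Move every >= *big_len* circular contig sharing a bin with other
    contigs into its own singleton bin; all other memberships unchanged."""
    out: List[ExternalBin] = []
    n_new = 0
    for b in bins:
        for m in b.members:
            if m not in lengths:
                raise KeyError(f"no metadata for contig {m!r}")
        movers = {m for m in b.members
                  if m in circular and lengths[m] >= big_len}
        if not movers or len(b.members) == 1:
            out.append(b)  # nothing to move, or already a singleton
            continue
        rest = b.members - movers
        if rest:
            out.append(ExternalBin.from_lengths(b.id, rest, lengths))
        for m in sorted(movers):
            n_new += 1
            out.append(ExternalBin.from_lengths(f"{b.id}_circ{n_new}", {m}, lengths))
    return out


def merge_with_rescued(bins: Sequence[ExternalBin],
                       circles: Sequence[CircularPath],
                       lengths: Dict[str, int],
                       circular: Set[str] = frozenset(),
                       big_len: int = 1_000_000,
                       window: tuple = (500_000, 10_000_000),
                       max_shared_bp: int = 1_000_000,
                       max_shared_contigs: int = 10) -> List[Bin]:
    """Combine external bins with rescued circles, dropping redundant bins.

    A bin whose total size falls in *window* (0.5-10 Mb) is discarded iff it
    shares more than *max_shared_bp* of sequence or more than
    *max_shared_contigs* contigs with any single rescued circle.  Output is
    the surviving bins plus every circle plus every >= *big_len* circular
    contig as its own bin.
    """
    final: List[Bin] = []
    in_circles = set().union(*(c.members for c in circles)) if circles else set()
    big_circ = sorted(c for c in circular
                      if lengths.get(c, 0) >= big_len and c not in in_circles)
    binned_elsewhere: Set[str] = set(big_circ) | in_circles

    for i, cid in enumerate(big_circ, 1):
        final.append(Bin(f"circ{i:04d}", {cid}, "circular_contig"))
    for i, circ in enumerate(circles, 1):
        final.append(Bin(f"rescue{i:04d}", set(circ.members), "rescued_circle"))

    for b in bins:
        lo, hi = window
        if lo <= b.total_bp <= hi:
            redundant = False
            for circ in circles:
                shared = b.members & circ.members
                shared_bp = sum(lengths[m] for m in shared)
                if shared_bp > max_shared_bp or len(shared) > max_shared_contigs:
                    redundant = True
                    break
            if redundant:
                continue
        members = b.members - binned_elsewhere
        if not members:
            continue
        kind = "multi_contig" if len(members) > 1 else "single_contig"
        final.append(Bin(b.id, members, kind))
    return final


# ---------------------------------------------------------------- tabular I/O

def read_bin_table(path) -> List[ExternalBin]:
    """Read a contig->bin TSV (columns contig_id, bin_id; header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0].lower() in ("contig_id", "contig", "contigname"):
        df = df.iloc[1:]
    groups: Dict[str, Set[str]] = {}
    for contig, bin_id in zip(df.iloc[:, 0], df.iloc[:, 1]):
        groups.setdefault(bin_id, set()).add(contig)
    return [ExternalBin(bid, mem) for bid, mem in sorted(groups.items())]


def write_bin_table(bins: Sequence[Bin], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tbin_id\tbin_kind\n")
        for b in bins:
            for m in sorted(b.members):
                fh.write(f"{m}\t{b.id}\t{b.kind}\n")


def read_quality_table(path) -> Dict[str, MagQuality]:
    """Read a CheckM-style quality TSV.

    Accepts either a minimal 3-column layout (bin_id, completeness,
    contamination) or the wider tabular report, matching columns by name
    case-insensitively.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.strip().lower(): c for c in df.columns}
    id_col = next((cols[c] for c in ("bin id", "bin_id", "mag", "bin") if c in cols), None)
    comp_col = next((cols[c] for c in ("completeness", "comp") if c in cols), None)
    cont_col = next((cols[c] for c in ("contamination", "cont") if c in cols), None)
    if not all((id_col, comp_col, cont_col)):
        raise ValueError(f"quality table missing required columns; found {list(df.columns)}")
    return {str(r[id_col]): MagQuality(float(r[comp_col]), float(r[cont_col]))
            for _, r in df.iterrows()}


def classify_table(qualities: Dict[str, MagQuality]) -> pd.DataFrame:
    rows = [(mag, q.completeness, q.contamination, quality_score(q),
             classify_quality(q)) for mag, q in qualities.items()]
    return pd.DataFrame(rows, columns=["mag", "completeness", "contamination",
                                       "quality_score", "category"])
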
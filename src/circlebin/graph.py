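"""Bidirected assembly-graph model with GFA 1.0 I/O and depth-table parsing.

The graph follows GFA conventions: segments are contigs/unitigs, links are
oriented overlaps.  Every link implies its bidirected mirror, so adjacency
queries on ``(y, flipped)`` see ``(x, flipped)`` whenever ``x+ -> y+`` is
recorded.  A segment is flagged circular when it carries a self-link with
equal orientations on both ends, or when external metadata says so.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd


class GFAParseError(ValueError):
    """Malformed GFA content; message names the offending line number."""


class GraphReferenceError(KeyError):
    """A link or query names a segment that does not exist."""


@dataclass(frozen=True, order=True)
class OrientedSegment:
    """A segment id plus a strand: '+' as stored, '-' reverse complement."""

    id: str
    orient: str

    def __post_init__(self):
        if self.orient not in ("+", "-"):
            raise ValueError(f"orient must be '+' or '-', got {self.orient!r}")

    def reverse(self) -> "OrientedSegment":
        return OrientedSegment(self.id, "-" if self.orient == "+" else "+")

    def __str__(self) -> str:
        return f"{self.id}{self.orient}"


@dataclass
class Segment:
    id: str
    length: int
    sequence: Optional[str] = None
    coverage: Optional[float] = None
    is_circular: bool = False

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"segment {self.id}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"segment {self.id}: length {self.length} != sequence "
                f"length {len(self.sequence)}")


@dataclass(frozen=True)
class Link:
    from_: OrientedSegment
    to: OrientedSegment
    overlap: int = 0

    def mirror(self) -> "Link":
        return Link(self.to.reverse(), self.from_.reverse(), self.overlap)


# CIGAR ops that consume the reference (overlap length on the target side)
_CIGAR_REF_OPS = set("MDN=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_overlap(cigar: str) -> int:
    """Total reference-consuming length of a GFA overlap CIGAR; '*' -> 0."""
    if cigar in ("*", ""):
        return 0
    total = 0
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise GFAParseError(f"bad CIGAR {cigar!r}")
        if m.group(2) in _CIGAR_REF_OPS:
            total += int(m.group(1))
        pos = m.end()
    if pos != len(cigar):
        raise GFAParseError(f"bad CIGAR {cigar!r}")
    return total


@dataclass
class AssemblyGraph:
    """Segments plus bidirected links, with mirror-closed adjacency."""

    segments: Dict[str, Segment] = field(default_factory=dict)
    links: List[Link] = field(default_factory=list)

    def __post_init__(self):
        self._adj: Dict[OrientedSegment, set] = {}
        self._overlap: Dict[Tuple[OrientedSegment, OrientedSegment], int] = {}
        for ln in self.links:
            self._index_link(ln)

    def _index_link(self, ln: Link) -> None:
        for e in (ln, ln.mirror()):
            self._adj.setdefault(e.from_, set()).add(e.to)
            self._overlap[(e.from_, e.to)] = e.overlap

    def add_segment(self, seg: Segment) -> None:
        if seg.id in self.segments:
            raise ValueError(f"duplicate segment id {seg.id!r}")
        self.segments[seg.id] = seg

    def add_link(self, ln: Link) -> None:
        for v in (ln.from_, ln.to):
            if v.id not in self.segments:
                raise GraphReferenceError(f"link references unknown segment {v.id!r}")
        self.links.append(ln)
        self._index_link(ln)
        # same-orientation self-link marks a self-closing (circular) contig
        if ln.from_ == ln.to:
            self.segments[ln.from_.id].is_circular = True

    def neighbors(self, v: OrientedSegment) -> List[OrientedSegment]:
        """Successors of *v* under bidirected semantics, sorted (id, orient)."""
        if v.id not in self.segments:
            raise GraphReferenceError(f"unknown segment {v.id!r}")
        return sorted(self._adj.get(v, ()), key=lambda o: (o.id, o.orient))

    def link_overlap(self, a: OrientedSegment, b: OrientedSegment) -> int:
        """Overlap (bp) of the link a->b; raises if the link is absent."""
        try:
            return self._overlap[(a, b)]
        except KeyError:
            raise GraphReferenceError(f"no link {a} -> {b}") from None

    def oriented_sequence(self, v: OrientedSegment) -> str:
        seg = self.segments[v.id]
        if seg.sequence is None:
            raise GraphReferenceError(f"segment {v.id!r} has no sequence")
        if v.orient == "+":
            return seg.sequence
        from ._kmer import revcomp
        return revcomp(seg.sequence)


def read_gfa(path) -> AssemblyGraph:
    """Parse a GFA 1.0 file (S and L lines; sequences may be '*')."""
    g = AssemblyGraph()
    pending_links: List[Tuple[int, Link]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line[0] in "#H":
                continue
            fields = line.split("\t")
            try:
                if fields[0] == "S":
                    _parse_s_line(g, fields)
                elif fields[0] == "L":
                    pending_links.append((lineno, _parse_l_line(fields)))
                # other record types ignored
            except (IndexError, ValueError) as exc:
                if isinstance(exc, GFAParseError):
                    raise GFAParseError(f"line {lineno}: {exc}") from None
                raise GFAParseError(f"line {lineno}: malformed record") from None
    for lineno, ln in pending_links:
        try:
            g.add_link(ln)
        except GraphReferenceError as exc:
            raise GraphReferenceError(f"line {lineno}: {exc.args[0]}") from None
    return g


def _parse_s_line(g: AssemblyGraph, fields: List[str]) -> None:
    name, seq = fields[1], fields[2]
    tags = _parse_tags(fields[3:])
    if seq == "*":
        if "LN" not in tags:
            raise GFAParseError(f"segment {name!r}: no sequence and no LN tag")
        length, sequence = int(tags["LN"]), None
    else:
        length, sequence = len(seq), seq
    coverage = float(tags["dp"]) if "dp" in tags else None
    circular = tags.get("cl") == "1"
    g.add_segment(Segment(name, length, sequence, coverage, circular))


def _parse_l_line(fields: List[str]) -> Link:
    frm = OrientedSegment(fields[1], fields[2])
    to = OrientedSegment(fields[3], fields[4])
    cigar = fields[5] if len(fields) > 5 else "*"
    return Link(frm, to, cigar_overlap(cigar))


def _parse_tags(raw: Iterable[str]) -> Dict[str, str]:
    tags = {}
    for item in raw:
        parts = item.split(":", 2)
        if len(parts) == 3:
            tags[parts[0]] = parts[2]
    return tags


def write_gfa(graph: AssemblyGraph, path) -> None:
    """Serialize back to GFA 1.0; circular flags kept as a cl:i tag."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for seg in graph.segments.values():
            seq = seg.sequence if seg.sequence is not None else "*"
            tags = [f"LN:i:{seg.length}"]
            if seg.coverage is not None:
                tags.append(f"dp:f:{seg.coverage}")
            if seg.is_circular:
                tags.append("cl:i:1")
            fh.write(f"S\t{seg.id}\t{seq}\t" + "\t".join(tags) + "\n")
        for ln in graph.links:
            fh.write(f"L\t{ln.from_.id}\t{ln.from_.orient}\t{ln.to.id}\t"
                     f"{ln.to.orient}\t{ln.overlap}M\n")


_DEPTH_ID_COLS = ("contigName", "contig_id", "contig", "id")
_DEPTH_VAL_COLS = ("totalAvgDepth", "depth", "coverage", "meanDepth")


def read_depth_table(path) -> Dict[str, float]:
    """Read a per-contig mean-depth TSV (MetaBAT2 depth dialect accepted).

    Extra columns (contigLen, per-sample variance, ...) are ignored.
    """
    df = pd.read_csv(path, sep="\t")
    id_col = next((c for c in _DEPTH_ID_COLS if c in df.columns), None)
    val_col = next((c for c in _DEPTH_VAL_COLS if c in df.columns), None)
    if id_col is None or val_col is None:
        raise ValueError(
            f"depth table needs id column {_DEPTH_ID_COLS} and depth column "
            f"{_DEPTH_VAL_COLS}; found {list(df.columns)}")
    depths = df[val_col].astype(float)
    if (depths < 0).any():
        bad = df[id_col][depths < 0].iloc[0]
        raise ValueError(f"negative depth for contig {bad!r}")
    return dict(zip(df[id_col].astype(str), depths))


def attach_depths(graph: AssemblyGraph, depths: Dict[str, float]) -> None:
    """Set Segment.coverage from a depth map for ids present in the graph."""
    for cid, depth in depths.items():
        if cid in graph.segments:
            graph.segments[cid].coverage = depth
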
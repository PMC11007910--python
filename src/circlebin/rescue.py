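"""Circle rescue: enumerate long circular paths in an assembly graph.

Strain diversity and shared homology leave many bacterial chromosomes as
circular tangles in long-read metagenome assembly graphs rather than single
circular contigs.  This module walks the bidirected graph with a capped
depth-first search to recover such chromosomes as closed oriented walks
("rescued circles"), then removes near-duplicate circles by Mash distance.

The search is deliberately greedy and frugal:

* DFS roots are the unvisited contigs in decreasing length order, and each
  root contributes at most one accepted circle.
* A walk must return to its starting oriented segment (same id and same
  orientation) so the spelled sequence is a consistent circle; each segment
  id is used at most once per walk.
* At a fork, successors are tried in ascending order of how often they have
  been used in previously accepted circles (ties by id, then orient), and a
  candidate circle is rejected when the summed prior usage of its members
  reaches ``usage_cap`` — both rules throttle enumeration of near-identical
  paths through the same tangle.
* Accepted circles must span at least ``min_contigs`` contigs and
  ``min_path_len`` bases; single circular contigs are reported elsewhere.

Deduplication keeps the longer of two circles when they are within
``dedup_len_window`` in length and at most ``dedup_max_dist`` apart in Mash
distance; circles differing by more than the window are assumed to be
different replicons and both kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set

from .graph import AssemblyGraph, GraphReferenceError, OrientedSegment
from .sketch import MinHashSketch, SketchParams, mash_distance, sketch


@dataclass(frozen=True)
class RescueParams:
    min_path_len: int = 500_000
    min_contigs: int = 2
    usage_cap: int = 100
    dedup_max_dist: float = 0.05
    dedup_len_window: int = 1_000_000
    sketch_params: SketchParams = SketchParams()

    def __post_init__(self):
        if min(self.min_path_len, self.min_contigs, self.usage_cap,
               self.dedup_len_window) <= 0:
            raise ValueError("rescue parameters must be positive")
        if not 0.0 <= self.dedup_max_dist <= 1.0:
            raise ValueError("dedup_max_dist must be in [0, 1]")


@dataclass
class CircularPath:
    """A closed oriented walk; ``walk[-1]`` links back to ``walk[0]``."""

    walk: List[OrientedSegment]
    length: int
    members: Set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.members:
            self.members = {v.id for v in self.walk}

    @property
    def n_contigs(self) -> int:
        return len(self.members)


def path_length(walk: Sequence[OrientedSegment], graph: AssemblyGraph) -> int:
    """Closed-walk length: member lengths minus link overlaps on the walk."""
    total = sum(graph.segments[v.id].length for v in walk)
    for a, b in zip(walk, list(walk[1:]) + [walk[0]]):
        total -= graph.link_overlap(a, b)
    return max(total, 0)


def verify_closed_walk(path: CircularPath, graph: AssemblyGraph) -> bool:
    """True iff every consecutive pair (and last->first) is a graph link and
    no segment id repeats within the walk."""
    walk = path.walk
    ids = [v.id for v in walk]
    if len(set(ids)) != len(ids):
        return False
    for a, b in zip(walk, walk[1:] + [walk[0]]):
        try:
            graph.link_overlap(a, b)
        except GraphReferenceError:
            return False
    return True


def find_circular_paths(graph: AssemblyGraph,
                        params: RescueParams = RescueParams()) -> List[CircularPath]:
    """Capped DFS enumeration of long circular paths (see module docs)."""
    usage: Dict[str, int] = {}
    visited: Set[str] = set()
    paths: List[CircularPath] = []

    roots = sorted(graph.segments.values(), key=lambda s: (-s.length, s.id))
    for root in roots:
        if root.id in visited:
            continue
        found = _dfs_one_circle(graph, OrientedSegment(root.id, "+"),
                                params, usage)
        if found is None:
            continue
        paths.append(found)
        for cid in found.members:
            usage[cid] = usage.get(cid, 0) + 1
            visited.add(cid)
    return paths


def _dfs_one_circle(graph: AssemblyGraph, start: OrientedSegment,
                    params: RescueParams,
                    usage: Dict[str, int]) -> Optional[CircularPath]:
    """Iterative DFS from *start*; returns the first acceptable circle."""

    def successors(v: OrientedSegment) -> List[OrientedSegment]:
        nbrs = graph.neighbors(v)
        # less-used contigs first; deterministic tie-break by (id, orient)
        return sorted(nbrs, key=lambda o: (usage.get(o.id, 0), o.id, o.orient))

    walk = [start]
    on_path = {start.id}
    stack = [iter(successors(start))]
    while stack:
        try:
            nxt = next(stack[-1])
        except StopIteration:
            stack.pop()
            on_path.discard(walk.pop().id)
            continue
        if nxt == start and len(walk) >= params.min_contigs:
            cand = CircularPath(list(walk), path_length(walk, graph))
            if (cand.length >= params.min_path_len
                    and cand.n_contigs >= params.min_contigs
                    and sum(usage.get(c, 0) for c in cand.members) < params.usage_cap):
                return cand
            continue
        if nxt.id in on_path:
            continue
        walk.append(nxt)
        on_path.add(nxt.id)
        stack.append(iter(successors(nxt)))
    return None


def path_sequence(path: CircularPath, graph: AssemblyGraph) -> str:
    """Spelled circular sequence: oriented member sequences concatenated with
    each link's overlap trimmed from the successor (incl. the closing link)."""
    parts = []
    walk = path.walk
    for i, v in enumerate(walk):
        seq = graph.oriented_sequence(v)
        prev = walk[i - 1] if i > 0 else walk[-1]
        trim = graph.link_overlap(prev, v) if len(walk) > 1 else 0
        parts.append(seq[trim:] if i > 0 else seq)
    if len(walk) > 1:
        closing = graph.link_overlap(walk[-1], walk[0])
        if closing:
            whole = "".join(parts)
            return whole[:-closing] if closing < len(whole) else whole
    return "".join(parts)


def deduplicate_circles(paths: List[CircularPath], graph: AssemblyGraph,
                        params: RescueParams = RescueParams(),
                        sketches: Optional[List[MinHashSketch]] = None) -> List[CircularPath]:
    """Greedy dedup in decreasing length order.

    A circle is dropped iff some already-kept circle is within
    ``dedup_len_window`` of its length and at Mash distance at most
    ``dedup_max_dist``.  Only rescued circles are compared — normally
    assembled circular contigs never enter this comparison.
    """
    order = sorted(range(len(paths)),
                   key=lambda i: (-paths[i].length,
                                  min(paths[i].members) if paths[i].members else ""))
    if sketches is None:
        sketches = [None] * len(paths)
    kept: List[int] = []
    kept_sk: List[MinHashSketch] = []
    for i in order:
        sk = sketches[i]
        if sk is None:
            sk = sketch(path_sequence(paths[i], graph), params.sketch_params)
        dup = False
        for j_idx, j in enumerate(kept):
            if abs(paths[j].length - paths[i].length) > params.dedup_len_window:
                continue
            if mash_distance(kept_sk[j_idx], sk) <= params.dedup_max_dist:
                dup = True
                break
        if not dup:
            kept.append(i)
            kept_sk.append(sk)
    kept.sort()
    return [paths[i] for i in kept]


def rescue_circles(graph: AssemblyGraph,
                   params: RescueParams = RescueParams()) -> List[CircularPath]:
    """Find and deduplicate circular paths in one call."""
    return deduplicate_circles(find_circular_paths(graph, params), graph, params)
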
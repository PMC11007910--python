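"""Deterministic synthetic communities, graphs, reads and 16S gene sets.

Everything downstream is testable without real sequencing data through
these generators.  They emulate the regime the binning and completeness
methods target — HiFi-like metagenomes: multi-strain communities with a
wide, log-spread abundance range (default 10-200x), long low-error reads
(substitution-only; homopolymer indels are irrelevant to k-mer and
composition statistics), tangled assembly graphs containing known embedded
chromosome-scale cycles, and full-length 16S gene sets with species-level
divergence.  Every output is a pure function of its arguments including the
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .graph import AssemblyGraph, Link, OrientedSegment, Segment

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CommunityTruth:
    """Ground truth for a synthetic community."""

    genomes: List[Tuple[str, str, float]]  # (id, sequence, abundance x)
    contig_origin: Dict[str, str] = field(default_factory=dict)
    embedded_cycles: List[Set[str]] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "genomes": [{"id": g, "length": len(s), "abundance": a}
                            for g, s, a in self.genomes],
                "contig_origin": self.contig_origin,
                "embedded_cycles": [sorted(c) for c in self.embedded_cycles],
            }, fh, indent=1)


def random_genome(length: int, gc: float = 0.5, seed: int = 0,
                  skew: float = 0.5) -> str:
    """I.i.d. random DNA with P(G) + P(C) = gc.

    *skew* sets strand asymmetry within each base pair class:
    P(A) = (1-gc)*skew and P(G) = gc*skew.  Together gc and skew give
    genomes distinct k-mer compositions along two independent axes.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if not 0 < skew < 1:
        raise ValueError("skew must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) * skew, gc * (1 - skew), gc * skew, (1 - gc) * (1 - skew)]
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability *rate* (always to
    a different base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        # shift by 1..3 positions in base order, guaranteeing a change
        order = {b: i for i, b in enumerate(_BASES)}
        idx = np.array([order.get(b, 0) for b in arr[hits]])
        arr[hits] = _BASES[(idx + rng.integers(1, 4, size=hits.size)) % 4]
    return arr.tobytes().decode("ascii")


def fragment_genome(genome: str, n_contigs: int, min_len: int,
                    seed: int = 0) -> List[str]:
    """Split a genome into n non-overlapping fragments, each >= min_len,
    together covering the genome exactly."""
    L = len(genome)
    if n_contigs * min_len > L:
        raise ValueError(f"cannot cut {L} bp into {n_contigs} pieces of >= {min_len} bp")
    rng = np.random.default_rng(seed)
    extra = L - n_contigs * min_len
    parts = rng.multinomial(extra, np.full(n_contigs, 1.0 / n_contigs))
    lengths = (min_len + parts).tolist()
    out, pos = [], 0
    for ln in lengths:
        out.append(genome[pos:pos + ln])
        pos += ln
    return out


def simulate_reads(genomes: Sequence[str], abundances: Sequence[float],
                   read_len: int = 10_000, error_rate: float = 0.005,
                   seed: int = 0,
                   base_depth: float = 1.0) -> List[str]:
    """Uniform reads from circularised genomes.

    Per-genome depth is ``base_depth * abundance``; read starts are uniform
    with wrap-around, errors are i.i.d. substitutions.
    """
    if not 0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    reads: List[str] = []
    for gi, (genome, ab) in enumerate(zip(genomes, abundances)):
        L = len(genome)
        if read_len > L:
            raise ValueError(f"read_len {read_len} exceeds genome length {L}")
        n_reads = int(round(base_depth * ab * L / read_len))
        doubled = genome + genome[:read_len]
        for start in rng.integers(0, L, size=n_reads):
            reads.append(mutate(doubled[start:start + read_len], error_rate, rng))
    return reads


def make_strain_tangle(n_strains: int, backbone_len: int = 600_000,
                       shared_blocks: int = 1, seed: int = 0,
                       own_segment_len: int = 200_000,
                       shared_segment_len: int = 50_000,
                       with_sequences: bool = False,
                       ) -> Tuple[AssemblyGraph, CommunityTruth]:
    """A tangled graph of circular strain genomes sharing common segments.

    Each strain is a known embedded cycle of its own segments, interleaved
    with ``shared_blocks`` segments common to all strains — the
    high-strain-diversity topology that leaves chromosomes unresolved as
    circular subgraphs.  Each cycle totals at least *backbone_len*.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    rng = np.random.default_rng(seed)
    g = AssemblyGraph()
    truth = CommunityTruth(genomes=[])

    shared_ids = []
    for j in range(shared_blocks):
        sid = f"shared{j + 1}"
        seq = random_genome(shared_segment_len, 0.5, int(rng.integers(2 ** 31))) \
            if with_sequences else None
        g.add_segment(Segment(sid, shared_segment_len, seq))
        shared_ids.append(sid)

    shared_total = shared_blocks * shared_segment_len
    n_own = max(2 - shared_blocks, shared_blocks,
                int(np.ceil(max(backbone_len - shared_total, 1) / own_segment_len)))
    for i in range(n_strains):
        own_ids = []
        gc = 0.35 + 0.3 * (i / max(n_strains - 1, 1))
        for j in range(n_own):
            oid = f"s{i + 1}u{j + 1}"
            seq = random_genome(own_segment_len, gc, int(rng.integers(2 ** 31))) \
                if with_sequences else None
            g.add_segment(Segment(oid, own_segment_len, seq))
            own_ids.append(oid)
        # interleave: o1, S1, o2, S2, ..., then remaining own segments
        cycle = []
        for j, oid in enumerate(own_ids):
            cycle.append(oid)
            if j < len(shared_ids):
                cycle.append(shared_ids[j])
        for a, b in zip(cycle, cycle[1:] + [cycle[0]]):
            g.add_link(Link(OrientedSegment(a, "+"), OrientedSegment(b, "+"), 0))
        truth.embedded_cycles.append(set(cycle))
        abundance = float(10 * (200 / 10) ** rng.random())  # log-uniform 10-200x
        truth.genomes.append((f"strain{i + 1}", "", abundance))
        for oid in own_ids:
            truth.contig_origin[oid] = f"strain{i + 1}"
    return g, truth


def make_community(n_genomes: int = 8, seed: int = 0,
                   genome_len_range: Tuple[int, int] = (1_000_000, 3_000_000),
                   gc_range: Tuple[float, float] = (0.32, 0.66),
                   coverage_range: Tuple[float, float] = (10.0, 200.0),
                   contigs_per_genome: Tuple[int, int] = (5, 20),
                   min_contig_len: int = 100_000,
                   coverage_jitter: float = 0.05,
                   ) -> Tuple[Dict[str, str], Dict[str, float], CommunityTruth]:
    """Synthetic multi-genome community fragmented into binnable contigs.

    Genomes are placed on a 2-D composition grid — GC content levels crossed
    with strand skew — so every pair differs along at least one composition
    axis, and get log-spread coverages (default 10-200x); each genome is cut
    into 5-20 contigs of >= 100 kb.  Returns (contig sequences, contig
    depths, truth).
    """
    rng = np.random.default_rng(seed)
    n_gc = (n_genomes + 1) // 2
    gc_levels = np.linspace(*gc_range, n_gc) if n_gc > 1 \
        else [np.mean(gc_range)]
    gcs = [float(gc_levels[i // 2]) for i in range(n_genomes)]
    # canonical profiles are blind to skew *direction* (A<->T, G<->C swap is
    # reverse-complement symmetry), so the second axis is skew magnitude
    skews = [0.68 if i % 2 else 0.5 for i in range(n_genomes)]
    covs = np.geomspace(*coverage_range, n_genomes)
    rng.shuffle(covs)
    contigs: Dict[str, str] = {}
    depths: Dict[str, float] = {}
    truth = CommunityTruth(genomes=[])
    for i in range(n_genomes):
        glen = int(rng.integers(genome_len_range[0], genome_len_range[1] + 1))
        gid = f"genome{i + 1}"
        genome = random_genome(glen, gcs[i], int(rng.integers(2 ** 31)),
                               skew=skews[i])
        truth.genomes.append((gid, genome, float(covs[i])))
        lo, hi = contigs_per_genome
        n_max = min(hi, glen // min_contig_len)
        n_contigs = int(rng.integers(lo, max(n_max, lo) + 1))
        for j, frag in enumerate(fragment_genome(genome, n_contigs, min_contig_len,
                                                 int(rng.integers(2 ** 31)))):
            cid = f"{gid}_c{j + 1}"
            contigs[cid] = frag
            depths[cid] = float(covs[i]) * float(1 + coverage_jitter * rng.standard_normal())
            truth.contig_origin[cid] = gid
    return contigs, depths, truth


def simulate_ssu_genes(n_templates: int = 5, copies_per_template: int = 20,
                       template_divergence: float = 0.025,
                       copy_error: float = 0.003, length: int = 1500,
                       seed: int = 0):
    """Species-like 16S gene sets: templates derived from a shared ancestor
    (pairwise divergence ~2x *template_divergence*, >= 3% at the default),
    each emitting noisy copies at <= 0.5% per-copy error.

    Returns (genes, template_of) where genes is a list of
    :class:`~circlebin.otu.SSUGene` and template_of maps gene id -> template
    index.
    """
    from .otu import SSUGene

    rng = np.random.default_rng(seed)
    ancestor = random_genome(length, 0.55, int(rng.integers(2 ** 31)))
    templates = [mutate(ancestor, template_divergence, rng)
                 for _ in range(n_templates)]
    genes, template_of = [], {}
    for t, tmpl in enumerate(templates):
        for c in range(copies_per_template):
            gid = f"t{t + 1}_copy{c + 1}"
            genes.append(SSUGene(gid, mutate(tmpl, copy_error, rng)))
            template_of[gid] = t
    # interleave across templates so seeds are not trivially the first block
    order = np.argsort(rng.random(len(genes)))
    genes = [genes[i] for i in order]
    return genes, template_of


# --------------------------------------------------------------- sequence I/O

def write_fasta(seqs: Dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Sequence[str], path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads, 1):
            fh.write(f"@{prefix}{i}\n{r}\n+\n{'I' * len(r)}\n")


def read_seqs(path) -> List[str]:
    """Sequences from FASTA or FASTQ, sniffed from the first character."""
    from Bio import SeqIO
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]


def write_depth_table(depths: Dict[str, float], lengths: Dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("contigName\tcontigLen\ttotalAvgDepth\n")
        for cid in depths:
            fh.write(f"{cid}\t{lengths[cid]}\t{depths[cid]:.4f}\n")
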
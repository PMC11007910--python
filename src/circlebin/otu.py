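"""Greedy incremental OTU clustering of full-length 16S rRNA sequences.

HiFi reads are long enough to span a 16S gene, so species composition can be
estimated straight from reads: cluster the read-derived 16S genes into OTUs
(>= 99% identity over an alignment block longer than 1 kb) and then ask
which abundant OTUs are carried by the assembled MAGs.  An abundant OTU with
no MAG carrying its label marks a species the assembly failed to represent —
a reference-free completeness check complementary to the k-mer spectrum.

Clustering is order-dependent by construction (greedy incremental): each
gene either joins the best-identity qualifying seed or becomes a new seed.
Genes flagged "partial" never seed a new OTU but may join existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from Bio import Align

from ._kmer import revcomp

UNDEFINED = "undefined"


@dataclass
class SSUGene:
    id: str
    seq: str
    partial: bool = False
    source: str = "read"  # read | contig

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"gene {self.id}: empty sequence")


def _make_aligner() -> Align.PairwiseAligner:
    # local alignment with affine gaps, tuned for ~1.5 kb genes at a few
    # percent divergence: positive expected score keeps true pairs spanning
    # the full gene while random pairs align only short blocks
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -4
    a.extend_gap_score = -2
    return a


_ALIGNER = _make_aligner()


def align_identity(a: str, b: str) -> Tuple[int, float]:
    """Alignment block length (columns) and identity (matches / columns).

    Local alignment; both strands of *b* are tried and the higher-scoring
    one reported.  Returns (0, 0.0) when nothing aligns.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    best = (0, 0.0, float("-inf"))
    max_score = min(len(a), len(b)) * _ALIGNER.match_score
    for query in (b, revcomp(b)):
        try:
            aln = _ALIGNER.align(a.upper(), query.upper())[0]
        except (IndexError, ValueError):
            continue
        c = aln.counts()
        blen = c.gaps + c.identities + c.mismatches
        if blen == 0:
            continue
        ident = c.identities / blen
        if aln.score > best[2]:
            best = (blen, ident, aln.score)
        if best[2] >= 0.8 * max_score:
            break  # near-maximal same-strand hit; reverse strand cannot win
    return best[0], best[1]


@dataclass
class OTUAssignment:
    """Gene -> OTU labels plus the ordered seed list that defines the OTUs."""

    labels: Dict[str, str] = field(default_factory=dict)
    seeds: List[Tuple[str, str]] = field(default_factory=list)  # (label, gene id)
    seed_seqs: Dict[str, str] = field(default_factory=dict)  # label -> sequence
    identities: Dict[str, float] = field(default_factory=dict)

    @property
    def n_otus(self) -> int:
        return len(self.seeds)

    def label_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for lab in self.labels.values():
            if lab != UNDEFINED:
                out[lab] = out.get(lab, 0) + 1
        return out


def _best_seed(seq: str, assignment: OTUAssignment,
               min_blen: int, min_ident: float) -> Tuple[Optional[str], float]:
    """Best qualifying seed label for *seq*; ties go to the earliest seed."""
    best_label, best_ident = None, -1.0
    for label, _gene in assignment.seeds:
        blen, ident = align_identity(assignment.seed_seqs[label], seq)
        if blen > min_blen and ident >= min_ident and ident > best_ident:
            best_label, best_ident = label, ident
    return best_label, best_ident


def greedy_cluster(genes: Sequence[SSUGene], min_blen: int = 1000,
                   min_ident: float = 0.99) -> OTUAssignment:
    """Greedy incremental clustering in input order.

    A gene joins the qualifying seed of highest identity (first seed wins
    exact ties); otherwise it becomes a new seed — unless flagged partial,
    in which case it is left ``undefined`` rather than seeding an OTU.
    """
    assignment = OTUAssignment()
    for gene in genes:
        label, ident = _best_seed(gene.seq, assignment, min_blen, min_ident)
        if label is not None:
            assignment.labels[gene.id] = label
            assignment.identities[gene.id] = ident
        elif gene.partial:
            assignment.labels[gene.id] = UNDEFINED
        else:
            label = f"OTU{len(assignment.seeds) + 1:04d}"
            assignment.seeds.append((label, gene.id))
            assignment.seed_seqs[label] = gene.seq
            assignment.labels[gene.id] = label
            assignment.identities[gene.id] = 1.0
    return assignment


def assign_unseen(seq: str, assignment: OTUAssignment, min_blen: int = 1000,
                  min_ident: float = 0.99) -> str:
    """Label an unseen 16S copy against existing seeds only; never seeds."""
    label, _ = _best_seed(seq, assignment, min_blen, min_ident)
    return label if label is not None else UNDEFINED


@dataclass
class RecoveryReport:
    """Per abundant OTU: read copy count and whether any MAG carries it."""

    otus: List[str]
    copies: Dict[str, int]
    seen_in_mag: Dict[str, bool]

    @property
    def fraction_recovered(self) -> float:
        if not self.otus:
            return 0.0
        return sum(self.seen_in_mag[o] for o in self.otus) / len(self.otus)


def evaluate_recovery(read_assignment: OTUAssignment,
                      mag_gene_labels: Dict[str, Set[str]],
                      min_copies: int = 10) -> RecoveryReport:
    """Which abundant OTUs (>= *min_copies* read copies) appear in any MAG.

    A MAG may carry several labels (multiple distinct 16S copies); all of
    them count as seen.  OTUs below the copy threshold are dropped to avoid
    artifacts from sequencing errors and very low-coverage species.
    """
    counts = read_assignment.label_counts()
    mag_labels: Set[str] = set()
    for labels in mag_gene_labels.values():
        mag_labels |= {l for l in labels if l != UNDEFINED}
    keep = sorted((o for o, n in counts.items() if n >= min_copies),
                  key=lambda o: (-counts[o], o))
    return RecoveryReport(keep, {o: counts[o] for o in keep},
                          {o: o in mag_labels for o in keep})


def verify_assignment(genes: Sequence[SSUGene], assignment: OTUAssignment,
                      min_blen: int = 1000, min_ident: float = 0.99) -> bool:
    """Post-hoc check: every non-seed labeled gene aligns to its seed with
    blen > min_blen and identity >= min_ident."""
    seed_ids = {gid for _, gid in assignment.seeds}
    by_id = {g.id: g for g in genes}
    for gid, label in assignment.labels.items():
        if label == UNDEFINED or gid in seed_ids:
            continue
        blen, ident = align_identity(assignment.seed_seqs[label], by_id[gid].seq)
        if not (blen > min_blen and ident >= min_ident):
            return False
    return True
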
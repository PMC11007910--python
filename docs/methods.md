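# Methods

## Assembly-graph model

The graph is the GFA 1.0 bidirected contig graph: segments with length,
optional sequence and mean read depth; links as oriented overlaps whose
mirror (`y⁻ → x⁻` for every `x⁺ → y⁺`) is always implied in adjacency
queries. Overlap lengths come from the L-line CIGAR's reference-consuming
operations (`*` counts as 0). All coordinates are 0-based half-open, and
`-` orientation means reverse complement of the stored sequence.

Circularity of a single contig is a format-level decision: a segment is
flagged circular when it carries a self-link with equal orientations on both
ends, or when a `cl:i:1` tag (or external metadata) says so. Assemblers know
which contigs they closed; an exported graph does not always encode it, so
both routes are accepted.

Depth is consumed from a MetaBAT2-style TSV (`contigName`, `contigLen`,
`totalAvgDepth`; extra per-sample columns ignored) rather than recomputed
from alignments — depth estimation belongs to the assembler/mapper, not to
binning.

## Circle rescue

DFS roots are unvisited contigs in decreasing length order; each root
contributes at most one accepted circle, and contigs of accepted circles are
never used as roots again. A walk is accepted when it returns to its
*starting oriented segment* — same id and same orientation — so the spelled
sequence is a consistent circle; a bidirected closure onto the opposite
orientation does not spell a circular genome and is not accepted. Each
segment id may appear once per walk.

Two throttles keep the enumeration from spelling every near-identical path
through a tangle: at forks, successors are tried in ascending order of how
often they were used in previously accepted circles (ties by id, then
orient), and a candidate is rejected when the summed prior usage of its
members reaches the usage cap (default 100). Defaults: minimum path length
500 kb, minimum 2 contigs. The search is an explicit-stack DFS, so graph
size is bounded by memory, not recursion depth.

Deduplication processes circles in decreasing length (ties by smallest
member id, since a pairwise rule alone is order-ambiguous): a circle is
dropped iff an already-kept circle is within 1 Mb of its length *and* at
Mash distance ≤ 0.05. Circles more than 1 Mb apart in length are assumed to
be different replicons regardless of sequence similarity. Normally
assembled circular contigs never enter this comparison. The sketched
sequence is the walk's oriented concatenation with link overlaps trimmed
from each successor (and from the closing junction), the same convention
used for path length.

## MinHash sketching

Bottom-s MinHash (defaults k = 21, s = 1000) over canonical k-mers packed
into 64-bit integers and hashed with splitmix64 under a fixed seed
constant. The Jaccard index is estimated from the s smallest hashes of the
union; distance is −(1/k)·ln(2j/(1+j)), clamped to [0, 1]. Sketches are
deterministic within this package; byte-compatibility with external
sketching tools is a non-goal. The exact-Jaccard distance over all k-mers
is provided alongside as a brute-force companion and testing oracle.

## Composition binning

Candidates are contigs ≥ 100 kb that are neither members of rescued circles
nor circular contigs > 1 Mb (the latter become single-contig bins
directly). Features: 512 canonical 5-mer frequencies (normalised to sum 1;
k configurable — 4-mers give 136 columns and similar behaviour) plus log₁₀
mean depth, each column z-scored with a zero-variance guard.

t-SNE (scikit-learn Barnes–Hut, PCA init, fixed random state) embeds the
matrix to 2-D. Because t-SNE coordinates have arbitrary scale, the
embedding is rescaled to unit RMS distance from its centroid before any
radius is applied; the clustering radius r1 (default 0.1) is defined on
that normalised plane. Perplexity is clamped to (n−1)/3 when the candidate
set is small. With fewer than 3 candidates no embedding is attempted:
contigs ≥ 500 kb become singleton bins, the rest stay unbinned.

Radius clustering visits seeds in decreasing contig length (ties by id)
against a blocked set: (i) if any unblocked point lies within r1 of the
seed, bin the seed with all such points; (ii) otherwise, if unblocked
points exist within 1.6·r1 and some circle of radius 0.8·r1 whose boundary
passes through the seed covers them all, bin those (feasibility is tested
by sweeping 360 candidate centres at distance 0.8·r1 from the seed — the
geometric test is not otherwise specified by the heuristic, and a discrete
sweep is exact enough at these radii); (iii) otherwise the seed becomes a
single-contig bin iff longer than 500 kb, else it stays unbinned and may
still join a later seed's bin. Final bins are the disjoint union of
cluster bins, rescued circles and ≥ 1 Mb circular contigs; overlapping
membership is an integrity error.

## k-mer spectrum

Canonical k-mer counting (default k = 31, the conventional read-evaluation
size; windows with non-ACGT skipped) over reads and assembly gives the
joint table M[c][x]; assembly copy numbers are capped at c_max (default 4,
the last band aggregating ≥ 4×, matching how such plots are usually drawn).
Right-accumulation N⁽ᶜ⁾ₓ = Σ_{y ≥ x} M[c][y] and stacking N⁽ᶜ⁾ₓ/Nₓ produce
the bands; conservation Σ_c N⁽ᶜ⁾ₓ = Nₓ is asserted on every computed
spectrum. Plots truncate at the smallest x with Nₓ below a threshold
(default 10⁶, configurable down for desk-scale data).

High-multiplicity interval extraction marks every contig position whose
canonical k-mer has assembly multiplicity in [2, 15] and read multiplicity
≥ 800, spans k bases per hit, merges overlapping/book-ended spans per
contig, and dumps the sequences (BED 0-based half-open).

## 16S OTU clustering

Greedy incremental clustering in input order: a gene joins the
highest-identity seed with alignment block > 1000 columns and identity
≥ 0.99 (matches / alignment columns, gaps counted as columns; exact ties go
to the earliest seed), else it seeds a new OTU. Genes flagged "partial"
may join existing OTUs but never seed one; a flag allows sorting by length
descending instead of input order. Alignment is Biopython's
`PairwiseAligner` in local mode (match +1, mismatch −2, gap open −4,
extend −2), both strands, with an early exit when the forward strand
already scores ≥ 0.8 of the theoretical maximum — suitable for ~1.5 kb
genes at a few percent divergence: true pairs align end to end while random
pairs produce only short blocks, so the block-length rule rejects them.
Order dependence is intrinsic to greedy clustering and is documented, not
hidden; membership (seed-to-member identity) is re-verifiable post hoc, and
no member–member identity is claimed.

Recovery evaluation drops OTUs with fewer than 10 read copies, and a MAG
carrying several 16S labels contributes all of them as "seen".

## MAG quality and bin post-processing

Quality score = completeness − 5 × contamination. Categories, evaluated in
order: near-complete (completeness ≥ 90, contamination < 5), high-quality
(≥ 70, < 10), medium-quality (≥ 50 and score ≥ 50), else failed. Bounds are
taken literally (closed on ≥, open on <). Post-processing moves every
≥ 1 Mb circular contig that shares an external bin with other contigs into
its own singleton bin. Merging discards an external bin of 0.5–10 Mb total
size iff it shares > 1 Mb of sequence or > 10 contigs with any single
rescued circle (sharing is evaluated per circle; contigs are atomic, no
sub-contig overlap is computed), then combines surviving bins, circles and
big circular contigs.

## Synthetic data

The generators emulate the regime the methods target, not real sequencing:

* genomes are i.i.d. base streams on a composition grid — GC levels crossed
  with strand-skew magnitude. Canonical k-mer profiles are blind to skew
  *direction* (an A↔T/G↔C swap is reverse-complement symmetry), so the
  second axis varies the magnitude of the asymmetry; this gives every
  genome pair separation along at least one composition axis, standing in
  for the distinct oligonucleotide signatures of real taxa;
* communities default to 8 genomes of 1–3 Mb at log-spread 10–200×
  coverage with 5% depth jitter, each cut into 5–20 contigs ≥ 100 kb;
* strain tangles interleave per-strain segments (~200 kb) with segments
  shared across strains (~50 kb), so each strain is a known embedded cycle
  ≥ 500 kb in a tangled graph;
* reads are uniform circular substrings with i.i.d. substitution errors
  (≤ 5%); HiFi homopolymer indels are irrelevant to every statistic here
  except alignment identity, where the aligner handles gaps anyway;
* 16S sets derive 5 templates from a shared ancestor at 2.5% per-template
  divergence (~5% pairwise, safely past the 3% species gap) and emit 20
  copies each at 0.3% noise.

Passing tests on these fixtures show the algorithms implement their
contracts and separate genuinely distinct genomes; they do not show
performance on real communities with shared mobile elements, uneven
within-genome composition, or closely related strains below the species
boundary.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale sizes chosen to exercise
every code path: 50 random tangles (≤ 15 segments) with an exhaustive
simple-cycle oracle, 20 sketch-vs-exact pairs of 5 kb at 0–3% divergence,
~10 Mb of reads at k = 31 for the spectrum, one 8-genome community
(~80–110 contigs) embedded at perplexities {15, 30, 50} and clustered at
r1 ∈ {0.05, 0.1, 0.3}, and 100 simulated 16S genes. Binning recovery is
counted as genomes for which some bin is ≥ 90% single-origin by bp; across
the r1/perplexity grid the count varies by at most one genome, consistent
with the stated insensitivity of these parameters. All randomness flows
from explicit seeds; t-SNE uses a fixed `random_state`, so identical inputs
reproduce identical bins.

## Known limitations

* Circle rescue targets bacterial chromosomes: linear chromosomes,
  plasmids and viral genomes are out of scope, as are repeat-graph
  (metaFlye-style) topologies.
* The greedy one-circle-per-root rule can miss a second disjoint circle
  reachable from the same root; with ≤ 2 shared segments per tangle the
  harness requires recovery of all but at most one embedded cycle.
* The 0×-band rescue of near-miss k-mers by approximate alignment, and any
  annotation of extracted high-multiplicity intervals, are not implemented.
* Sketch hashes are internal: do not compare serialized sketches across
  tools.
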
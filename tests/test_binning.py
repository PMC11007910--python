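"""Feature extraction, t-SNE embedding, and radius clustering."""

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from circlebin._kmer import revcomp
from circlebin.binning import (Bin, BinningParams, assemble_final_bins,
                               bin_contigs, build_feature_matrix,
                               canonical_kmer_count, canonical_kmer_profile,
                               embed, radius_cluster, select_candidates)
from circlebin.graph import AssemblyGraph, Link, OrientedSegment, Segment
from circlebin.rescue import CircularPath
from circlebin.simulate import random_genome
from conftest import bin_purity_recovered


class TestKmerProfile:
    def test_512_canonical_5mers(self):
        assert canonical_kmer_count(5) == 512

    def test_homopolymer_single_entry(self):
        prof = canonical_kmer_profile("A" * 100)
        assert prof.shape == (512,)
        assert np.count_nonzero(prof) == 1
        assert prof.max() == 1.0
        assert prof[0] == 1.0  # AAAAA is the lexicographically first code

    def test_revcomp_symmetry(self):
        seq = random_genome(10_000, 0.42, 0)
        assert np.allclose(canonical_kmer_profile(seq),
                           canonical_kmer_profile(revcomp(seq)))

    def test_sums_to_one(self):
        seq = random_genome(5000, 0.6, 1)
        assert canonical_kmer_profile(seq).sum() == pytest.approx(1.0)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            canonical_kmer_profile("ACG")

    def test_k4_gives_136_canonical(self):
        # even k: 4^4/2 + (palindromic 4-mers)/2 = 136
        assert canonical_kmer_count(4) == 136


def _graph_with(segments):
    g = AssemblyGraph()
    for cid, ln, circ in segments:
        g.add_segment(Segment(cid, ln, is_circular=circ))
    return g


class TestSelectCandidates:
    def test_three_criteria(self):
        g = _graph_with([
            ("lin150", 150_000, False),   # candidate
            ("circ2m", 2_000_000, True),  # big circular -> excluded
            ("incirc", 150_000, False),   # circle member -> excluded
            ("lin80", 80_000, False),     # too short -> excluded
            ("circ800k", 800_000, True),  # small circular -> candidate
        ])
        circ = CircularPath([OrientedSegment("incirc", "+")], 150_000)
        assert select_candidates(g, [circ]) == ["circ800k", "lin150"]


class TestFeatureMatrix:
    def test_shape_is_n_by_513(self):
        seqs = {f"c{i}": random_genome(2000, 0.4 + 0.1 * i, i) for i in range(3)}
        covs = {f"c{i}": 10.0 * (i + 1) for i in range(3)}
        mat = build_feature_matrix(sorted(seqs), seqs, covs)
        assert mat.shape == (3, 513)
        assert np.isfinite(mat).all()

    def test_columns_standardized(self):
        seqs = {f"c{i}": random_genome(3000, 0.35 + 0.05 * i, i) for i in range(5)}
        covs = {f"c{i}": 5.0 + i for i in range(5)}
        mat = build_feature_matrix(sorted(seqs), seqs, covs)
        assert np.allclose(mat.mean(axis=0), 0, atol=1e-12)
        stds = mat.std(axis=0)
        assert np.allclose(stds[stds > 0], 1.0)

    def test_duplicate_rows_identical_and_degenerate_matrix_zero(self):
        seq = random_genome(2000, 0.5, 7)
        seqs = {"a": seq, "b": seq, "c": seq}
        covs = {"a": 10.0, "b": 10.0, "c": 10.0}
        mat = build_feature_matrix(["a", "b", "c"], seqs, covs)
        assert np.allclose(mat, 0.0)  # zero-variance guard

    def test_nonpositive_coverage_rejected(self):
        seqs = {"a": random_genome(2000, 0.5, 8)}
        with pytest.raises(ValueError):
            build_feature_matrix(["a"], seqs, {"a": 0.0})

    def test_missing_sequence_rejected(self):
        with pytest.raises(KeyError):
            build_feature_matrix(["zz"], {}, {"zz": 5.0})


class TestEmbed:
    def test_deterministic_for_fixed_seed(self, community_embedding):
        from circlebin.binning import embed as _embed
        cands, mat, coords = community_embedding
        again = _embed(mat, BinningParams(seed=1))
        assert np.array_equal(coords, again)

    def test_unit_rms_normalization(self, community_embedding):
        _, _, coords = community_embedding
        rms = np.sqrt((coords ** 2).sum(axis=1).mean())
        assert rms == pytest.approx(1.0, abs=1e-6)

    def test_two_blob_separation_has_high_silhouette(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, size=(50, 513))
        b = rng.normal(6.0, 1.0, size=(50, 513))
        mat = np.vstack([a, b])
        labels = np.array([0] * 50 + [1] * 50)
        coords = embed(mat, BinningParams(seed=0))
        assert silhouette_score(coords, labels) > 0.5

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            embed(np.zeros((2, 513)), BinningParams())


class TestRadiusCluster:
    def params(self, **kw):
        return BinningParams(**kw)

    def test_two_tight_groups_partition(self):
        coords = np.array([[0.0, 0.0], [0.05, 0.0], [0.0, 0.05],
                           [2.0, 2.0], [2.05, 2.0]])
        ids = ["a", "b", "c", "d", "e"]
        lengths = {"a": 500, "b": 400, "c": 300, "d": 200, "e": 100}
        bins = radius_cluster(coords, ids, lengths, self.params())
        sets = {frozenset(b.members) for b in bins}
        assert frozenset("abc") in sets and frozenset("de") in sets

    def test_isolated_long_point_becomes_singleton(self):
        coords = np.array([[0, 0], [5, 5], [5.01, 5]], dtype=float)
        ids = ["far", "x", "y"]
        lengths = {"far": 600_000, "x": 200_000, "y": 150_000}
        bins = radius_cluster(coords, ids, lengths, self.params())
        assert any(b.members == {"far"} and b.kind == "single_contig" for b in bins)

    def test_isolated_short_point_unbinned(self):
        coords = np.array([[0, 0], [5, 5], [5.01, 5]], dtype=float)
        ids = ["far", "x", "y"]
        lengths = {"far": 200_000, "x": 900_000, "y": 150_000}
        bins = radius_cluster(coords, ids, lengths, self.params())
        assert not any("far" in b.members for b in bins)

    def test_fallback_halfplane_bin_created(self):
        # neighbors on one side, between r1 and 1.6*r1 from the seed, all
        # coverable by a radius-0.8*r1 circle through the seed
        r1 = 0.1
        seed_pt = np.array([0.0, 0.0])
        neigh = np.array([[0.12, 0.0], [0.13, 0.02], [0.12, -0.02]])
        coords = np.vstack([seed_pt, neigh])
        ids = ["s", "n1", "n2", "n3"]
        lengths = {"s": 400_000, "n1": 100_000, "n2": 100_000, "n3": 100_000}
        bins = radius_cluster(coords, ids, lengths, self.params(r1=r1))
        assert any(b.members == {"s", "n1", "n2", "n3"} for b in bins)

    def test_fallback_infeasible_when_neighbors_on_opposite_sides(self):
        r1 = 0.1
        coords = np.array([[0.0, 0.0], [0.15, 0.0], [-0.15, 0.0]])
        ids = ["s", "n1", "n2"]
        lengths = {"s": 400_000, "n1": 100_000, "n2": 100_000}
        bins = radius_cluster(coords, ids, lengths, self.params(r1=r1))
        # no circle of radius 0.08 through s covers points 0.15 on both sides
        assert not any(b.members == {"s", "n1", "n2"} for b in bins)

    def test_bins_disjoint_and_deterministic(self, community, community_embedding):
        contigs, _, _ = community
        cands, _, coords = community_embedding
        lengths = {c: len(s) for c, s in contigs.items()}
        b1 = radius_cluster(coords, cands, lengths, self.params(seed=1))
        b2 = radius_cluster(coords, cands, lengths, self.params(seed=1))
        assert [b.members for b in b1] == [b.members for b in b2]
        seen = set()
        for b in b1:
            assert not (b.members & seen)
            seen |= b.members


class TestAssembleFinalBins:
    def test_disjoint_union_counts(self):
        circles = [CircularPath([OrientedSegment("a", "+"), OrientedSegment("b", "+")], 1),
                   CircularPath([OrientedSegment("c", "+"), OrientedSegment("d", "+")], 1)]
        clustered = [Bin("bin1", {"e", "f"}, "multi_contig"),
                     Bin("bin2", {"g"}, "single_contig"),
                     Bin("bin3", {"h", "i"}, "multi_contig")]
        out = assemble_final_bins(["bigcirc"], circles, clustered)
        assert len(out) == 6
        kinds = sorted(b.kind for b in out)
        assert kinds.count("rescued_circle") == 2
        assert kinds.count("circular_contig") == 1

    def test_empty_cluster_set(self):
        circles = [CircularPath([OrientedSegment("a", "+"), OrientedSegment("b", "+")], 1)]
        out = assemble_final_bins(["z"], circles, [])
        assert {b.kind for b in out} == {"circular_contig", "rescued_circle"}

    def test_overlap_is_integrity_error(self):
        circles = [CircularPath([OrientedSegment("a", "+"), OrientedSegment("b", "+")], 1)]
        clustered = [Bin("bin1", {"a"}, "single_contig")]
        with pytest.raises(ValueError):
            assemble_final_bins([], circles, clustered)


class TestParameterRecovery:
    """Desk-scale analogue of near-complete/low-contamination binning."""

    def test_most_genomes_recovered_pure(self, community, community_embedding):
        contigs, _, truth = community
        cands, _, coords = community_embedding
        lengths = {c: len(s) for c, s in contigs.items()}
        bins = radius_cluster(coords, cands, lengths, BinningParams(seed=1))
        assert len(bin_purity_recovered(bins, truth, lengths)) >= 6

    def test_every_big_circular_contig_is_own_bin(self):
        g = _graph_with([("bigc", 1_500_000, True), ("l1", 600_000, False)])
        g.segments["bigc"].sequence = random_genome(10_000, 0.5, 1)
        g.segments["l1"].sequence = random_genome(10_000, 0.4, 2)
        g.segments["bigc"].coverage = 10.0
        g.segments["l1"].coverage = 20.0
        bins = bin_contigs(g, [])
        assert any(b.members == {"bigc"} and b.kind == "circular_contig"
                   for b in bins)
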
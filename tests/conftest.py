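"""Shared fixtures; expensive simulations are session-scoped."""

import numpy as np
import pytest

from circlebin import simulate
from circlebin.graph import AssemblyGraph, Link, OrientedSegment, Segment


def make_cycle_graph(ids_lengths, orient="+"):
    """Simple one-cycle graph helper: [(id, length), ...] linked in order."""
    g = AssemblyGraph()
    for cid, ln in ids_lengths:
        g.add_segment(Segment(cid, ln))
    ids = [cid for cid, _ in ids_lengths]
    for a, b in zip(ids, ids[1:] + [ids[0]]):
        g.add_link(Link(OrientedSegment(a, orient), OrientedSegment(b, orient), 0))
    return g


@pytest.fixture(scope="session")
def community():
    """Default 8-genome synthetic community (contigs, depths, truth)."""
    return simulate.make_community(8, seed=1)


@pytest.fixture(scope="session")
def community_embedding(community):
    """Feature matrix + default-parameter embedding for the community."""
    from circlebin import binning
    contigs, depths, _ = community
    cands = sorted(contigs)
    mat = binning.build_feature_matrix(cands, contigs, depths)
    coords = binning.embed(mat, binning.BinningParams(seed=1))
    return cands, mat, coords


@pytest.fixture(scope="session")
def ssu_clustering():
    """5-template 16S simulation plus its greedy clustering at 99%."""
    from circlebin import otu
    genes, template_of = simulate.simulate_ssu_genes(
        5, 20, template_divergence=0.025, copy_error=0.003, seed=3)
    assignment = otu.greedy_cluster(genes)
    return genes, template_of, assignment


def bin_purity_recovered(bins, truth, lengths, min_purity=0.9):
    """Genomes for which some bin is >= min_purity single-origin by bp."""
    got = set()
    for b in bins:
        bp = {}
        for m in b.members:
            g = truth.contig_origin[m]
            bp[g] = bp.get(g, 0) + lengths[m]
        g, best = max(bp.items(), key=lambda kv: kv[1])
        if best / sum(bp.values()) >= min_purity:
            got.add(g)
    return got
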
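"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from clusterscout import (
    FamilyCatalog,
    GeneModel,
    NeighborhoodRegion,
    classify_region,
)


@pytest.fixture
def thalianol_like_genes():
    """A toy annotation shaped like the Arabidopsis thalianol cluster:
    an acyltransferase (outside the five-family universe) followed by
    a terpene synthase and three P450s, all tightly packed."""
    return [
        GeneModel("ACT", "chr5", 1_000, 3_000, "+", "BAHD acyltransferase"),
        GeneModel("THAS", "chr5", 5_000, 8_000, "+", "terpene synthase (thalianol synthase)"),
        GeneModel("THAH", "chr5", 10_000, 13_000, "-", "cytochrome P450 708A2"),
        GeneModel("THAD", "chr5", 15_000, 18_000, "+", "cytochrome P450 705A5"),
        GeneModel("CYP705A12", "chr5", 20_000, 23_000, "-", "cytochrome P450 705A12"),
    ]


@pytest.fixture
def thalianol_catalog():
    return FamilyCatalog(assignments={
        "THAS": "TPS", "THAH": "P450", "THAD": "P450", "CYP705A12": "P450",
    })


def make_region(region_id, members, families, chrom="chr1", start=1, end=100_000):
    """Fabricate a classified region for summary/matching tests."""
    return classify_region(NeighborhoodRegion(
        region_id=region_id, chrom=chrom, span_start=start, span_end=end,
        members=tuple(members), families=tuple(families),
    ))


def random_annotation(rng, n_genes, n_chrom=2, chrom_len=500_000, family_rate=0.4):
    """A random annotation + catalog with no placement guarantees,
    for stress-testing detection against the oracle."""
    genes, assignments = [], {}
    families = ("P450", "2ODD", "TPS", "PKS", "UGT")
    for i in range(n_genes):
        chrom = f"c{rng.integers(1, n_chrom + 1)}"
        start = int(rng.integers(1, chrom_len))
        length = int(rng.integers(200, 5_000))
        gid = f"g{i:04d}"
        genes.append(GeneModel(gid, chrom, start, start + length, "+"))
        if rng.random() < family_rate:
            assignments[gid] = str(rng.choice(families))
    return genes, FamilyCatalog(assignments=assignments)


def chain_oracle(genes, catalog, max_intervening, max_gap_bp, min_genes):
    """Exhaustive chain-enumeration oracle for neighborhood detection.

    Builds a graph over family genes with an edge for every consecutive
    pair (in sorted order) satisfying the intervening/gap constraints, and
    reads maximal chains off its connected components. Returns frozensets
    of member IDs.
    """
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    by_chrom = {}
    for g in ordered:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = set()
    for cg in by_chrom.values():
        fam = [(k, g) for k, g in enumerate(cg) if g.gene_id in catalog]
        graph = nx.Graph()
        graph.add_nodes_from(g.gene_id for _, g in fam)
        for (ki, gi), (kj, gj) in zip(fam, fam[1:]):
            intervening = kj - ki - 1
            gap = max(0, gj.start - gi.end)
            if intervening <= max_intervening and gap <= max_gap_bp:
                graph.add_edge(gi.gene_id, gj.gene_id)
        for comp in nx.connected_components(graph):
            if len(comp) >= min_genes:
                out.add(frozenset(comp))
    return out


def pcc_oracle(values):
    """Pearson correlation from the definitional summation."""
    n_genes, n_samples = values.shape
    out = np.ones((n_genes, n_genes))
    for i in range(n_genes):
        for j in range(n_genes):
            xi, xj = values[i], values[j]
            mi, mj = xi.mean(), xj.mean()
            num = ((xi - mi) * (xj - mj)).sum()
            den = np.sqrt(((xi - mi) ** 2).sum() * ((xj - mj) ** 2).sum())
            out[i, j] = num / den
    return out


def mutual_rank_oracle(pcc):
    """Double-loop mutual-rank oracle with fractional tie ranks."""
    n = pcc.shape[0]
    ranks = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            greater = sum(
                1 for k in range(n) if k != i and pcc[i, k] > pcc[i, j]
            )
            equal = sum(
                1 for k in range(n) if k != i and pcc[i, k] == pcc[i, j]
            )
            ranks[i, j] = greater + (equal + 1) / 2
    mr = np.sqrt(ranks * ranks.T)
    np.fill_diagonal(mr, 0.0)
    return mr
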
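"""Mutual-rank co-expression networks over candidate-region genes.

The screen follows the ATTED-II scoring convention: Pearson correlation of
log-transformed expression profiles, ranks of each gene's partners by
descending correlation, and the mutual rank MR(i,j) = sqrt(rank_i(j) *
rank_j(i)) as the edge score (lower = stronger co-expression). Connected
components of the thresholded network define "co-expressed networks"; a
candidate neighboring-gene region qualifies when enough of its members land
in one component.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .genome_io import ExpressionMatrix
from .neighborhood import NeighborhoodRegion

logger = logging.getLogger(__name__)

DEFAULT_MR_MAX = 30.0
DEFAULT_MIN_COEXPRESSED_MEMBERS = 3
DEFAULT_PSEUDO_COUNT = 1.0
DEFAULT_MIN_EXPRESSED_SAMPLES = 3


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with its gene-ID axis."""

    gene_ids: list[str]
    pcc: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.pcc.shape != (n, n):
            raise ValueError("pcc shape inconsistent with gene_ids")
        if not np.allclose(self.pcc, self.pcc.T, atol=1e-12):
            raise ValueError("pcc matrix not symmetric")
        if np.nanmax(np.abs(self.pcc)) > 1 + 1e-12:
            raise ValueError("pcc values outside [-1, 1]")


@dataclass
class MutualRankMatrix:
    """Symmetric mutual-rank matrix; the diagonal stores a 0 sentinel."""

    gene_ids: list[str]
    mr: np.ndarray


@dataclass
class CoexpressionNetwork:
    """Undirected thresholded network; edges carry pcc and mutual_rank."""

    graph: nx.Graph
    mr_max: float | None
    pcc_min: float | None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class CoexpressedRegionReport:
    """Co-expression evidence for one candidate region.

    ``n_members_in_largest_component`` counts region members inside the
    single network component holding the most of them;
    ``mean_mr_within`` averages MR over edges between region members (0
    when no such edge exists). ``qualifies`` flags regions with at least
    ``min_coexpressed_members`` members co-located in one component.
    """

    region_id: str
    n_members: int
    n_members_in_network: int
    n_members_in_largest_component: int
    mean_mr_within: float
    qualifies: bool


def preprocess_expression(
    matrix: ExpressionMatrix,
    min_expressed_samples: int = DEFAULT_MIN_EXPRESSED_SAMPLES,
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
) -> ExpressionMatrix:
    """log2(value + pseudo_count) transform with low-information filtering.

    Genes expressed (> 0) in fewer than ``min_expressed_samples`` samples
    are dropped, as are zero-variance genes (with a logged warning).
    Correlation over fewer than 3 samples is meaningless and is an error.
    """
    if matrix.shape[1] < 3:
        raise ValueError(
            f"need >= 3 samples for correlation, got {matrix.shape[1]}"
        )
    raw = matrix.values
    if (raw < 0).any():
        raise ValueError("raw expression values must be non-negative")
    expressed = (raw > 0).sum(axis=1) >= min_expressed_samples
    transformed = np.log2(raw + pseudo_count)
    variable = transformed.std(axis=1) > 0
    n_const = int((expressed & ~variable).sum())
    if n_const:
        logger.warning("dropping %d zero-variance genes", n_const)
    keep = expressed & variable
    return ExpressionMatrix(data=matrix.data.loc[keep].apply(
        lambda col: np.log2(col + pseudo_count)
    ))


def pcc_matrix(matrix: ExpressionMatrix) -> CorrelationMatrix:
    """Pearson product-moment correlation between all gene pairs."""
    vals = matrix.values
    if vals.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    if (vals.std(axis=1) == 0).any():
        bad = [g for g, s in zip(matrix.gene_ids, vals.std(axis=1)) if s == 0]
        raise ValueError(f"zero-variance genes reached correlation: {bad[:5]}")
    pcc = np.corrcoef(vals)
    pcc = np.clip((pcc + pcc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(pcc, 1.0)
    return CorrelationMatrix(gene_ids=matrix.gene_ids, pcc=pcc)


def mutual_rank(corr: CorrelationMatrix) -> MutualRankMatrix:
    """Mutual rank MR(i,j) = sqrt(rank_i(j) * rank_j(i)).

    For each gene i its partners j != i are ranked by descending pcc(i,j),
    best rank 1; ties receive the average (fractional) rank. MR lies in
    [1, n-1] off the diagonal; the diagonal holds a 0 sentinel.
    """
    n = len(corr.gene_ids)
    if n < 3:
        raise ValueError("need >= 3 genes for mutual ranking")
    ranks = np.zeros((n, n))
    idx = np.arange(n)
    for i in range(n):
        partners = idx != i
        ranks[i, partners] = rankdata(-corr.pcc[i, partners], method="average")
    mr = np.sqrt(ranks * ranks.T)
    np.fill_diagonal(mr, 0.0)
    return MutualRankMatrix(gene_ids=corr.gene_ids, mr=mr)


def build_network(
    corr: CorrelationMatrix,
    mr: MutualRankMatrix,
    mr_max: float | None = DEFAULT_MR_MAX,
    pcc_min: float | None = None,
) -> CoexpressionNetwork:
    """Threshold the MR/pcc matrices into an undirected network.

    An edge (i, j) is kept iff MR(i,j) <= mr_max (when enabled) AND
    pcc(i,j) >= pcc_min (when enabled); at least one rule must be enabled.
    Every gene is a node, so unconnected genes appear as isolates.
    """
    if corr.gene_ids != mr.gene_ids:
        raise ValueError("correlation and mutual-rank matrices disagree on gene_ids")
    if mr_max is None and pcc_min is None:
        raise ValueError("at least one of mr_max / pcc_min must be enabled")
    if mr_max is not None and mr_max < 0:
        raise ValueError("mr_max must be >= 0")
    g = nx.Graph(mr_max=mr_max, pcc_min=pcc_min)
    g.add_nodes_from(corr.gene_ids)
    ids = corr.gene_ids
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if mr_max is not None and mr.mr[i, j] > mr_max:
                continue
            if pcc_min is not None and corr.pcc[i, j] < pcc_min:
                continue
            g.add_edge(ids[i], ids[j],
                       pcc=float(corr.pcc[i, j]),
                       mutual_rank=float(mr.mr[i, j]))
    return CoexpressionNetwork(graph=g, mr_max=mr_max, pcc_min=pcc_min)


def extract_coexpressed_regions(
    network: CoexpressionNetwork,
    regions: list[NeighborhoodRegion],
    min_coexpressed_members: int = DEFAULT_MIN_COEXPRESSED_MEMBERS,
) -> list[CoexpressedRegionReport]:
    """Score candidate regions against the network's connected components.

    Region members absent from the network node set count as
    not-in-network (no error: real expression matrices are incomplete).
    Reports are sorted by (qualifies desc, mean_mr_within asc, region_id).
    """
    if min_coexpressed_members < 2:
        raise ValueError("min_coexpressed_members must be >= 2")
    g = network.graph
    component_of: dict[str, int] = {}
    for ci, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            component_of[node] = ci

    reports: list[CoexpressedRegionReport] = []
    for region in regions:
        in_net = [m for m in region.members if m in component_of]
        counts: dict[int, int] = {}
        for m in in_net:
            counts[component_of[m]] = counts.get(component_of[m], 0) + 1
        largest = max(counts.values(), default=0)
        within = [
            g.edges[a, b]["mutual_rank"]
            for k, a in enumerate(region.members)
            for b in region.members[k + 1:]
            if g.has_edge(a, b)
        ]
        reports.append(CoexpressedRegionReport(
            region_id=region.region_id,
            n_members=region.n_members,
            n_members_in_network=len(in_net),
            n_members_in_largest_component=largest,
            mean_mr_within=float(np.mean(within)) if within else 0.0,
            qualifies=largest >= min_coexpressed_members,
        ))
    reports.sort(key=lambda r: (not r.qualifies, r.mean_mr_within, r.region_id))
    return reports


# ---------------------------------------------------------------------------
# Exports

def write_edge_list(network: CoexpressionNetwork, path) -> None:
    """Edge-list TSV (gene_a, gene_b, pcc, mutual_rank), a < b, sorted."""
    rows = sorted(
        (min(a, b), max(a, b), d["pcc"], d["mutual_rank"])
        for a, b, d in network.graph.edges(data=True)
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_a", "gene_b", "pcc", "mutual_rank"])
        for a, b, pcc, mr in rows:
            writer.writerow([a, b, f"{pcc:.6f}", f"{mr:.4f}"])


def write_graphml(network: CoexpressionNetwork, path) -> None:
    g = network.graph.copy()
    # GraphML attributes may not be None
    g.graph["mr_max"] = -1.0 if network.mr_max is None else float(network.mr_max)
    g.graph["pcc_min"] = -2.0 if network.pcc_min is None else float(network.pcc_min)
    nx.write_graphml(g, path)


def write_region_reports(reports: list[CoexpressedRegionReport], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([
            "region_id", "n_members", "n_members_in_network",
            "n_members_in_largest_component", "mean_mr_within", "qualifies",
        ])
        for r in reports:
            writer.writerow([
                r.region_id, r.n_members, r.n_members_in_network,
                r.n_members_in_largest_component, f"{r.mean_mr_within:.4f}",
                str(r.qualifies).lower(),
            ])
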
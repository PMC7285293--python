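"""Synthetic genomes and expression matrices with planted ground truth.

The generator emulates the two inputs of the neighboring-gene screen:

* a genome annotation whose chromosomes carry planted multi-family
  clusters and single-family tandem arrays among background genes, placed
  so that the planted truth is recoverable at the default detector
  settings (every planted region is separated from any other family gene
  by more than the default chaining gap), and
* an expression matrix in which each co-regulated planted region shares a
  one-factor latent signal: on the log2 scale, member value =
  baseline_g + b * f_s + noise with f_s ~ N(0,1) per sample, so the
  expected within-region correlation is b^2 / (b^2 + sigma^2).

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .genome_io import (
    DEFAULT_FAMILIES,
    ExpressionMatrix,
    FamilyCatalog,
    GeneModel,
)
from .neighborhood import (
    DEFAULT_MAX_GAP_BP,
    MULTI_FAMILY_CLUSTER,
    SINGLE_FAMILY_TANDEM,
    NeighborhoodRegion,
    classify_region,
    read_region_table,
    write_region_table,
)

#: Product strings emitted for each family; each matches the corresponding
#: default keyword rule, so keyword assignment recovers the ground truth.
FAMILY_PRODUCTS: dict[str, str] = {
    "P450": "cytochrome P450 family protein",
    "2ODD": "2-oxoglutarate-dependent dioxygenase",
    "TPS": "terpene synthase",
    "PKS": "polyketide synthase",
    "UGT": "UDP-glycosyltransferase",
}

BACKGROUND_PRODUCT = "hypothetical protein"

#: Isolation margin around planted regions and between labelled background
#: genes; exceeds the default detector max_gap_bp so chains cannot cross it.
ISOLATION_BP = DEFAULT_MAX_GAP_BP + 10_000

GENE_LEN_RANGE = (1_000, 3_000)


@dataclass(frozen=True)
class PlantedRegionSpec:
    """One planted region: member families in genomic order.

    ``families`` has one label per member (>= 3 members); a tandem array
    repeats one label, a cluster mixes at least two. ``coregulated`` marks
    regions that share a latent expression factor.
    """

    category: str
    families: tuple[str, ...]
    intra_gap_bp: int = 1_500
    coregulated: bool = False

    def __post_init__(self) -> None:
        if self.category not in (MULTI_FAMILY_CLUSTER, SINGLE_FAMILY_TANDEM):
            raise ValueError(f"unknown category {self.category!r}")
        if len(self.families) < 3:
            raise ValueError("planted regions need >= 3 members")
        distinct = len(set(self.families))
        if self.category == SINGLE_FAMILY_TANDEM and distinct != 1:
            raise ValueError("tandem arrays must repeat a single family")
        if self.category == MULTI_FAMILY_CLUSTER and distinct < 2:
            raise ValueError("clusters need >= 2 distinct families")
        if self.intra_gap_bp <= 0:
            raise ValueError("intra_gap_bp must be > 0")


@dataclass
class SyntheticGenomeSpec:
    """Layout of a synthetic annotated genome."""

    n_chromosomes: int = 3
    chrom_length: int = 1_200_000
    n_background_genes: int = 200
    background_family_rate: float = 0.10
    planted: tuple[PlantedRegionSpec, ...] = ()
    min_intergenic: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_family_rate <= 1:
            raise ValueError("background_family_rate must be in [0, 1]")
        if min(self.n_chromosomes, self.chrom_length, self.n_background_genes,
               self.min_intergenic) < 0:
            raise ValueError("all counts must be >= 0")


@dataclass
class SyntheticExpressionSpec:
    """One-factor latent co-regulation model for expression simulation.

    ``module_loading`` (b) and ``noise_sd`` (sigma) set the expected
    within-module Pearson correlation b^2/(b^2 + sigma^2); the defaults
    (b=2, sigma=1) emulate the strong co-regulation of characterized
    biosynthetic clusters (expected r = 0.8). Baselines are per-gene log2
    means.
    """

    n_samples: int = 50
    module_loading: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    pseudo_count: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


class SyntheticGenome(NamedTuple):
    """Generator output: annotation, family truth, region truth."""

    genes: list[GeneModel]
    catalog: FamilyCatalog
    truth: list[NeighborhoodRegion]
    coregulated_ids: frozenset[str]


def default_genome_spec(seed: int = 0) -> SyntheticGenomeSpec:
    """The default study conditions: five planted regions among 200
    background genes — two co-regulated clusters (one thalianol-style
    TPS/P450/UGT composition), one non-co-regulated cluster, and two
    tandem arrays."""
    return SyntheticGenomeSpec(
        planted=(
            PlantedRegionSpec(MULTI_FAMILY_CLUSTER, ("TPS", "P450", "P450", "UGT"),
                              coregulated=True),
            PlantedRegionSpec(MULTI_FAMILY_CLUSTER, ("P450", "2ODD", "UGT"),
                              coregulated=True),
            PlantedRegionSpec(MULTI_FAMILY_CLUSTER, ("PKS", "P450", "P450")),
            PlantedRegionSpec(SINGLE_FAMILY_TANDEM, ("UGT",) * 4),
            PlantedRegionSpec(SINGLE_FAMILY_TANDEM, ("P450",) * 3),
        ),
        seed=seed,
    )


def simulate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Generate an annotation, family catalog and planted-region truth.

    Planted regions are centred in exclusion blocks padded by
    ``ISOLATION_BP`` on both sides; background genes fall only outside the
    blocks, and background family labels are thinned so no two labelled
    background genes (or a labelled gene and a planted region) are within
    chaining distance of each other. Raises if the planted regions cannot
    fit on the chromosomes.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    if spec.planted and spec.n_chromosomes == 0:
        raise ValueError("cannot plant regions on zero chromosomes")

    per_chrom: dict[str, list[tuple[int, PlantedRegionSpec]]] = {
        c: [] for c in chrom_names
    }
    for i, pspec in enumerate(spec.planted):
        per_chrom[chrom_names[i % spec.n_chromosomes]].append((i, pspec))

    genes_by_chrom: dict[str, list[tuple[int, int, str | None, bool]]] = {}
    truth_layout: list[tuple[str, int, list[int]]] = []  # chrom, planted idx, slot idxs

    for chrom in chrom_names:
        specs = per_chrom[chrom]
        entries: list[tuple[int, int, str | None, bool]] = []  # start, end, family, planted
        blocks: list[tuple[int, int]] = []
        # planted blocks at evenly spaced anchors
        spans = []
        for _, pspec in specs:
            lens = rng.integers(*GENE_LEN_RANGE, size=len(pspec.families))
            span = int(lens.sum() + (len(pspec.families) - 1) * pspec.intra_gap_bp)
            spans.append((lens, span))
        for k, ((orig_idx, pspec), (lens, span)) in enumerate(zip(specs, spans)):
            block_len = span + 2 * ISOLATION_BP
            anchor = (k + 1) * spec.chrom_length // (len(specs) + 1)
            b_start = anchor - block_len // 2
            if b_start < 1 or b_start + block_len > spec.chrom_length:
                raise ValueError(
                    f"planted region does not fit on {chrom} "
                    f"(chrom_length={spec.chrom_length}, block={block_len})"
                )
            if blocks and b_start <= blocks[-1][1]:
                raise ValueError(f"planted blocks overlap on {chrom}")
            blocks.append((b_start, b_start + block_len))
            pos = b_start + ISOLATION_BP
            slot_idxs = []
            for fam, length in zip(pspec.families, lens):
                entries.append((pos, pos + int(length) - 1, fam, True))
                slot_idxs.append(len(entries) - 1)
                pos += int(length) + pspec.intra_gap_bp
            truth_layout.append((chrom, orig_idx, slot_idxs))
        genes_by_chrom[chrom] = entries
        # record blocks for background placement below
        per_chrom[chrom] = blocks  # type: ignore[assignment]

    # distribute background genes across chromosomes proportional to free space
    free_intervals: dict[str, list[tuple[int, int]]] = {}
    free_len: dict[str, int] = {}
    for chrom in chrom_names:
        blocks = sorted(per_chrom[chrom])  # type: ignore[arg-type]
        ivs, cursor = [], 1
        for b_start, b_end in blocks:
            if b_start - cursor > 0:
                ivs.append((cursor, b_start - 1))
            cursor = b_end + 1
        if spec.chrom_length - cursor > 0:
            ivs.append((cursor, spec.chrom_length))
        free_intervals[chrom] = ivs
        free_len[chrom] = sum(e - s + 1 for s, e in ivs)

    total_free = sum(free_len.values())
    if spec.n_background_genes and total_free == 0:
        raise ValueError("no free space left for background genes")
    if spec.n_background_genes:
        probs = np.array([free_len[c] for c in chrom_names], dtype=float)
        counts = rng.multinomial(spec.n_background_genes, probs / probs.sum())
    else:
        counts = np.zeros(len(chrom_names), dtype=int)

    for chrom, n_bg in zip(chrom_names, counts):
        placed = _place_background(
            rng, free_intervals[chrom], int(n_bg), spec.min_intergenic
        )
        genes_by_chrom[chrom].extend((s, e, None, False) for s, e in placed)

    # assign IDs in genomic order; label background genes with isolation thinning
    all_genes: list[GeneModel] = []
    assignments: dict[str, str] = {}
    id_by_slot: dict[tuple[str, int], str] = {}
    for chrom in chrom_names:
        entries = genes_by_chrom[chrom]
        order = sorted(range(len(entries)), key=lambda k: (entries[k][0], entries[k][1]))
        last_labeled_end: int | None = None
        for rank, slot in enumerate(order, start=1):
            start, end, fam, is_planted = entries[slot]
            gene_id = f"{chrom}_g{rank:04d}"
            id_by_slot[(chrom, slot)] = gene_id
            if is_planted:
                label = fam
                last_labeled_end = end
            else:
                label = None
                if fam is None and rng.random() < spec.background_family_rate:
                    isolated = (
                        last_labeled_end is None
                        or start - last_labeled_end > ISOLATION_BP
                    )
                    if isolated:
                        label = str(rng.choice(DEFAULT_FAMILIES))
                        last_labeled_end = end
            strand = "+" if rng.random() < 0.5 else "-"
            product = FAMILY_PRODUCTS[label] if label else BACKGROUND_PRODUCT
            all_genes.append(GeneModel(gene_id, chrom, start, end, strand, product))
            if label:
                assignments[gene_id] = label

    truth: list[NeighborhoodRegion] = []
    coregulated: set[str] = set()
    for chrom, pidx, slots in sorted(truth_layout, key=lambda t: t[1]):
        pspec = spec.planted[pidx]
        members = tuple(id_by_slot[(chrom, s)] for s in slots)
        starts = [genes_by_chrom[chrom][s][0] for s in slots]
        ends = [genes_by_chrom[chrom][s][1] for s in slots]
        region = classify_region(NeighborhoodRegion(
            region_id=f"truth_{pidx + 1:04d}",
            chrom=chrom,
            span_start=min(starts),
            span_end=max(ends),
            members=members,
            families=pspec.families,
        ))
        truth.append(region)
        if pspec.coregulated:
            coregulated.add(region.region_id)

    all_genes.sort(key=GeneModel.sort_key)
    return SyntheticGenome(
        genes=all_genes,
        catalog=FamilyCatalog(assignments=assignments),
        truth=truth,
        coregulated_ids=frozenset(coregulated),
    )


def _place_background(
    rng: np.random.Generator,
    intervals: list[tuple[int, int]],
    n: int,
    min_intergenic: int,
) -> list[tuple[int, int]]:
    """Place n genes uniformly in the free intervals with spacing.

    Within an interval, k genes of total length L_g with minimum
    intergenic distance m need L_g + (k-1)*m bp of the interval; sorted
    uniform offsets over the leftover slack give an exact
    spacing-respecting placement.
    """
    if n == 0 or not intervals:
        return []
    lens = rng.integers(*GENE_LEN_RANGE, size=n)
    weights = np.array([e - s + 1 for s, e in intervals], dtype=float)
    for _ in range(100):
        counts = rng.multinomial(n, weights / weights.sum())
        placed: list[tuple[int, int]] = []
        cursor = 0
        feasible = True
        for (iv_start, iv_end), k in zip(intervals, counts):
            if k == 0:
                continue
            seg = lens[cursor:cursor + k]
            cursor += k
            need = int(seg.sum()) + (k - 1) * min_intergenic
            room = iv_end - iv_start + 1 - need
            if room < 0:
                feasible = False
                break
            offsets = np.sort(rng.integers(0, room + 1, size=k))
            for gi in range(k):
                start = (iv_start + int(offsets[gi]) + int(seg[:gi].sum())
                         + gi * min_intergenic)
                placed.append((start, start + int(seg[gi]) - 1))
        if feasible:
            return placed
    raise ValueError("could not place background genes; spec infeasible")


def simulate_expression(
    spec: SyntheticExpressionSpec,
    genes: list[GeneModel],
    truth: list[NeighborhoodRegion],
    coregulated_ids: frozenset[str] | None = None,
) -> ExpressionMatrix:
    """Simulate a raw-scale gene x sample expression matrix.

    Members of each co-regulated truth region share a per-sample latent
    factor f_s ~ N(0,1) scaled by the module loading b; every gene gets an
    independent N(0, sigma^2) noise term on top of its log2 baseline. The
    matrix is exported on the raw scale as 2^value - pseudo_count, clipped
    at 0, so the log2(x + pseudo_count) preprocessing recovers the latent
    values exactly wherever no clipping occurred.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [g.gene_id for g in genes]
    index = {gid: i for i, gid in enumerate(gene_ids)}
    n_genes, n_samples = len(gene_ids), spec.n_samples

    baselines = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n_genes)
    log_vals = baselines[:, None] + rng.normal(0.0, spec.noise_sd, size=(n_genes, n_samples))

    active = truth if coregulated_ids is None else [
        r for r in truth if r.region_id in coregulated_ids
    ]
    for region in active:
        factor = rng.normal(0.0, 1.0, size=n_samples)
        for gid in region.members:
            if gid in index:
                log_vals[index[gid]] += spec.module_loading * factor

    raw = np.clip(np.exp2(log_vals) - spec.pseudo_count, 0.0, None)
    data = pd.DataFrame(
        raw,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"S{j + 1:03d}" for j in range(n_samples)],
    )
    return ExpressionMatrix(data=data)


def write_ground_truth(
    truth: list[NeighborhoodRegion],
    path,
    coregulated_ids: frozenset[str] = frozenset(),
) -> None:
    """Write truth regions with the region-report schema.

    A trailing ``coregulated`` column records the expression ground truth;
    the standard region reader ignores it, so match_regions round-trips.
    """
    write_region_table(truth, path)
    # append coregulated column by rewriting
    import csv

    with open(path, encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    rows[0].append("coregulated")
    for row in rows[1:]:
        row.append(str(row[0] in coregulated_ids).lower())
    with open(path, "w", encoding="utf-8", newline="") as fh:
        csv.writer(fh, delimiter="\t", lineterminator="\n").writerows(rows)


def read_ground_truth(path) -> tuple[list[NeighborhoodRegion], frozenset[str]]:
    """Read truth regions and the co-regulated region-ID set back."""
    import csv

    regions = read_region_table(path)
    coreg: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if row.get("coregulated") == "true":
                coreg.add(row["region_id"])
    return regions, frozenset(coreg)
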
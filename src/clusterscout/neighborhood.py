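"""Detection and classification of neighboring-gene regions.

A region is a maximal run of proximal family-labelled genes on one
chromosome. Two consecutive family genes are chained when at most
``max_intervening`` unassigned genes lie between them and the genomic gap
from the end of the earlier to the start of the later is at most
``max_gap_bp``. Runs with at least ``min_genes`` members are emitted and
classified as multi-family cluster candidates (two or more distinct
families; a strict flag records three or more, the classical biosynthetic
gene cluster definition) or single-family tandem-duplication arrays — the
genomic substrate for neo-functionalization.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field, replace

from .genome_io import DEFAULT_FAMILIES, FamilyCatalog, GeneModel

logger = logging.getLogger(__name__)

MULTI_FAMILY_CLUSTER = "multi_family_cluster"
SINGLE_FAMILY_TANDEM = "single_family_tandem"

DEFAULT_MAX_INTERVENING = 3
DEFAULT_MAX_GAP_BP = 50_000
DEFAULT_MIN_GENES = 3
DEFAULT_MIN_DISTINCT_FAMILIES = 2


@dataclass(frozen=True)
class NeighborhoodRegion:
    """A detected run of >= min_genes proximal family genes.

    ``members`` are ordered by genomic start; ``families`` holds one label
    per member in the same order. The span covers every member interval
    (1-based inclusive). ``strict_cluster`` is True when the region holds
    at least three distinct families.
    """

    region_id: str
    chrom: str
    span_start: int
    span_end: int
    members: tuple[str, ...]
    families: tuple[str, ...]
    category: str = ""
    strict_cluster: bool = False
    dominant_family: str | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def distinct_families(self) -> frozenset[str]:
        return frozenset(self.families)

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass
class SurveySummary:
    """Per-run counts of detected region categories.

    The additivity invariant ``n_total_regions == n_cluster_regions +
    sum(n_tandem_by_family.values())`` holds by construction.
    """

    label: str
    n_cluster_regions: int = 0
    n_tandem_by_family: dict[str, int] = field(default_factory=dict)

    @property
    def n_tandem_regions(self) -> int:
        return sum(self.n_tandem_by_family.values())

    @property
    def n_total_regions(self) -> int:
        return self.n_cluster_regions + self.n_tandem_regions

    def as_row(self, families: tuple[str, ...] = DEFAULT_FAMILIES) -> dict:
        row = {"label": self.label, "n_cluster_regions": self.n_cluster_regions}
        for fam in families:
            row[f"n_tandem_{fam}"] = self.n_tandem_by_family.get(fam, 0)
        row["n_tandem_regions"] = self.n_tandem_regions
        row["n_total_regions"] = self.n_total_regions
        return row


def classify_region(
    region: NeighborhoodRegion,
    min_distinct_families: int = DEFAULT_MIN_DISTINCT_FAMILIES,
) -> NeighborhoodRegion:
    """Assign the cluster/tandem category to a region.

    multi_family_cluster when the region holds at least
    ``min_distinct_families`` distinct labels, otherwise
    single_family_tandem with ``dominant_family`` set. ``strict_cluster``
    additionally records whether three or more distinct families are
    present.
    """
    if min_distinct_families < 2:
        raise ValueError("min_distinct_families must be >= 2")
    distinct = region.distinct_families
    if len(distinct) >= min_distinct_families:
        return replace(
            region,
            category=MULTI_FAMILY_CLUSTER,
            strict_cluster=len(distinct) >= 3,
            dominant_family=None,
        )
    dominant = Counter(region.families).most_common(1)[0][0]
    return replace(
        region,
        category=SINGLE_FAMILY_TANDEM,
        strict_cluster=False,
        dominant_family=dominant,
    )


def detect_neighborhoods(
    genes: list[GeneModel],
    catalog: FamilyCatalog,
    max_intervening: int = DEFAULT_MAX_INTERVENING,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
    min_genes: int = DEFAULT_MIN_GENES,
    min_distinct_families: int = DEFAULT_MIN_DISTINCT_FAMILIES,
    region_id_prefix: str = "region",
) -> list[NeighborhoodRegion]:
    """Chain proximal family genes per chromosome into maximal regions.

    Genes are pre-sorted by (chrom, start, end, gene_id) so the result is
    invariant to input order. Two consecutive family genes join one chain
    iff the number of genes between them (in sorted order; necessarily
    unassigned) is at most ``max_intervening`` AND the distance from the
    end of the earlier to the start of the later is at most ``max_gap_bp``
    (overlapping genes count as distance 0). Maximal chains with at least
    ``min_genes`` members are emitted, already classified.
    """
    if max_intervening < 0:
        raise ValueError("max_intervening must be >= 0")
    if max_gap_bp <= 0:
        raise ValueError("max_gap_bp must be > 0")
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")

    annotated_ids = {g.gene_id for g in genes}
    orphans = set(catalog.assignments) - annotated_ids
    if orphans:
        logger.warning(
            "%d catalog genes absent from the annotation (ignored), e.g. %s",
            len(orphans), sorted(orphans)[:3],
        )

    ordered = sorted(genes, key=GeneModel.sort_key)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in ordered:
        by_chrom.setdefault(g.chrom, []).append(g)

    raw_regions: list[tuple[str, list[GeneModel]]] = []
    for chrom in sorted(by_chrom):
        cg = by_chrom[chrom]
        fam_pos = [k for k, g in enumerate(cg) if g.gene_id in catalog]
        chain: list[int] = []
        for k in fam_pos:
            if chain and not _joinable(cg, chain[-1], k, max_intervening, max_gap_bp):
                if len(chain) >= min_genes:
                    raw_regions.append((chrom, [cg[i] for i in chain]))
                chain = []
            chain.append(k)
        if len(chain) >= min_genes:
            raw_regions.append((chrom, [cg[i] for i in chain]))

    regions: list[NeighborhoodRegion] = []
    width = max(4, len(str(len(raw_regions))))
    for idx, (chrom, members) in enumerate(raw_regions, start=1):
        region = NeighborhoodRegion(
            region_id=f"{region_id_prefix}_{idx:0{width}d}",
            chrom=chrom,
            span_start=min(g.start for g in members),
            span_end=max(g.end for g in members),
            members=tuple(g.gene_id for g in members),
            families=tuple(catalog.get(g.gene_id) for g in members),
        )
        regions.append(classify_region(region, min_distinct_families))
    return regions


def _joinable(
    chrom_genes: list[GeneModel],
    i: int,
    j: int,
    max_intervening: int,
    max_gap_bp: int,
) -> bool:
    """Chain predicate between family genes at sorted positions i < j."""
    intervening = j - i - 1
    gap = max(0, chrom_genes[j].start - chrom_genes[i].end)
    return intervening <= max_intervening and gap <= max_gap_bp


def summarize_survey(
    regions: list[NeighborhoodRegion],
    label: str,
    families: tuple[str, ...] = DEFAULT_FAMILIES,
) -> SurveySummary:
    """Aggregate classified regions into per-category survey counts."""
    n_cluster = 0
    tandems: dict[str, int] = {fam: 0 for fam in families}
    for r in regions:
        if r.category == MULTI_FAMILY_CLUSTER:
            n_cluster += 1
        elif r.category == SINGLE_FAMILY_TANDEM:
            tandems[r.dominant_family] = tandems.get(r.dominant_family, 0) + 1
        else:
            raise ValueError(f"region {r.region_id} is unclassified")
    return SurveySummary(
        label=label,
        n_cluster_regions=n_cluster,
        n_tandem_by_family={f: n for f, n in tandems.items() if n},
    )


def match_regions(
    detected: list[NeighborhoodRegion],
    truth: list[NeighborhoodRegion],
    min_jaccard: float = 0.5,
) -> tuple[float, float]:
    """Precision/recall of detected regions against a ground-truth set.

    A detected region matches a truth region when the Jaccard index of
    their member gene-ID sets is at least ``min_jaccard``; matching is
    greedy one-to-one in descending Jaccard order. Empty truth and empty
    detected both score 1.0 by convention (vacuous success).
    """
    if not 0 < min_jaccard <= 1:
        raise ValueError("min_jaccard must be in (0, 1]")
    pairs: list[tuple[float, int, int]] = []
    for di, d in enumerate(detected):
        for ti, t in enumerate(truth):
            inter = len(d.member_set & t.member_set)
            if inter == 0:
                continue
            jac = inter / len(d.member_set | t.member_set)
            if jac >= min_jaccard:
                pairs.append((jac, di, ti))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_d: set[int] = set()
    used_t: set[int] = set()
    for jac, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
    precision = len(used_d) / len(detected) if detected else 1.0
    recall = len(used_t) / len(truth) if truth else 1.0
    return precision, recall


# ---------------------------------------------------------------------------
# Region reports

REGION_TSV_COLUMNS = (
    "region_id", "chrom", "span_start", "span_end", "n_members",
    "n_distinct_families", "category", "strict_cluster", "dominant_family",
    "member_ids", "member_families",
)


def write_region_table(regions: list[NeighborhoodRegion], path) -> None:
    """Write regions as the canonical tab-separated region report."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REGION_TSV_COLUMNS)
        for r in regions:
            writer.writerow([
                r.region_id, r.chrom, r.span_start, r.span_end, r.n_members,
                len(r.distinct_families), r.category, str(r.strict_cluster).lower(),
                r.dominant_family or ".",
                ",".join(r.members), ",".join(r.families),
            ])


def read_region_table(path) -> list[NeighborhoodRegion]:
    regions: list[NeighborhoodRegion] = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            regions.append(NeighborhoodRegion(
                region_id=row["region_id"],
                chrom=row["chrom"],
                span_start=int(row["span_start"]),
                span_end=int(row["span_end"]),
                members=tuple(row["member_ids"].split(",")),
                families=tuple(row["member_families"].split(",")),
                category=row["category"],
                strict_cluster=row["strict_cluster"] == "true",
                dominant_family=None if row["dominant_family"] == "." else row["dominant_family"],
            ))
    return regions


def write_region_bed(regions: list[NeighborhoodRegion], path) -> None:
    """BED6 export: 0-based half-open spans, score = member count."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.span_start - 1}\t{r.span_end}\t{r.region_id}"
                f"\t{r.n_members}\t.\n"
            )
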
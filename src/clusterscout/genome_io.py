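"""Readers and writers for the formats the pipeline touches.

Covers GFF3 gene annotations, two-column gene-family tables, tab-separated
expression matrices, and keyword-based family assignment from annotation
product descriptions. Coordinates are kept 1-based inclusive (the GFF3
convention) on every public type; interval arithmetic elsewhere converts
internally.
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

#: The five signature enzyme families of plant specialized metabolism used by
#: the genomic survey: cytochrome P450s, 2-oxoglutarate-dependent
#: dioxygenases, terpene synthases, polyketide synthases and UDP-sugar
#: dependent glycosyltransferases (family 1).
DEFAULT_FAMILIES: tuple[str, ...] = ("P450", "2ODD", "TPS", "PKS", "UGT")

#: Case-insensitive substring rules mapping annotation product text to a
#: family label. First matching rule (in order) wins.
DEFAULT_KEYWORD_RULES: tuple[tuple[str, str], ...] = (
    ("cytochrome P450", "P450"),
    ("2-oxoglutarate", "2ODD"),
    ("dioxygenase", "2ODD"),
    ("terpene synthase", "TPS"),
    ("polyketide synthase", "PKS"),
    ("chalcone synthase", "PKS"),
    ("UDP-glycosyltransferase", "UGT"),
    ("UDP-glucosyltransferase", "UGT"),
)

STRANDS = ("+", "-", ".")


class GFF3ParseError(ValueError):
    """Raised for malformed GFF3 input; message names the offending line."""


@dataclass(frozen=True, order=True)
class GeneModel:
    """One annotated gene.

    Coordinates are 1-based inclusive base pairs, as in GFF3.
    ``product`` is the free-text description used for keyword family
    assignment; it may be empty. Strand is parsed and carried but plays no
    role in neighborhood detection (plant clusters mix orientations).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def sort_key(self) -> tuple[str, int, int, str]:
        # equal starts break ties by (end, gene_id) for determinism
        return (self.chrom, self.start, self.end, self.gene_id)


@dataclass
class FamilyCatalog:
    """Assignment of gene IDs to signature enzyme families.

    Each gene carries at most one label, and every label must belong to the
    recognized family set (``DEFAULT_FAMILIES`` unless extended).
    """

    assignments: dict[str, str] = field(default_factory=dict)
    families: tuple[str, ...] = DEFAULT_FAMILIES

    def __post_init__(self) -> None:
        bad = {v for v in self.assignments.values()} - set(self.families)
        if bad:
            raise ValueError(
                f"unknown family labels {sorted(bad)}; allowed: {list(self.families)}"
            )

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)

    def get(self, gene_id: str) -> str | None:
        return self.assignments.get(gene_id)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values backed by a pandas DataFrame.

    Rows are genes, columns samples. Raw input values are non-negative;
    after preprocessing they are log2-transformed.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path, feature_type: str = "gene") -> list[GeneModel]:
    """Read gene features from a GFF3 file.

    Only rows whose type column equals ``feature_type`` become GeneModels;
    mRNA/CDS/exon rows are ignored (the survey counts genes, not
    transcripts). Comment and directive lines are skipped. Raises
    :class:`GFF3ParseError` for lines with the wrong column count, an
    invalid interval, a missing ID attribute, or a duplicate gene ID.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFF3ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            if cols[2] != feature_type:
                continue
            feat = feature_from_line(line)
            if feat.start is None or feat.end is None:
                raise GFF3ParseError(f"{path}: line {lineno}: non-numeric coordinates")
            ids = feat.attributes.get("ID", [])
            if not ids:
                raise GFF3ParseError(f"{path}: line {lineno}: missing ID attribute")
            gene_id = ids[0]
            if gene_id in seen:
                raise GFF3ParseError(f"{path}: line {lineno}: duplicate ID {gene_id!r}")
            if feat.end < feat.start:
                raise GFF3ParseError(
                    f"{path}: line {lineno}: end < start for {gene_id!r}"
                )
            seen.add(gene_id)
            product = feat.attributes.get("product", [""])
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand if feat.strand in STRANDS else ".",
                    product=product[0] if product else "",
                )
            )
    return genes


def write_gff3(genes: list[GeneModel], path, feature_type: str = "gene") -> None:
    """Write GeneModels as GFF3, losslessly round-trippable by read_gff3."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={_attr_quote(g.gene_id)}"
            if g.product:
                attrs += f";product={_attr_quote(g.product)}"
            fh.write(
                f"{g.chrom}\tclusterscout\t{feature_type}\t{g.start}\t{g.end}"
                f"\t.\t{g.strand}\t.\t{attrs}\n"
            )


def _attr_quote(text: str) -> str:
    # GFF3 reserves ; = & , and % inside attribute values
    return urllib.parse.quote(text, safe=" .:_()-/[]|")


# ---------------------------------------------------------------------------
# Family tables and keyword assignment

def read_family_table(path, families: tuple[str, ...] = DEFAULT_FAMILIES) -> FamilyCatalog:
    """Read a two-column tab-separated gene_id / family-label table.

    A header line is tolerated (detected by a second column that is not a
    recognized family label on the first line). Duplicate gene IDs with
    conflicting labels are an error, as are unrecognized labels.
    """
    assignments: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns"
                )
            gene_id, label = cols[0].strip(), cols[1].strip()
            if lineno == 1 and label not in families:
                continue  # header line
            if label not in families:
                raise ValueError(
                    f"{path}: line {lineno}: unknown family {label!r}; "
                    f"allowed: {list(families)}"
                )
            if gene_id in assignments and assignments[gene_id] != label:
                raise ValueError(
                    f"{path}: line {lineno}: gene {gene_id!r} assigned to both "
                    f"{assignments[gene_id]!r} and {label!r}"
                )
            assignments[gene_id] = label
    return FamilyCatalog(assignments=assignments, families=families)


def write_family_table(catalog: FamilyCatalog, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tfamily\n")
        for gene_id, label in sorted(catalog.assignments.items()):
            fh.write(f"{gene_id}\t{label}\n")


def assign_families_by_keyword(
    genes: list[GeneModel],
    rules: tuple[tuple[str, str], ...] = DEFAULT_KEYWORD_RULES,
    families: tuple[str, ...] = DEFAULT_FAMILIES,
) -> FamilyCatalog:
    """Assign families by case-insensitive substring search on product text.

    The first matching rule in rule order wins; genes with no match stay
    unassigned. Idempotent and independent of gene order.
    """
    if not rules:
        raise ValueError("keyword rule list must be non-empty")
    lowered = [(kw.lower(), fam) for kw, fam in rules]
    assignments: dict[str, str] = {}
    for g in genes:
        product = g.product.lower()
        if not product:
            continue
        for kw, fam in lowered:
            if kw in product:
                assignments[g.gene_id] = fam
                break
    return FamilyCatalog(assignments=assignments, families=families)


# ---------------------------------------------------------------------------
# Expression matrices

def read_expression_matrix(path, strict_nonnegative: bool = True) -> ExpressionMatrix:
    """Read a tab-separated gene x sample matrix.

    First column holds gene IDs, first row sample IDs; the body must be
    numeric. Non-numeric cells and ragged rows are reported with their
    row/column location.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed rows: {exc}") from exc
    df.index = df.index.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r} (ragged row?)"
        )
    if strict_nonnegative and (numeric.to_numpy() < 0).any():
        r, c = np.argwhere(numeric.to_numpy() < 0)[0]
        raise ValueError(
            f"{path}: negative value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}; raw expression must be non-negative"
        )
    return ExpressionMatrix(data=numeric)


def write_expression_matrix(matrix: ExpressionMatrix, path, float_format: str = "%.6g") -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)
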
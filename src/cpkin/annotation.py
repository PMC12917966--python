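"""Locus annotation: genes vs intergenic spacers.

A SNP locus is GENIC when its 1-based position falls inside an annotated
feature (closed interval, literal coordinate — the two inverted-repeat copies
are not cross-mapped), otherwise INTERGENIC and labelled by its flanking
features as ``"upstream ~ downstream"`` along the coordinate line.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .matrix import GenotypeMatrix

GENIC = "GENIC"
INTERGENIC = "INTERGENIC"


@dataclass(frozen=True)
class GeneFeature:
    name: str
    start: int  # 1-based, closed
    end: int
    strand: str = "+"
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


class GeneAnnotation:
    """Sorted feature table over one circular genome."""

    def __init__(self, features: Iterable[GeneFeature]):
        self.features = sorted(features, key=lambda f: (f.start, f.end))
        if not self.features:
            raise ValueError("annotation must contain at least one feature")

    @property
    def span(self) -> tuple[int, int]:
        return self.features[0].start, max(f.end for f in self.features)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneAnnotation":
        """Columns: name, start, end, strand, product (header required)."""
        lines = Path(path).read_text().splitlines()
        feats = []
        for line in lines[1:]:
            if not line.strip():
                continue
            name, start, end, strand, product = (line.split("\t") + [""] * 5)[:5]
            feats.append(GeneFeature(name, int(start), int(end), strand, product))
        return cls(feats)


@dataclass
class LocusAnnotation:
    position: int
    category: str  # GENIC | INTERGENIC
    label: str  # gene name, "geneA/geneB" if overlapping, or "geneA ~ geneB"
    products: str = ""


def annotate_locus(position: int, annotation: GeneAnnotation) -> LocusAnnotation:
    """Assign one position to a gene or to its flanking intergenic spacer."""
    hits = [f for f in annotation.features if position in f]
    if hits:
        label = "/".join(f.name for f in hits)
        products = ", ".join(f.product for f in hits if f.product)
        return LocusAnnotation(position, GENIC, label, products)
    lo, hi = annotation.span
    if position < lo or position > hi:
        raise ValueError(
            f"position {position} outside annotated span [{lo}, {hi}]"
        )
    left = max((f for f in annotation.features if f.end < position), key=lambda f: f.end)
    right = min((f for f in annotation.features if f.start > position), key=lambda f: f.start)
    products = ", ".join(p for p in (left.product, right.product) if p)
    return LocusAnnotation(position, INTERGENIC, f"{left.name} ~ {right.name}", products)


@dataclass
class AnnotationSummary:
    """Partition of a SNP panel into genic and intergenic loci.

    ``per_gene`` counts loci per genic label; share percentages use the genic
    count, the panel size, or an externally supplied discovery total (e.g. all
    SNPs found before frequency filtering) as denominators.
    """

    n_loci: int
    n_genic: int
    n_intergenic: int
    per_gene: dict[str, int] = field(default_factory=dict)
    total_discovered: int | None = None

    def gene_share_of_genic(self, gene: str) -> float:
        """Percent of genic loci falling in ``gene``."""
        if self.n_genic == 0:
            return 0.0
        return 100.0 * self.per_gene.get(gene, 0) / self.n_genic

    def gene_share_of_total(self, gene: str) -> float:
        """Percent of the discovery total (or of the panel) falling in ``gene``."""
        denom = self.total_discovered if self.total_discovered else self.n_loci
        if denom == 0:
            return 0.0
        return 100.0 * self.per_gene.get(gene, 0) / denom

    def to_tsv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        buf.write("metric\tvalue\n")
        buf.write(f"n_loci\t{self.n_loci}\n")
        buf.write(f"n_genic\t{self.n_genic}\n")
        buf.write(f"n_intergenic\t{self.n_intergenic}\n")
        for g, c in sorted(self.per_gene.items()):
            buf.write(f"gene:{g}\t{c}\n")
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text


def summarize_locus_annotations(
    annotations: Sequence[LocusAnnotation], total_discovered: int | None = None
) -> AnnotationSummary:
    """Summarize pre-annotated loci; genic + intergenic always partition the panel."""
    genic = [a for a in annotations if a.category == GENIC]
    per_gene = Counter(a.label for a in genic)
    return AnnotationSummary(
        n_loci=len(annotations),
        n_genic=len(genic),
        n_intergenic=len(annotations) - len(genic),
        per_gene=dict(per_gene),
        total_discovered=total_discovered,
    )


def summarize_annotation(
    matrix: GenotypeMatrix,
    annotation: GeneAnnotation,
    total_discovered: int | None = None,
) -> AnnotationSummary:
    """Annotate every locus of ``matrix`` against ``annotation`` and summarize."""
    annos = [annotate_locus(p, annotation) for p in matrix.positions]
    return summarize_locus_annotations(annos, total_discovered)
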
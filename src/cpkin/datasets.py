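"""Packaged datasets.

``breeding_panel_genotypes.tsv`` and ``breeding_panel_annotation.tsv`` are
transcriptions of a published loblolly-pine breeding-population cpSNP panel:
a 54-sample x 32-locus chloroplast genotype matrix and the per-locus
gene/intergenic annotation of the same panel (81 SNPs were discovered in
that population; the 32 retained loci are the high-frequency subset).
``synthetic_features.tsv`` is a synthetic gene feature table — constructed
intervals, not real chloroplast coordinates — built to be consistent with
the panel's per-locus labels, for exercising interval-based annotation.
"""

from __future__ import annotations

from importlib import resources

from .annotation import GENIC, INTERGENIC, GeneAnnotation, GeneFeature, LocusAnnotation
from .matrix import GenotypeMatrix


def _read(name: str) -> str:
    return resources.files("cpkin").joinpath("data", name).read_text()


def load_breeding_panel_matrix() -> GenotypeMatrix:
    """The published 54 x 32 chloroplast genotype matrix ('-'/base/'N' cells)."""
    return GenotypeMatrix.from_tsv_text(_read("breeding_panel_genotypes.tsv"))


def load_breeding_panel_annotations() -> list[LocusAnnotation]:
    """Per-locus annotations of the 32-SNP panel (gene name or 'geneA ~ geneB')."""
    out = []
    for line in _read("breeding_panel_annotation.tsv").splitlines()[1:]:
        pos, _ref, _alt, label, products = line.split("\t")
        category = INTERGENIC if "~" in label else GENIC
        out.append(LocusAnnotation(int(pos), category, label, products))
    return out


def load_synthetic_features() -> GeneAnnotation:
    """Synthetic gene intervals consistent with the published locus labels."""
    feats = []
    for line in _read("synthetic_features.tsv").splitlines()[1:]:
        name, start, end, strand, product = line.split("\t")
        feats.append(GeneFeature(name, int(start), int(end), strand, product))
    return GeneAnnotation(feats)
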
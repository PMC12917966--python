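"""Genotype matrices of chloroplast SNPs.

A :class:`GenotypeMatrix` holds one row per sample and one column per SNP
locus.  Cells use the compact encoding common in organellar haplotype tables:
``'-'`` for a call identical to the reference base, a base letter for an
alternative call, and ``'N'`` for missing or excluded data.  Because the
chloroplast is effectively haploid, a cell is a single character, never a
diploid genotype.

Missing data are interpreted through an *N policy*: under ``"as-reference"``
an ``'N'`` counts as the reference state (the convention used for haplotype
comparison and frequency filtering throughout this package), while
``"pairwise-drop"`` excludes N cells from the relevant denominator.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

AS_REFERENCE = "as-reference"
PAIRWISE_DROP = "pairwise-drop"
N_POLICIES = (AS_REFERENCE, PAIRWISE_DROP)

_BASES = set("ACGT")


class MultiAllelicLocusError(ValueError):
    """Raised when calls at one locus disagree on the alternative base."""


def _check_policy(n_policy: str) -> str:
    if n_policy not in N_POLICIES:
        raise ValueError(f"unknown N policy {n_policy!r}; expected one of {N_POLICIES}")
    return n_policy


@dataclass(frozen=True)
class Locus:
    """One SNP column: 1-based position plus reference and alternative base.

    ``alt`` may be ``'.'`` when the column is invariant (no alternative seen).
    """

    position: int
    ref: str
    alt: str = "."

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based and must be >= 1")
        if self.ref not in _BASES:
            raise ValueError(f"reference base must be one of ACGT, got {self.ref!r}")


class GenotypeMatrix:
    """Samples x SNP-loci table in '-'/base/'N' encoding.

    Parameters
    ----------
    samples:
        Ordered sample identifiers (unique).
    loci:
        Ordered :class:`Locus` objects with strictly increasing positions.
    cells:
        Array-like of single characters, shape ``(n_samples, n_loci)``.
    chrom:
        Sequence name used for VCF export.
    """

    def __init__(
        self,
        samples: Sequence[str],
        loci: Sequence[Locus],
        cells: Iterable[Iterable[str]],
        chrom: str = "chloroplast",
    ) -> None:
        self.samples = list(samples)
        self.loci = list(loci)
        self.cells = np.asarray(cells, dtype="<U1")
        self.chrom = chrom
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        positions = [l.position for l in self.loci]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("locus positions must be strictly increasing")
        if self.cells.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"cells shape {self.cells.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        ok = set("ACGTN-")
        bad = set(self.cells.ravel().tolist()) - ok
        if bad:
            raise ValueError(f"invalid cell characters: {sorted(bad)}")
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._locus_index = {l.position: j for j, l in enumerate(self.loci)}

    # -- basic access --------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def positions(self) -> list[int]:
        return [l.position for l in self.loci]

    def row(self, sample: str) -> np.ndarray:
        try:
            return self.cells[self._sample_index[sample]]
        except KeyError:
            raise KeyError(f"sample {sample!r} not in matrix") from None

    def column(self, position: int) -> np.ndarray:
        try:
            return self.cells[:, self._locus_index[position]]
        except KeyError:
            raise KeyError(f"locus {position} not in matrix") from None

    def locus(self, position: int) -> Locus:
        return self.loci[self._locus_index[position]]

    def __contains__(self, sample: str) -> bool:
        return sample in self._sample_index

    def subset(
        self,
        samples: Sequence[str] | None = None,
        positions: Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        samples = self.samples if samples is None else list(samples)
        positions = self.positions if positions is None else list(positions)
        si = [self._sample_index[s] for s in samples]
        lj = [self._locus_index[p] for p in positions]
        return GenotypeMatrix(
            samples, [self.loci[j] for j in lj], self.cells[np.ix_(si, lj)], self.chrom
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.loci == other.loci
            and bool(np.array_equal(self.cells, other.cells))
        )

    # -- serialization -------------------------------------------------

    def to_tsv(self, path: str | Path | None = None) -> str:
        """Serialize in the haplotype-table layout: header of positions, a REF
        and an ALT meta-row, then one row per sample."""
        buf = io.StringIO()
        buf.write("sample\t" + "\t".join(str(p) for p in self.positions) + "\n")
        buf.write("REF\t" + "\t".join(l.ref for l in self.loci) + "\n")
        buf.write("ALT\t" + "\t".join(l.alt for l in self.loci) + "\n")
        for i, s in enumerate(self.samples):
            buf.write(s + "\t" + "\t".join(self.cells[i]) + "\n")
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_tsv(cls, source: str | Path, chrom: str = "chloroplast") -> "GenotypeMatrix":
        """Read a haplotype-table TSV.

        The REF meta-row is required.  The ALT row is optional; when absent the
        alternative base of each locus is inferred as the most frequent
        non-reference letter in the column (``'.'`` for invariant columns).
        """
        return cls.from_tsv_text(Path(source).read_text(), chrom)

    @classmethod
    def from_tsv_text(cls, text: str, chrom: str = "chloroplast") -> "GenotypeMatrix":
        lines = [l.rstrip("\n") for l in text.splitlines() if l.strip()]
        header = lines[0].split("\t")
        positions = [int(p.replace(",", "")) for p in header[1:]]
        meta: dict[str, list[str]] = {}
        samples, rows = [], []
        for line in lines[1:]:
            fields = line.split("\t")
            name, cells = fields[0], fields[1:]
            if name in ("REF", "ALT"):
                meta[name] = cells
                continue
            samples.append(name)
            rows.append(cells)
        if "REF" not in meta:
            raise ValueError("genotype TSV must contain a REF meta-row")
        cells = np.asarray(rows, dtype="<U1")
        if "ALT" in meta:
            alts = meta["ALT"]
        else:
            alts = []
            for j, ref in enumerate(meta["REF"]):
                col = cells[:, j]
                letters = [c for c in col if c in _BASES and c != ref]
                alts.append(max(sorted(set(letters)), key=letters.count) if letters else ".")
        loci = [Locus(p, r, a) for p, r, a in zip(positions, meta["REF"], alts)]
        return cls(samples, loci, cells, chrom)

    def to_vcf(self, path: str | Path | None = None) -> str:
        """Export as a haploid multi-sample VCF v4.2.

        ``'-'`` maps to GT ``0``, the locus alt letter to GT ``1``, any other
        base letter to an additional ALT allele, and ``'N'`` to ``.``.
        """
        buf = io.StringIO()
        buf.write("##fileformat=VCFv4.2\n")
        buf.write(f"##contig=<ID={self.chrom}>\n")
        buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">\n')
        buf.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(self.samples)
            + "\n"
        )
        for j, loc in enumerate(self.loci):
            col = self.cells[:, j]
            alts = [] if loc.alt == "." else [loc.alt]
            for c in col:
                if c in _BASES and c != loc.ref and c not in alts:
                    alts.append(c)
            gts = []
            for c in col:
                if c == "N":
                    gts.append(".")
                elif c == "-":
                    gts.append("0")
                else:
                    gts.append(str(1 + alts.index(c)))
            alt_field = ",".join(alts) if alts else "."
            buf.write(
                f"{self.chrom}\t{loc.position}\t.\t{loc.ref}\t{alt_field}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        import pysam

        with pysam.VariantFile(str(path)) as vf:
            samples = list(vf.header.samples)
            loci, rows = [], []
            chrom = "chloroplast"
            for rec in vf:
                chrom = rec.chrom
                alts = list(rec.alts or [])
                loci.append(Locus(rec.pos, rec.ref, alts[0] if alts else "."))
                alleles = [rec.ref] + alts
                col = []
                for s in samples:
                    gt = rec.samples[s].get("GT", (None,))
                    a = gt[0] if gt else None
                    if a is None:
                        col.append("N")
                    elif a == 0:
                        col.append("-")
                    else:
                        col.append(alleles[a])
                rows.append(col)
        cells = np.asarray(rows, dtype="<U1").T if rows else np.empty((len(samples), 0), "<U1")
        return cls(samples, loci, cells, chrom)


# ---------------------------------------------------------------------------
# construction from per-sample calls


def build_matrix(
    calls_by_sample: Mapping[str, Iterable],
    positions: Sequence[int] | None = None,
    chrom: str = "chloroplast",
) -> GenotypeMatrix:
    """Assemble per-sample SNP calls into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    calls_by_sample:
        Mapping sample id -> iterable of ``SnpCall`` (see :mod:`cpkin.calling`).
    positions:
        Locus set to materialize.  Defaults to the union of positions with at
        least one ALT call.  A sample with no call at a locus is recorded as
        reference (``'-'``).

    Raises
    ------
    MultiAllelicLocusError
        If two samples' ALT calls disagree on the alternative base at a locus.
    """
    calls = {s: list(c) for s, c in calls_by_sample.items()}
    ref_at: dict[int, str] = {}
    alt_at: dict[int, str] = {}
    for s, cs in calls.items():
        for c in cs:
            ref_at.setdefault(c.position, c.ref_base)
            if c.status == "ALT":
                prev = alt_at.get(c.position)
                if prev is not None and prev != c.called_base:
                    raise MultiAllelicLocusError(
                        f"locus {c.position}: conflicting alternative bases "
                        f"{prev} and {c.called_base}"
                    )
                alt_at[c.position] = c.called_base
    if positions is None:
        positions = sorted(alt_at)
    else:
        positions = sorted(positions)
    loci = [Locus(p, ref_at.get(p, "A"), alt_at.get(p, ".")) for p in positions]
    samples = list(calls)
    cells = np.full((len(samples), len(positions)), "-", dtype="<U1")
    pidx = {p: j for j, p in enumerate(positions)}
    for i, s in enumerate(samples):
        for c in calls[s]:
            j = pidx.get(c.position)
            if j is None:
                continue
            if c.status == "ALT":
                cells[i, j] = c.called_base
            elif c.status in ("MISSING", "HETEROPLASMIC_EXCLUDED"):
                cells[i, j] = "N"
    return GenotypeMatrix(samples, loci, cells, chrom)


# ---------------------------------------------------------------------------
# frequency / carrier filters


def carrier_count(matrix: GenotypeMatrix, position: int, n_policy: str = AS_REFERENCE) -> int:
    """Number of samples carrying a non-reference base at ``position``.

    Any base letter different from the reference counts as a carrier ("variable
    individual"); ``'N'`` never does.  ``n_policy`` does not change the count
    itself, only how the complementary denominator is interpreted elsewhere.
    """
    _check_policy(n_policy)
    col = matrix.column(position)
    return int(np.sum((col != "-") & (col != "N")))


def minor_allele_frequency(
    matrix: GenotypeMatrix, position: int, n_policy: str = AS_REFERENCE
) -> float:
    """MAF of the locus: frequency of the rarer of the two allele classes.

    Under ``as-reference`` the denominator is the full sample count (N cells
    count as reference); under ``pairwise-drop`` it is the number of non-N
    cells.  A locus where the alternative base is nearly universal therefore
    has a *reference* minor allele and can still pass a MAF filter.
    """
    _check_policy(n_policy)
    col = matrix.column(position)
    carriers = int(np.sum((col != "-") & (col != "N")))
    if n_policy == AS_REFERENCE:
        denom = matrix.n_samples
    else:
        denom = int(np.sum(col != "N"))
    if denom == 0:
        return 0.0
    f = carriers / denom
    return min(f, 1.0 - f)


def alt_allele_frequency(
    matrix: GenotypeMatrix, position: int, n_policy: str = AS_REFERENCE
) -> float:
    """Frequency of the non-reference allele (carriers over the policy denominator)."""
    _check_policy(n_policy)
    col = matrix.column(position)
    carriers = int(np.sum((col != "-") & (col != "N")))
    denom = matrix.n_samples if n_policy == AS_REFERENCE else int(np.sum(col != "N"))
    return carriers / denom if denom else 0.0


def filter_loci(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    min_carriers: int = 3,
    biallelic_only: bool = True,
    n_policy: str = AS_REFERENCE,
) -> GenotypeMatrix:
    """Retain high-frequency loci.

    A locus is kept when its *non-reference* allele frequency is >= ``maf_min``
    and its carrier count is >= ``min_carriers``.  Thresholding the alternative
    allele (rather than the folded minor allele) keeps near-fixed loci, where
    the alternative base is nearly universal and the rare allele is the
    reference one — those represent fixed differences from the reference
    accession, not low-frequency variation.  With ``biallelic_only`` loci
    showing more than one alternative letter are dropped.  Idempotent.
    """
    keep = []
    for loc in matrix.loci:
        col = matrix.column(loc.position)
        if biallelic_only:
            letters = {c for c in col if c in _BASES and c != loc.ref}
            if len(letters) > 1:
                continue
        if carrier_count(matrix, loc.position, n_policy) < min_carriers:
            continue
        if alt_allele_frequency(matrix, loc.position, n_policy) < maf_min:
            continue
        keep.append(loc.position)
    return matrix.subset(positions=keep)


def snp_density(n_snps: int, genome_length: int) -> float:
    """Polymorphism density in SNPs per bp (e.g. 81 SNPs / 121 kb ~= 6.7e-4)."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    return n_snps / genome_length
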
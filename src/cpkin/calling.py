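"""Homoplasmic chloroplast SNP calling from aligned reads.

The caller applies four filters, in order:

1. read level — only uniquely, properly paired alignments with mapping
   quality >= 20 are used (secondary/supplementary/unmapped records are
   discarded);
2. base level — bases below quality 20 are excluded from pileup counts;
3. depth — a site needs >= 3 filtered bases to be callable, otherwise it is
   reported as missing (``N``);
4. homoplasmy — the major base must reach a configurable fraction of the
   filtered depth (default 0.9); mixed columns are excluded as putative
   heteroplasmy and reported as ``N``.

Chloroplasts are effectively haploid within an individual, so a passing site
yields a single base: ``REF`` if it equals the reference, ``ALT`` otherwise.
Ties for the major base are never broken arbitrarily — a tied column is ``N``.
Coordinates are 1-based on the forward strand throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .simulate import ReferenceGenome

BASES = "ACGT"
_BASE_TO_IDX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_TO_IDX[ord(_b)] = _i
    _BASE_TO_IDX[ord(_b.lower())] = _i

REF = "REF"
ALT = "ALT"
MISSING = "MISSING"
HETEROPLASMIC_EXCLUDED = "HETEROPLASMIC_EXCLUDED"

DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_BASEQ = 20
DEFAULT_MIN_DEPTH = 3
DEFAULT_HOMOPLASMY = 0.9


class MalformedInputError(ValueError):
    """Aligned input inconsistent with the reference (e.g. read beyond its end)."""


@dataclass
class PileupColumn:
    """Filtered base counts at one reference position (1-based)."""

    position: int
    ref_base: str
    base_counts: dict[str, int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


@dataclass
class SnpCall:
    sample: str
    position: int
    ref_base: str
    called_base: str  # A/C/G/T or N
    status: str  # REF | ALT | MISSING | HETEROPLASMIC_EXCLUDED
    depth: int
    major_fraction: float


@dataclass
class CoverageStats:
    sample: str
    mean_depth: float
    breadth_1x: float


# ---------------------------------------------------------------------------
# read-level filter


def filter_reads(
    reads: Iterable[pysam.AlignedSegment], min_mapq: int = DEFAULT_MIN_MAPQ
) -> Iterator[pysam.AlignedSegment]:
    """Keep uniquely and properly paired reads with MAPQ >= ``min_mapq``."""
    for r in reads:
        if r.is_unmapped or r.is_secondary or r.is_supplementary:
            continue
        if not r.is_proper_pair:
            continue
        if r.mapping_quality < min_mapq:
            continue
        yield r


def read_sam(path: str | Path) -> list[pysam.AlignedSegment]:
    """Materialize all records of a SAM/BAM file."""
    with pysam.AlignmentFile(str(path), check_sq=False) as f:
        return list(f)


# ---------------------------------------------------------------------------
# pileup


class Pileup:
    """Base-quality-filtered pileup over the whole reference.

    Counts are held as an ``(L, 4)`` array (A, C, G, T) so per-genome
    statistics are vectorized; :meth:`column` materializes a
    :class:`PileupColumn` view for one position.
    """

    def __init__(self, ref: ReferenceGenome):
        self.ref = ref
        self.counts = np.zeros((ref.length, 4), dtype=np.int64)

    def add_read(self, read: pysam.AlignedSegment, min_baseq: int = DEFAULT_MIN_BASEQ) -> None:
        seq = read.query_sequence
        if seq is None:
            return
        quals = read.query_qualities
        q = np.asarray(quals, dtype=np.int64) if quals is not None else np.full(len(seq), 60)
        b = _BASE_TO_IDX[np.frombuffer(seq.encode(), dtype=np.uint8)]
        ct = read.cigartuples
        if ct is not None and len(ct) == 1 and ct[0][0] == 0:  # all-match CIGAR
            rpos = read.reference_start + np.arange(len(seq))
            qpos = np.arange(len(seq))
        else:
            pairs = read.get_aligned_pairs(matches_only=True)
            if not pairs:
                return
            qpos = np.array([p[0] for p in pairs])
            rpos = np.array([p[1] for p in pairs])
        if rpos[-1] >= self.ref.length or rpos[0] < 0:
            raise MalformedInputError(
                f"read {read.query_name} maps outside the {self.ref.length} bp reference"
            )
        keep = (q[qpos] >= min_baseq) & (b[qpos] >= 0)
        np.add.at(self.counts, (rpos[keep], b[qpos[keep]]), 1)

    def column(self, position: int) -> PileupColumn:
        """Column at a 1-based position."""
        row = self.counts[position - 1]
        counts = {BASES[i]: int(row[i]) for i in range(4) if row[i]}
        return PileupColumn(position, self.ref.sequence[position - 1], counts)

    def covered_positions(self) -> np.ndarray:
        """1-based positions with at least one filtered base."""
        return np.nonzero(self.counts.sum(axis=1) > 0)[0] + 1

    def coverage_stats(self, sample: str = "") -> CoverageStats:
        total = self.counts.sum(axis=1)
        return CoverageStats(
            sample=sample,
            mean_depth=float(total.mean()),
            breadth_1x=float((total > 0).mean()),
        )


def build_pileup(
    reads: Iterable[pysam.AlignedSegment],
    ref: ReferenceGenome,
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> Pileup:
    """Accumulate base counts from (pre-filtered) reads, dropping bases < Q``min_baseq``."""
    pile = Pileup(ref)
    for r in reads:
        pile.add_read(r, min_baseq)
    return pile


# ---------------------------------------------------------------------------
# site genotyping


def call_site(
    column: PileupColumn,
    homoplasmy_min_fraction: float = DEFAULT_HOMOPLASMY,
    min_depth: int = DEFAULT_MIN_DEPTH,
    sample: str = "",
) -> SnpCall:
    """Genotype one pileup column.

    Depth below ``min_depth`` -> ``MISSING``/``N``.  Otherwise the major base is
    called when it reaches ``homoplasmy_min_fraction`` of the filtered depth and
    is unique; mixed or tied columns -> ``HETEROPLASMIC_EXCLUDED``/``N``.
    """
    depth = column.depth
    if depth == 0:
        return SnpCall(sample, column.position, column.ref_base, "N", MISSING, 0, 0.0)
    major_count = max(column.base_counts.values())
    majors = [b for b, c in column.base_counts.items() if c == major_count]
    frac = major_count / depth
    if depth < min_depth:
        return SnpCall(sample, column.position, column.ref_base, "N", MISSING, depth, frac)
    if frac >= homoplasmy_min_fraction and len(majors) == 1:
        base = majors[0]
        status = REF if base == column.ref_base else ALT
        return SnpCall(sample, column.position, column.ref_base, base, status, depth, frac)
    return SnpCall(
        sample, column.position, column.ref_base, "N", HETEROPLASMIC_EXCLUDED, depth, frac
    )


def call_at_sites(
    pileup: Pileup,
    positions: Sequence[int],
    homoplasmy_min_fraction: float = DEFAULT_HOMOPLASMY,
    min_depth: int = DEFAULT_MIN_DEPTH,
    sample: str = "",
) -> list[SnpCall]:
    """Genotype a fixed panel of positions (uncovered panel sites are MISSING)."""
    return [
        call_site(pileup.column(int(p)), homoplasmy_min_fraction, min_depth, sample)
        for p in positions
    ]


def call_sample(
    reads: Iterable[pysam.AlignedSegment] | str | Path,
    ref: ReferenceGenome,
    sample: str = "",
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    min_depth: int = DEFAULT_MIN_DEPTH,
    homoplasmy_min_fraction: float = DEFAULT_HOMOPLASMY,
) -> tuple[list[SnpCall], CoverageStats]:
    """Full per-sample caller: read filter, pileup, site genotyping.

    Returns calls at *informative* covered positions — ALT calls plus covered
    sites that could not be called (low depth or heteroplasmic) — together with
    post-filter coverage statistics.  Homozygous-reference positions are not
    listed; uncovered positions are implicitly missing.
    """
    if isinstance(reads, (str, Path)):
        reads = read_sam(reads)
    else:
        reads = list(reads)
    for r in reads:
        if not r.is_unmapped and r.reference_name != ref.id:
            raise MalformedInputError(
                f"SAM reference {r.reference_name!r} does not match {ref.id!r}"
            )
    kept = list(filter_reads(reads, min_mapq))
    pile = build_pileup(kept, ref, min_baseq)
    calls: list[SnpCall] = []
    for p in pile.covered_positions():
        c = call_site(pile.column(int(p)), homoplasmy_min_fraction, min_depth, sample)
        if c.status != REF:
            calls.append(c)
    return calls, pile.coverage_stats(sample)
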
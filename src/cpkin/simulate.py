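"""Synthetic chloroplast cohorts with known-truth transmission.

This module generates everything the downstream pipeline consumes — a circular
reference sequence, parental haplotypes segregating at biallelic sites, a
pedigree of full-sib families, progeny haplotypes, and aligned short reads in
SAM format — so that SNP calling, matrix assembly, parentage classification
and tree building can all be exercised and validated without any external
download.

Transmission model
------------------
Conifer chloroplasts travel with pollen, so by default every progeny inherits
its recorded father's haplotype.  Three perturbations, each with a
configurable rate, produce the event classes a parentage screen must detect:

* ``CONTAMINATION`` — the true pollen donor is an *external* haplotype absent
  from the sampled parent panel (stray pollen in the orchard);
* ``LEAKAGE`` — maternal transmission (rare organelle leakage);
* de novo substitutions — each progeny receives ``Poisson(mu * L * g)``
  private mutations on top of its donor haplotype, where ``mu`` is the
  per-site per-year substitution rate, ``L`` the genome length and ``g`` the
  generation time in years.

Every progeny's true donor and event type are recorded in a
:class:`TruthTable` for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .matrix import GenotypeMatrix, Locus

BASES = "ACGT"

PATERNAL = "PATERNAL"
LEAKAGE = "LEAKAGE"
CONTAMINATION = "CONTAMINATION"
EXTERNAL = "EXTERNAL"


@dataclass(frozen=True)
class ReferenceGenome:
    """A circular chloroplast reference with 1-based forward-strand coordinates."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if set(self.sequence) - set(BASES):
            raise ValueError("reference sequence must contain only A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def to_fasta(self, path: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        rec = SeqRecord(Seq(self.sequence), id=self.id, description="")
        SeqIO.write([rec], str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, circular: bool = True) -> "ReferenceGenome":
        from Bio import SeqIO

        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls(rec.id, str(rec.seq).upper(), circular)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the tester-design setting this package targets: a 9 x 5
    mating design (45 progeny), a ~121 kb chloroplast genome segregating at 32
    biallelic sites, strictly paternal transmission with a 20% stray-pollen
    (contamination) rate and no maternal leakage, a pine chloroplast
    substitution rate of 0.2e-9 per site per year with a 25-year generation
    time, and ~12.3x short-read coverage with 150 bp reads.
    """

    n_mothers: int = 9
    n_fathers: int = 5
    n_progeny_per_cross: int = 1
    n_polymorphic_sites: int = 32
    contamination_rate: float = 0.2
    leakage_rate: float = 0.0
    de_novo_mu: float = 0.2e-9  # substitutions / site / year
    generation_years: float = 25.0
    depth_mean: float = 12.3  # reads per site
    read_length: int = 150
    base_error_rate: float = 0.002
    frac_low_mapq: float = 0.05
    seed: int = 0
    genome_length: int = 121_000
    n_external_donors: int = 5
    n_progeny: int | None = None  # overrides the full factorial when the
    # cohort is a sampled subset of crosses (e.g. 54 progeny from 13 x 10)

    def __post_init__(self) -> None:
        for name in ("contamination_rate", "leakage_rate", "base_error_rate", "frac_low_mapq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.contamination_rate + self.leakage_rate > 1.0:
            raise ValueError("contamination_rate + leakage_rate must be <= 1")
        for name in ("n_mothers", "n_fathers", "n_progeny_per_cross", "read_length", "genome_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SimulationConfig":
        p = Path(source)
        return cls(**json.loads(p.read_text() if p.exists() else str(source)))


@dataclass
class TruthRecord:
    progeny_id: str
    recorded_mother: str
    recorded_father: str
    true_donor: str  # clone id, or an EXTERNAL_* donor id
    event: str  # PATERNAL | LEAKAGE | CONTAMINATION
    de_novo_positions: list[int] = field(default_factory=list)


class TruthTable:
    """Ground truth for a simulated cohort: one record per progeny."""

    def __init__(self, records: Iterable[TruthRecord]):
        self.records = list(records)
        for r in self.records:
            if r.event == PATERNAL and r.true_donor != r.recorded_father:
                raise ValueError(f"{r.progeny_id}: PATERNAL event with foreign donor")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def event_fractions(self) -> dict[str, float]:
        n = len(self.records)
        out = {PATERNAL: 0.0, LEAKAGE: 0.0, CONTAMINATION: 0.0}
        for r in self.records:
            out[r.event] += 1.0
        return {k: v / n for k, v in out.items()} if n else out

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = ["progeny_id\trecorded_mother\trecorded_father\ttrue_donor\tevent\tde_novo_positions"]
        for r in self.records:
            pos = ",".join(str(p) for p in r.de_novo_positions)
            lines.append(f"{r.progeny_id}\t{r.recorded_mother}\t{r.recorded_father}\t{r.true_donor}\t{r.event}\t{pos}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        lines = Path(path).read_text().splitlines()
        recs = []
        for line in lines[1:]:
            pid, m, f, donor, event, pos = (line.split("\t") + [""])[:6]
            positions = [int(x) for x in pos.split(",") if x]
            recs.append(TruthRecord(pid, m, f, donor, event, positions))
        return cls(recs)


# ---------------------------------------------------------------------------
# reference / haplotypes


def simulate_reference(length: int, seed: int, id: str = "cp_sim") -> ReferenceGenome:
    """Uniform-composition random circular reference of ``length`` bp."""
    if length < 1000:
        raise ValueError("reference length must be >= 1000 bp")
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
    return ReferenceGenome(id, seq)


def simulate_parents(
    ref: ReferenceGenome,
    n_parents: int,
    n_sites: int,
    seed: int,
    prefix: str = "P",
    carry_prob: float = 0.5,
) -> tuple[dict[str, str], dict[int, tuple[str, str]]]:
    """Draw parental haplotypes differing from the reference at biallelic sites.

    ``n_sites`` candidate positions are sampled without replacement; each gets
    a single alternative base, and each parent independently carries each
    site's alternative with probability ``carry_prob``.  Returns the haplotype
    map and the site spectrum ``{position: (ref_base, alt_base)}`` (1-based).
    """
    if n_sites >= ref.length:
        raise ValueError("n_sites must be smaller than the reference length")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(ref.length, size=n_sites, replace=False)) + 1
    sites: dict[int, tuple[str, str]] = {}
    for p in positions:
        r = ref.sequence[p - 1]
        alt = BASES[(BASES.index(r) + rng.integers(1, 4)) % 4]
        sites[int(p)] = (r, alt)
    haplotypes: dict[str, str] = {}
    for i in range(n_parents):
        hap = list(ref.sequence)
        for p, (_, alt) in sites.items():
            if rng.random() < carry_prob:
                hap[p - 1] = alt
        haplotypes[f"{prefix}{i + 1:02d}"] = "".join(hap)
    return haplotypes, sites


def tester_pedigree(
    mothers: Sequence[str], fathers: Sequence[str], n_progeny_per_cross: int = 1
) -> list[tuple[str, str, str]]:
    """Full-factorial tester design: every mother x father cross produces
    ``n_progeny_per_cross`` progeny.  Returns (progeny_id, mother, father)."""
    out = []
    for m in mothers:
        for f in fathers:
            for k in range(1, n_progeny_per_cross + 1):
                out.append((f"F{f}_M{m}_{k}", m, f))
    if not out:
        raise ValueError("empty pedigree")
    return out


def sampled_pedigree(
    mothers: Sequence[str], fathers: Sequence[str], n_progeny: int, seed: int
) -> list[tuple[str, str, str]]:
    """Pedigree with ``n_progeny`` progeny over uniformly drawn crosses, for
    cohorts (like 54 progeny from 13 x 10 parents) that are not full factorials."""
    if n_progeny < 1:
        raise ValueError("empty pedigree")
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, str], int] = {}
    out = []
    for _ in range(n_progeny):
        m = mothers[rng.integers(0, len(mothers))]
        f = fathers[rng.integers(0, len(fathers))]
        counts[(m, f)] = counts.get((m, f), 0) + 1
        out.append((f"F{f}_M{m}_{counts[(m, f)]}", m, f))
    return out


def simulate_cross(
    parents: Mapping[str, str],
    pedigree: Sequence[tuple[str, str, str]],
    config: SimulationConfig,
    sites: Mapping[int, tuple[str, str]] | None = None,
) -> tuple[dict[str, str], TruthTable]:
    """Transmit haplotypes through the pedigree under the paternal model.

    Each progeny's haplotype is its true donor's haplotype plus
    ``Poisson(de_novo_mu * L * generation_years)`` random substitutions.  The
    donor is the recorded father, except with probability ``leakage_rate``
    (mother) or ``contamination_rate`` (a haplotype from an internally
    generated external pollen pool, mimicking unsampled males).

    When the panel's segregating ``sites`` (``{pos: (ref, alt)}``) are given,
    external donors carry an independent random allele pattern over them — a
    stray pollen parent comes from the same population, so it segregates at
    the same loci — plus a few private substitutions that keep each donor
    distinct from every sampled parent even under a pattern collision.
    """
    if not pedigree:
        raise ValueError("empty pedigree")
    for _, m, f in pedigree:
        if m not in parents or f not in parents:
            raise ValueError(f"pedigree parent missing from panel: {m!r} / {f!r}")
    rng = np.random.default_rng(config.seed + 1)
    some_hap = next(iter(parents.values()))
    L = len(some_hap)
    lam = config.de_novo_mu * L * config.generation_years

    external: dict[str, str] = {}
    for i in range(config.n_external_donors):
        hap = list(some_hap)
        if sites:
            for p, (ref_b, alt_b) in sites.items():
                hap[p - 1] = alt_b if rng.random() < 0.5 else ref_b
        k = max(3, L // 30000)
        for p in rng.choice(L, size=k, replace=False):
            hap[p] = BASES[(BASES.index(hap[p]) + 1 + int(rng.integers(0, 3))) % 4]
        external[f"{EXTERNAL}_{i + 1}"] = "".join(hap)
    ext_ids = list(external)

    haplotypes: dict[str, str] = {}
    records: list[TruthRecord] = []
    for pid, mother, father in pedigree:
        u = rng.random()
        if u < config.contamination_rate:
            event, donor = CONTAMINATION, ext_ids[int(rng.integers(0, len(ext_ids)))]
            hap = external[donor]
        elif u < config.contamination_rate + config.leakage_rate:
            event, donor = LEAKAGE, mother
            hap = parents[mother]
        else:
            event, donor = PATERNAL, father
            hap = parents[father]
        n_mut = int(rng.poisson(lam))
        de_novo: list[int] = []
        if n_mut:
            hap_l = list(hap)
            for p in rng.choice(L, size=n_mut, replace=False):
                hap_l[p] = BASES[(BASES.index(hap_l[p]) + 1 + int(rng.integers(0, 3))) % 4]
                de_novo.append(int(p) + 1)
            hap = "".join(hap_l)
        haplotypes[pid] = hap
        records.append(TruthRecord(pid, mother, father, donor, event, sorted(de_novo)))
    return haplotypes, TruthTable(records)


def haplotypes_to_matrix(
    haplotypes: Mapping[str, str],
    ref: ReferenceGenome,
    sites: Mapping[int, tuple[str, str]] | Iterable[int],
    chrom: str | None = None,
) -> GenotypeMatrix:
    """Project full-length haplotypes onto a SNP panel (truth matrix).

    ``sites`` is either ``{position: (ref, alt)}`` or a plain position list (alt
    then inferred per column).  De novo substitutions outside the panel are
    invisible by construction, as in any fixed-panel genotyping assay.
    """
    if isinstance(sites, Mapping):
        positions = sorted(sites)
        alts = {p: sites[p][1] for p in positions}
    else:
        positions = sorted(sites)
        alts = {}
    samples = list(haplotypes)
    cells = []
    for s in samples:
        hap = haplotypes[s]
        row = []
        for p in positions:
            b = hap[p - 1]
            row.append("-" if b == ref.sequence[p - 1] else b)
        cells.append(row)
    loci = []
    for j, p in enumerate(positions):
        alt = alts.get(p)
        if alt is None:
            letters = [cells[i][j] for i in range(len(samples)) if cells[i][j] != "-"]
            alt = max(sorted(set(letters)), key=letters.count) if letters else "."
        loci.append(Locus(p, ref.sequence[p - 1], alt))
    return GenotypeMatrix(samples, loci, cells, chrom or ref.id)


# ---------------------------------------------------------------------------
# read simulation / SAM output

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_READ1 = 0x40
FLAG_SECONDARY = 0x100


@dataclass
class SamRead:
    """One aligned read; maps 1:1 onto a SAM record (all-match CIGAR)."""

    qname: str
    flag: int
    rname: str
    pos: int  # 1-based leftmost
    mapq: int
    seq: str
    quals: list[int]

    def to_sam_line(self) -> str:
        qual = "".join(chr(q + 33) for q in self.quals)
        return (
            f"{self.qname}\t{self.flag}\t{self.rname}\t{self.pos}\t{self.mapq}\t"
            f"{len(self.seq)}M\t=\t{self.pos}\t0\t{self.seq}\t{qual}"
        )


def simulate_reads(
    haplotype: str,
    ref: ReferenceGenome,
    config: SimulationConfig,
    seed: int | None = None,
    sample: str = "S",
) -> list[SamRead]:
    """Uniform shotgun reads from one haplotype.

    Reads are ``read_length`` bp, never span the circular origin, and carry
    paired/proper-pair flags.  Per base, a sequencing error is injected with
    probability ``base_error_rate``; erroneous bases get a degraded quality
    drawn from Q10-Q40 (so roughly a third of them fall below the usual Q20
    cutoff), correct bases get Q40.  A fraction ``frac_low_mapq`` of reads is
    emitted either with MAPQ 10 or with the proper-pair flag cleared, to
    exercise read-level filters downstream.
    """
    L = len(haplotype)
    if config.read_length > L:
        raise ValueError("read_length exceeds reference length")
    if config.depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_reads = int(round(config.depth_mean * L / config.read_length))
    hap = np.frombuffer(haplotype.encode(), dtype="S1")
    base_arr = np.frombuffer(BASES.encode(), dtype="S1")
    base_index = {b: i for i, b in enumerate(BASES)}
    starts = rng.integers(1, L - config.read_length + 2, size=n_reads)
    u_bad = rng.random(n_reads)
    bad_kind = rng.integers(0, 2, size=n_reads)  # 0: low MAPQ, 1: improper pair
    reads: list[SamRead] = []
    for i in range(n_reads):
        s0 = int(starts[i]) - 1
        seq = hap[s0 : s0 + config.read_length].copy()
        quals = np.full(config.read_length, 40, dtype=int)
        err = rng.random(config.read_length) < config.base_error_rate
        if err.any():
            idx = np.nonzero(err)[0]
            for j in idx:
                cur = base_index[seq[j].decode()]
                seq[j] = base_arr[(cur + 1 + int(rng.integers(0, 3))) % 4]
            quals[idx] = rng.integers(10, 41, size=len(idx))
        flag = FLAG_PAIRED | FLAG_PROPER | FLAG_READ1
        mapq = 60
        if u_bad[i] < config.frac_low_mapq:
            if bad_kind[i] == 0:
                mapq = 10
            else:
                flag &= ~FLAG_PROPER
        reads.append(
            SamRead(
                qname=f"{sample}_r{i:06d}",
                flag=flag,
                rname=ref.id,
                pos=int(starts[i]),
                mapq=mapq,
                seq=seq.tobytes().decode(),
                quals=quals.tolist(),
            )
        )
    return reads


def sam_text(reads: Iterable[SamRead], ref: ReferenceGenome) -> str:
    header = f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:{ref.id}\tLN:{ref.length}\n"
    return header + "".join(r.to_sam_line() + "\n" for r in reads)


def write_sam(reads: Iterable[SamRead], ref: ReferenceGenome, path: str | Path) -> None:
    Path(path).write_text(sam_text(reads, ref))


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ReferenceGenome, dict[str, str], dict[int, tuple[str, str]], list[tuple[str, str, str]], dict[str, str], TruthTable]:
    """Convenience wrapper: reference + parents + pedigree + progeny + truth.

    Parent clones are named ``1xx`` (mothers) and ``2xx`` (fathers) so progeny
    ids follow the ``F<father>_M<mother>_<k>`` labelling scheme.
    """
    ref = simulate_reference(config.genome_length, config.seed)
    n_parents = config.n_mothers + config.n_fathers
    haps, sites = simulate_parents(ref, n_parents, config.n_polymorphic_sites, config.seed + 7, prefix="")
    ids = list(haps)
    mothers = [f"1{i + 1:02d}" for i in range(config.n_mothers)]
    fathers = [f"2{i + 1:02d}" for i in range(config.n_fathers)]
    renamed = {new: haps[old] for new, old in zip(mothers + fathers, ids)}
    if config.n_progeny:
        pedigree = sampled_pedigree(mothers, fathers, config.n_progeny, config.seed + 3)
    else:
        pedigree = tester_pedigree(mothers, fathers, config.n_progeny_per_cross)
    progeny, truth = simulate_cross(renamed, pedigree, config, sites=sites)
    return ref, renamed, sites, pedigree, progeny, truth
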
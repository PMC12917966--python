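"""End-to-end pipeline: SAM files -> calls -> matrix -> annotation -> kinship -> tree.

A :class:`PipelineConfig` holds every threshold in one place so a run is fully
reproducible: outputs are stamped with a hash of the configuration and the
seed, and re-running the same configuration reproduces byte-identical text
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import calling, kinship, phylo
from .annotation import GeneAnnotation, summarize_annotation
from .matrix import AS_REFERENCE, GenotypeMatrix, build_matrix, filter_loci
from .simulate import ReferenceGenome

log = logging.getLogger("cpkin")


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    Thresholds default to the caller's standard filter set: MAPQ >= 20,
    base quality >= 20, depth >= 3, homoplasmy fraction 0.9, then a
    MAF >= 0.05 / >= 3-carrier locus filter, missing data treated as
    reference, and exact (0-mismatch) parentage matching.
    """

    ref_fasta: str = ""
    sam_dir: str = ""
    annotation_tsv: str = ""
    pedigree_tsv: str = ""
    out_dir: str = "cpkin_run"
    min_depth: int = 3
    min_mapq: int = 20
    min_baseq: int = 20
    homoplasmy: float = 0.9
    maf_min: float = 0.05
    min_carriers: int = 3
    max_mismatch: int = 0
    n_policy: str = AS_REFERENCE
    bootstrap_reps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.homoplasmy <= 1.0:
            raise ValueError("homoplasmy must be in [0, 1]")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if min(self.min_depth, self.min_mapq, self.min_baseq) < 0:
            raise ValueError("thresholds must be non-negative")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write results under ``config.out_dir``.

    Outputs: per-run config + hash, multi-sample VCF and TSV matrices (raw and
    frequency-filtered), a coverage report, an annotation summary (if an
    annotation was given), per-progeny match reports (if a pedigree or
    parseable sample labels are available), and a bootstrap NJ tree in Newick.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, p in (("reference", config.ref_fasta), ("SAM directory", config.sam_dir)):
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"{name} not found: {p!r}")
    ref = ReferenceGenome.from_fasta(config.ref_fasta)
    sam_files = sorted(Path(config.sam_dir).glob("*.sam")) + sorted(
        Path(config.sam_dir).glob("*.bam")
    )
    if not sam_files:
        raise FileNotFoundError(f"no SAM/BAM files in {config.sam_dir!r}")
    log.info(
        "calling %d samples (mapq>=%d baseq>=%d depth>=%d homoplasmy>=%.2f)",
        len(sam_files), config.min_mapq, config.min_baseq, config.min_depth, config.homoplasmy,
    )

    calls_by_sample, coverage, pileups = {}, [], {}
    for f in sam_files:
        sample = f.stem
        reads = list(
            calling.filter_reads(calling.read_sam(f), config.min_mapq)
        )
        pile = calling.build_pileup(reads, ref, config.min_baseq)
        pileups[sample] = pile
        cov = pile.coverage_stats(sample)
        coverage.append(cov)
        calls = []
        for p in pile.covered_positions():
            c = calling.call_site(
                pile.column(int(p)), config.homoplasmy, config.min_depth, sample
            )
            if c.status != calling.REF:
                calls.append(c)
        calls_by_sample[sample] = calls

    # union of ALT positions across cohort, then re-genotype every sample there
    positions = sorted(
        {c.position for cs in calls_by_sample.values() for c in cs if c.status == calling.ALT}
    )
    full_calls = {
        s: calling.call_at_sites(pileups[s], positions, config.homoplasmy, config.min_depth, s)
        for s in calls_by_sample
    }
    matrix = build_matrix(full_calls, positions, chrom=ref.id)
    filtered = filter_loci(
        matrix, config.maf_min, config.min_carriers, n_policy=config.n_policy
    )
    log.info("matrix: %d loci called, %d retained after frequency filter",
             matrix.n_loci, filtered.n_loci)

    with open(out / "coverage.tsv", "w") as fh:
        fh.write("sample\tmean_depth\tbreadth_1x\n")
        for cov in coverage:
            fh.write(f"{cov.sample}\t{cov.mean_depth:.4f}\t{cov.breadth_1x:.4f}\n")
    matrix.to_tsv(out / "matrix_raw.tsv")
    filtered.to_tsv(out / "matrix_filtered.tsv")
    filtered.to_vcf(out / "matrix_filtered.vcf")

    if config.annotation_tsv:
        ann = GeneAnnotation.from_tsv(config.annotation_tsv)
        summary = summarize_annotation(filtered, ann, total_discovered=matrix.n_loci)
        summary.to_tsv(out / "annotation_summary.tsv")

    reports = []
    if config.pedigree_tsv:
        ped = kinship.Pedigree.from_tsv(config.pedigree_tsv)
        labelled = kinship.pedigree_from_labels(filtered.samples)
        ped.ramets = ped.ramets or labelled.ramets
        reports = kinship.classify_cohort(ped, filtered, config.n_policy, config.max_mismatch)
    else:
        ped = kinship.pedigree_from_labels(filtered.samples)
        if ped.progeny and ped.ramets:
            reports = kinship.classify_cohort(ped, filtered, config.n_policy, config.max_mismatch)
    if reports:
        kinship.reports_to_tsv(reports, out / "match_reports.tsv")
        (out / "match_reports.json").write_text(
            "[" + ",".join(r.to_json() for r in reports) + "]"
        )

    if filtered.n_samples >= 3 and filtered.n_loci >= 1:
        tree = phylo.bootstrap_support(
            filtered, n_reps=config.bootstrap_reps, seed=config.seed, n_policy=config.n_policy
        )
        phylo.write_newick(tree, out / "tree.nwk")

    config.to_json(out / "config.json")
    (out / "run.json").write_text(
        json.dumps(
            {
                "config_hash": config.digest(),
                "seed": config.seed,
                "n_samples": matrix.n_samples,
                "n_loci_called": matrix.n_loci,
                "n_loci_filtered": filtered.n_loci,
                "n_match_reports": len(reports),
            },
            indent=2,
        )
    )
    return out
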
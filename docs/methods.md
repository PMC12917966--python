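# Methods

## Transmission model and assumptions

The analysis assumes Pinaceae-type chloroplast inheritance: each offspring
receives its pollen parent's chloroplast genome as a single, non-recombining,
effectively haploid haplotype. Within an individual the chloroplast is
assumed homoplasmic; sites where read evidence is mixed are treated as
uncallable rather than genotyped. Coordinates are 1-based on the forward
strand of a single circular reference, and only biallelic substitutions are
modelled — indels, rearrangements, and structural heteroplasmy are out of
scope.

Under this model, parentage verification reduces to exact string matching
over a SNP panel. Three processes can break an exact father–offspring match:

* **de novo substitution** — Poisson with mean `E = μ·L·g` per transmitted
  haplotype (`μ` substitutions·site⁻¹·year⁻¹, `L` bp, `g` years per
  generation). At pine-like values (`μ = 0.2e-9`, `L = 121 kb`, `g = 25 y`)
  `E ≈ 6.05e-4`, so ≥ 1 private SNP occurs in < 0.1 % of transmissions and
  ≥ 3 in ~4e-11 — multi-SNP discrepancies are never mutational.
* **maternal leakage** — transmission through the seed parent, reported at
  ≤ 1 % in conifers. `leakage_test(k, n, p0)` gives the exact upper-tail
  binomial probability of observing `k` of `n` discordant progeny under a
  null leakage rate `p0`; no normal approximation is used because progeny
  arrays are small (tens).
* **pollen contamination** — fertilization by an unsampled male; detected as
  a progeny haplotype matching no sampled clone (`NOVEL`) or matching a
  sampled clone other than the recorded parents (`ALTERNATE_FATHER`).

## SNP caller

Four filters, applied in order: (i) read level — properly paired, uniquely
mapped reads only, operationalized as MAPQ ≥ 20 plus exclusion of
secondary/supplementary records (MAPQ is the only uniqueness signal
retained in a SAM record); (ii) base level — bases with quality < 20 are
excluded from pileup counts; (iii) depth — a site needs ≥ 3 *post-filter*
bases to be callable, otherwise `MISSING`/`N`; (iv) homoplasmy — the major
base must reach a configurable fraction of filtered depth, default 0.9.
The 0.9 default reflects the practical detection limit of chromatogram-based
verification (minor components below ~10–15 % go unseen), so a site with
> 10 % minor signal is excluded as putative heteroplasmy rather than forced
to a genotype. Ties for the major base are never broken arbitrarily: a tied
column is `N`. All thresholds are boundary-inclusive (MAPQ 20, Q20, depth 3
pass). Whether depth is measured before or after base-quality filtering is a
genuine ambiguity; this implementation uses post-filter depth, and the
threshold is exposed for sensitivity analysis.

Raising the homoplasmy threshold is monotone: it can only withdraw calls
(REF/ALT → N), never create them or flip REF↔ALT — this is property-tested
against an independent exact-rational oracle exhaustively to depth 6.

## Matrix, missing data, and the frequency filter

Cells use the organellar haplotype-table encoding: `-` reference, base letter
alternative, `N` missing/excluded. The default *N-as-reference* policy
substitutes the reference state for `N` in every comparison and denominator;
`pairwise-drop` instead removes N cells from the relevant comparison and is
available as a sensitivity switch.

The locus filter keeps loci with carrier count ≥ 3 and **non-reference
allele frequency** ≥ 5 %. The non-reference (rather than folded minor)
allele is thresholded deliberately: loci where the alternative base is
nearly universal are fixed differences between the study germplasm and the
reference accession — informative, and retained — whereas folding would
discard them (a 53/54 locus has a folded MAF of 1.9 %). Folded MAF is still
reported by `minor_allele_frequency()`. A carrier is any sample whose cell
is a non-reference base letter; matrices *loaded* from external tables
tolerate a stray second alternative letter (and count it as a carrier),
while matrices *built* from calls enforce strict biallelism and raise on
conflicting alternative bases.

## Parentage classification

Each parent clone may be represented by several ramets (clonal copies).
A clone's comparison haplotype is the majority consensus across its ramets;
any locus at which ramets disagree (under the N policy) is masked out of
that clone's comparisons and reported by `ramet_consistency` — one deviant
ramet can therefore neither veto nor fabricate a match. A clone matches a
progeny when the progeny row differs from the consensus at ≤ `max_mismatch`
unmasked loci (default 0, exact matching; the de novo expectation report
guides any relaxation). Classification priority: recorded father → recorded
mother → unique other clone (`ALTERNATE_FATHER`) → several distinct clones
(`AMBIGUOUS`, with the tie set) → none (`NOVEL`). Progeny of unsampled
parents can additionally be screened with `family_uniformity`: full sibs of
a single true donor share one haplotype even when that donor was never
genotyped.

Exact matching interacts with missing data: under N-as-reference, a site
that is `N` in the progeny but alternative in the father counts as a
mismatch. At ~12× coverage this demotes a small fraction of true paternal
progeny to `NOVEL` (about 5 % in the end-to-end simulation at 32 panel
sites); it never produces a wrong positive assignment, which is the
conservative direction for pedigree verification.

## Clustering

The tree stage serves a clustering purpose — showing maternal exclusion and
paternal haplogroups — not phylogenetic inference, so it uses
neighbor-joining on pairwise haplotype mismatch counts rather than a
likelihood search. NJ is exact on additive matrices (property-tested on
random integer-length trees of 4–8 taxa) and deterministic here; negative
branch lengths are clamped to zero, and zero-length internal edges are
collapsed into polytomies by default so groups of identical haplotypes
appear as unresolved clusters rather than arbitrary binary resolutions
(identical haplotypes are kept as separate leaves). Supports come from
resampling SNP columns with replacement (default 1000 replicates, seeded)
and counting the recurrence of each internal bipartition of the full-data
tree. Because the distance treats the SNP concatenation without its
invariant context, support values are not comparable to values printed by
model-based analyses of the same data.

## Synthetic cohorts: what they emulate, and what they don't

Defaults are the study conditions this package targets: a 9 × 5 tester
design (45 progeny, one per cross), a 121 kb circular reference segregating
at 32 biallelic sites, strictly paternal transmission with a 20 %
contamination rate (the discordance level the assay is meant to flag), zero
leakage, `μ = 0.2e-9`, `g = 25 y`, 150 bp reads at 12.3× mean depth, 0.2 %
base-error rate, and a 5 % fraction of reads that are low-MAPQ or improperly
paired. Contaminating donors are drawn from an external pool that segregates
at the same panel sites (stray pollen comes from the same population) plus a
few private markers guaranteeing distinctness from every sampled parent.
Erroneous bases receive degraded qualities (uniform Q10–Q40), so roughly a
third of errors are removed by the Q20 filter, as in real data.

Not emulated: origin-spanning reads (circularity is recorded but reads stop
at the coordinate end), insert-size structure beyond the proper-pair flag,
duplicate reads, mapping bias around the inverted repeat, indels, and
coverage heterogeneity beyond uniform sampling. Passing simulation tests
therefore demonstrates correctness of the calling/matching logic under a
clean error model, not robustness to alignment artefacts of real repeat-rich
chloroplast data.

## Problem sizes and numerical choices

Test and acceptance runs use reduced problem sizes chosen to keep the full
suite fast while leaving every rate estimable: 4–20 kb references for
read-level simulations (the 121 kb default is exercised at the haplotype
level, e.g. 10⁵ transmissions for the Poisson-mean check), 500 progeny for
contamination-rate recovery (99 % binomial CI half-width ±4.6 % at c = 0.2),
10⁶ draws for Monte-Carlo cross-checks of exact tails, and 100–200 bootstrap
replicates in pipeline tests (1000 remains the CLI default). All generators
are `numpy.random.default_rng` streams with explicit seeds; fixed seeds give
bit-reproducible outputs, including byte-identical SAM, TSV, and Newick
files. Statistical checks on simulated rates use 99 % binomial confidence
intervals or 3-standard-error bands rather than exact equality.

Degenerate inputs are defined rather than accidental: zero reads yield zero
calls and zero breadth; an all-reference column has zero carriers; an
all-zero distance matrix yields a star tree; a single replicate yields
supports in {0, 100}; empty pedigrees, singleton matrices, sub-minimum ramet
sets, and out-of-span annotation queries raise typed errors.

## Known limitations

* Exact matching is conservative under missing data (see above); raising
  `max_mismatch` trades that against sensitivity to true discordance, and
  should be guided by the de novo expectation (≤ 1 even at generous rates).
* The caller performs no realignment, BAQ, duplicate marking, or indel
  handling; columns are taken as aligned.
* Annotation is by literal coordinate; a locus inside the inverted repeat is
  annotated at its own copy only.
* Likelihood-based parentage (LOD scores, exclusion probabilities) is out of
  scope — the assay is exact-match by design, reflecting the effectively
  clonal transmission of the chloroplast.
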
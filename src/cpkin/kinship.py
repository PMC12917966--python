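"""Haplotype-based parentage verification under paternal organelle inheritance.

Given a genotype matrix, a pedigree of recorded crosses, and a mapping from
parent clones to their sampled ramets, each progeny is classified by exact
haplotype matching:

* ``PATERNAL_MATCH`` — identical (within ``max_mismatch``) to the recorded
  father's clone haplotype: the expected outcome in pines;
* ``MATERNAL_MATCH`` — identical to the recorded mother instead (organelle
  leakage through the seed parent);
* ``ALTERNATE_FATHER`` — identical to exactly one other sampled clone
  (mislabelling or pollen from a known but unintended donor);
* ``AMBIGUOUS`` — identical to more than one clone with distinct identities;
* ``NOVEL`` — matches no sampled clone (pollen contamination from an
  unsampled male, or an unsampled recorded parent).

Missing genotypes are handled by the *N policy* (see :mod:`cpkin.matrix`):
under ``as-reference`` an ``N`` is replaced by the reference state before
comparison, so every locus is compared.

Two small statistical helpers quantify whether observed discordance can be
explained away: the Poisson expectation for de novo substitutions per
generation (``mu * L * g``) and an exact upper-tail binomial test of the
observed discordant fraction against a null leakage rate.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .matrix import AS_REFERENCE, PAIRWISE_DROP, GenotypeMatrix, _check_policy

PATERNAL_MATCH = "PATERNAL_MATCH"
MATERNAL_MATCH = "MATERNAL_MATCH"
ALTERNATE_FATHER = "ALTERNATE_FATHER"
NOVEL = "NOVEL"
AMBIGUOUS = "AMBIGUOUS"


class IncompatibleMatricesError(ValueError):
    pass


class InsufficientCandidatesError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pedigree


@dataclass
class ProgenyRecord:
    progeny_id: str
    mother: str
    father: str


@dataclass
class Pedigree:
    """Recorded crosses plus the clone -> sampled-ramet mapping.

    A clone with no ramets in ``ramets`` is an unsampled parent; its progeny
    can never produce a ``PATERNAL_MATCH``/``MATERNAL_MATCH`` against it.
    """

    progeny: list[ProgenyRecord]
    ramets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_id = {p.progeny_id: p for p in self.progeny}

    def record(self, progeny_id: str) -> ProgenyRecord:
        try:
            return self._by_id[progeny_id]
        except KeyError:
            raise KeyError(f"progeny {progeny_id!r} not in pedigree") from None

    def sampled(self, clone: str) -> bool:
        return bool(self.ramets.get(clone))

    def clones(self) -> list[str]:
        return sorted(self.ramets)

    @classmethod
    def from_tsv(
        cls, path: str | Path, ramets: Mapping[str, Sequence[str]] | None = None
    ) -> "Pedigree":
        """Read ``progeny_id, mother_id, father_id`` records (header required)."""
        lines = Path(path).read_text().splitlines()
        recs = []
        for line in lines[1:]:
            if not line.strip():
                continue
            pid, m, f = line.split("\t")[:3]
            recs.append(ProgenyRecord(pid, m, f))
        return cls(recs, {k: list(v) for k, v in (ramets or {}).items()})

    def to_tsv(self, path: str | Path | None = None) -> str:
        text = "progeny_id\tmother_id\tfather_id\n" + "".join(
            f"{p.progeny_id}\t{p.mother}\t{p.father}\n" for p in self.progeny
        )
        if path is not None:
            Path(path).write_text(text)
        return text


_PROGENY_RE = re.compile(r"^F(?P<father>[^_]+)_M(?P<mother>[^_]+)_(?P<index>\d+)$")


def parse_sample_label(label: str) -> dict[str, str]:
    """Decode the two field-labelling schemes used on sample names.

    ``"F222_M014_5"`` is progeny 5 of paternal clone 222 x maternal clone 014;
    ``"014 K1-9-10"`` (or ``"222-I4-15"``) is a parental ramet: clone id then a
    planting-position code.  Returns a dict with ``kind`` = ``"progeny"`` or
    ``"parent"`` and the decoded fields.
    """
    m = _PROGENY_RE.match(label)
    if m:
        return {"kind": "progeny", **m.groupdict()}
    parts = re.split(r"[ \-]", label, maxsplit=1)
    if len(parts) == 2 and parts[0]:
        return {"kind": "parent", "clone": parts[0], "ramet": parts[1]}
    return {"kind": "parent", "clone": label, "ramet": ""}


def pedigree_from_labels(sample_ids: Sequence[str]) -> Pedigree:
    """Build a pedigree directly from labelled matrix sample ids."""
    recs, ramets = [], {}
    for s in sample_ids:
        info = parse_sample_label(s)
        if info["kind"] == "progeny":
            recs.append(ProgenyRecord(s, info["mother"], info["father"]))
        else:
            ramets.setdefault(info["clone"], []).append(s)
    return Pedigree(recs, ramets)


# ---------------------------------------------------------------------------
# distances


def _apply_policy(row: np.ndarray, n_policy: str) -> np.ndarray:
    row = np.asarray(row, dtype="<U1")
    if n_policy == AS_REFERENCE:
        out = row.copy()
        out[out == "N"] = "-"
        return out
    return row


def haplotype_distance(
    row_a: Sequence[str], row_b: Sequence[str], n_policy: str = AS_REFERENCE
) -> tuple[int, int]:
    """Mismatch count between two genotype rows over a shared locus set.

    Returns ``(n_compared, n_mismatch)``.  Under ``as-reference`` every locus is
    compared (``N`` := reference); under ``pairwise-drop`` loci where either row
    is ``N`` are skipped.  Symmetric in its arguments.
    """
    _check_policy(n_policy)
    a = np.asarray(row_a, dtype="<U1")
    b = np.asarray(row_b, dtype="<U1")
    if a.shape != b.shape:
        raise IncompatibleMatricesError(
            f"rows compare {a.shape[0]} vs {b.shape[0]} loci"
        )
    if n_policy == AS_REFERENCE:
        a, b = _apply_policy(a, n_policy), _apply_policy(b, n_policy)
        mask = np.ones(a.shape, dtype=bool)
    else:
        mask = (a != "N") & (b != "N")
    return int(mask.sum()), int(np.sum(a[mask] != b[mask]))


# ---------------------------------------------------------------------------
# clone consensus / ramet consistency


@dataclass
class RametConflict:
    position: int
    cells: dict[str, str]  # ramet sample id -> cell


def ramet_consistency(
    clone: str,
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    n_policy: str = AS_REFERENCE,
) -> list[RametConflict]:
    """Loci at which the sampled ramets of one clone disagree.

    Ramets are clonal copies of a single genotype, so any disagreement flags a
    genotyping error or a labelling/grafting mix-up.  Under ``as-reference``,
    ``N`` vs reference is not a conflict.  Requires >= 2 sampled ramets.
    """
    ramets = [r for r in pedigree.ramets.get(clone, []) if r in matrix]
    if len(ramets) < 2:
        raise InsufficientCandidatesError(f"clone {clone!r} has < 2 sampled ramets")
    rows = {r: _apply_policy(matrix.row(r), n_policy) for r in ramets}
    conflicts = []
    for j, loc in enumerate(matrix.loci):
        cells = {r: rows[r][j] for r in ramets}
        vals = set(cells.values())
        if n_policy == PAIRWISE_DROP:
            vals -= {"N"}
        if len(vals) > 1:
            conflicts.append(
                RametConflict(loc.position, {r: str(matrix.row(r)[j]) for r in ramets})
            )
    return conflicts


def clone_consensus(
    clone: str,
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    n_policy: str = AS_REFERENCE,
) -> tuple[np.ndarray, np.ndarray]:
    """Majority haplotype across a clone's ramets plus a comparison mask.

    Conflicting loci (ramets disagreeing under the N policy) are masked out of
    the clone's comparisons entirely, so a single bad ramet cannot veto or
    fabricate a parent-progeny match.  Returns ``(consensus_row, mask)``.
    """
    ramets = [r for r in pedigree.ramets.get(clone, []) if r in matrix]
    if not ramets:
        raise InsufficientCandidatesError(f"clone {clone!r} has no sampled ramets")
    rows = np.stack([_apply_policy(matrix.row(r), n_policy) for r in ramets])
    consensus = rows[0].copy()
    mask = np.ones(rows.shape[1], dtype=bool)
    for j in range(rows.shape[1]):
        vals, counts = np.unique(rows[:, j], return_counts=True)
        if n_policy == PAIRWISE_DROP:
            keep = vals != "N"
            vals, counts = vals[keep], counts[keep]
            if vals.size == 0:
                consensus[j] = "N"
                continue
        if len(vals) > 1:
            mask[j] = False
            consensus[j] = vals[np.argmax(counts)]
        else:
            consensus[j] = vals[0]
    return consensus, mask


# ---------------------------------------------------------------------------
# classification


@dataclass
class MatchReport:
    progeny_id: str
    mode: str
    assigned_donor: str | None
    recorded_mother: str
    recorded_father: str
    tie_set: list[str] = field(default_factory=list)
    distances: dict[str, tuple[int, int]] = field(default_factory=dict)  # sample -> (n, mm)
    clone_distances: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def classify_progeny(
    progeny_id: str,
    pedigree: Pedigree,
    matrix: GenotypeMatrix,
    n_policy: str = AS_REFERENCE,
    max_mismatch: int = 0,
) -> MatchReport:
    """Classify one progeny's inheritance mode by exact haplotype matching.

    A clone "matches" when the progeny row differs from the clone consensus at
    <= ``max_mismatch`` unmasked loci.  Priority: recorded father, then
    recorded mother, then a unique other clone; several non-recorded matches
    give ``AMBIGUOUS``; none gives ``NOVEL``.
    """
    if progeny_id not in matrix:
        raise KeyError(f"progeny {progeny_id!r} not present in matrix")
    rec = pedigree.record(progeny_id)
    candidates = [c for c in pedigree.clones() if pedigree.sampled(c) and
                  any(r in matrix for r in pedigree.ramets[c])]
    if not candidates:
        raise InsufficientCandidatesError("no sampled candidate clones in matrix")
    prow = _apply_policy(matrix.row(progeny_id), n_policy)

    distances: dict[str, tuple[int, int]] = {}
    clone_distances: dict[str, tuple[int, int]] = {}
    matches: list[str] = []
    for clone in candidates:
        for ramet in pedigree.ramets[clone]:
            if ramet in matrix:
                distances[ramet] = haplotype_distance(prow, matrix.row(ramet), n_policy)
        consensus, mask = clone_consensus(clone, matrix, pedigree, n_policy)
        if n_policy == PAIRWISE_DROP:
            mask = mask & (prow != "N") & (consensus != "N")
        n_cmp = int(mask.sum())
        mm = int(np.sum(prow[mask] != consensus[mask]))
        clone_distances[clone] = (n_cmp, mm)
        if mm <= max_mismatch:
            matches.append(clone)

    if rec.father in matches:
        mode, donor, ties = PATERNAL_MATCH, rec.father, []
    elif rec.mother in matches:
        mode, donor, ties = MATERNAL_MATCH, rec.mother, []
    elif len(matches) == 1:
        mode, donor, ties = ALTERNATE_FATHER, matches[0], []
    elif len(matches) > 1:
        mode, donor, ties = AMBIGUOUS, None, sorted(matches)
    else:
        mode, donor, ties = NOVEL, None, []
    return MatchReport(
        progeny_id=progeny_id,
        mode=mode,
        assigned_donor=donor,
        recorded_mother=rec.mother,
        recorded_father=rec.father,
        tie_set=ties,
        distances=distances,
        clone_distances=clone_distances,
    )


def classify_cohort(
    pedigree: Pedigree,
    matrix: GenotypeMatrix,
    n_policy: str = AS_REFERENCE,
    max_mismatch: int = 0,
) -> list[MatchReport]:
    return [
        classify_progeny(p.progeny_id, pedigree, matrix, n_policy, max_mismatch)
        for p in pedigree.progeny
        if p.progeny_id in matrix
    ]


def reports_to_tsv(reports: Sequence[MatchReport], path: str | Path | None = None) -> str:
    buf = io.StringIO()
    buf.write("progeny_id\trecorded_mother\trecorded_father\tmode\tassigned_donor\ttie_set\n")
    for r in reports:
        buf.write(
            f"{r.progeny_id}\t{r.recorded_mother}\t{r.recorded_father}\t{r.mode}\t"
            f"{r.assigned_donor or 'NONE'}\t{','.join(r.tie_set)}\n"
        )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def family_uniformity(
    progeny_ids: Sequence[str], matrix: GenotypeMatrix, n_policy: str = AS_REFERENCE
) -> dict[tuple[str, str], int]:
    """Pairwise mismatch counts within a family (e.g. progeny of an unsampled
    father): an all-zero result means the sibs share one haplotype, consistent
    with a single common pollen donor."""
    out = {}
    for i, a in enumerate(progeny_ids):
        for b in progeny_ids[i + 1 :]:
            _, mm = haplotype_distance(matrix.row(a), matrix.row(b), n_policy)
            out[(a, b)] = mm
    return out


# ---------------------------------------------------------------------------
# expectation statistics


@dataclass
class DeNovoExpectation:
    mu: float
    L: int
    generation_years: float
    k: int
    expected_count: float
    p_ge_k: float


def expected_de_novo(
    mu: float, L: int, generation_years: float, k: int = 1
) -> DeNovoExpectation:
    """Poisson expectation for de novo substitutions on one transmitted haplotype.

    ``expected_count = mu * L * g``;  ``p_ge_k = P[Poisson(expected_count) >= k]``.
    With pine chloroplast rates (mu ~ 0.2e-9 /site/year, L = 121 kb, g = 25 y)
    the expectation is ~6e-4, so even a single de novo SNP per cross is rare
    and multi-SNP parent-offspring discrepancies cannot be mutational.
    """
    if mu < 0 or L <= 0 or generation_years <= 0 or k < 0:
        raise ValueError("mu must be >= 0; L, generation_years positive; k >= 0")
    lam = mu * L * generation_years
    return DeNovoExpectation(
        mu=mu,
        L=L,
        generation_years=generation_years,
        k=k,
        expected_count=lam,
        p_ge_k=float(stats.poisson.sf(k - 1, lam)),
    )


@dataclass
class LeakageTest:
    n_discordant: int
    n_total: int
    leakage_rate_null: float
    observed_fraction: float
    p_value: float


def leakage_test(
    n_discordant: int, n_total: int, leakage_rate_null: float = 0.01
) -> LeakageTest:
    """Exact upper-tail binomial test of discordant-progeny frequency.

    Tests whether observing ``n_discordant`` of ``n_total`` progeny with a
    non-paternal haplotype is compatible with a null organelle-leakage rate
    (conifer literature reports <= 1%).  ``p = P[Bin(n, p0) >= k]``, computed
    exactly — no normal approximation, since progeny arrays are small.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_discordant <= n_total:
        raise ValueError("n_discordant must be in [0, n_total]")
    if not 0.0 <= leakage_rate_null <= 1.0:
        raise ValueError("leakage_rate_null must be a probability")
    p = float(stats.binom.sf(n_discordant - 1, n_total, leakage_rate_null))
    return LeakageTest(
        n_discordant=n_discordant,
        n_total=n_total,
        leakage_rate_null=leakage_rate_null,
        observed_fraction=n_discordant / n_total,
        p_value=min(p, 1.0),
    )


# ---------------------------------------------------------------------------
# matrix concordance (e.g. short-read calls vs Sanger re-genotyping)


@dataclass
class ConcordanceReport:
    n_samples: int
    n_loci: int
    overall: float
    per_locus: dict[int, float]
    per_sample: dict[str, float]
    disagreements: list[tuple[str, int, str, str]]  # sample, position, cell_a, cell_b


def concordance(matrix_a: GenotypeMatrix, matrix_b: GenotypeMatrix) -> ConcordanceReport:
    """Cell-level agreement between two genotype matrices.

    Samples and loci are intersected first; agreement is computed only over
    cells that are non-``N`` in both matrices (a platform that could not call a
    site neither confirms nor contradicts the other).
    """
    samples = [s for s in matrix_a.samples if s in matrix_b]
    positions = sorted(set(matrix_a.positions) & set(matrix_b.positions))
    if not samples or not positions:
        raise IncompatibleMatricesError("matrices share no samples or no loci")
    a = matrix_a.subset(samples, positions)
    b = matrix_b.subset(samples, positions)
    valid = (a.cells != "N") & (b.cells != "N")
    agree = (a.cells == b.cells) & valid
    overall = float(agree.sum() / valid.sum()) if valid.sum() else 1.0
    per_locus = {}
    for j, p in enumerate(positions):
        v = valid[:, j]
        per_locus[p] = float(agree[:, j].sum() / v.sum()) if v.sum() else 1.0
    per_sample = {}
    for i, s in enumerate(samples):
        v = valid[i]
        per_sample[s] = float(agree[i].sum() / v.sum()) if v.sum() else 1.0
    disagreements = [
        (samples[i], positions[j], str(a.cells[i, j]), str(b.cells[i, j]))
        for i, j in zip(*np.nonzero(valid & ~agree))
    ]
    return ConcordanceReport(
        n_samples=len(samples),
        n_loci=len(positions),
        overall=overall,
        per_locus=per_locus,
        per_sample=per_sample,
        disagreements=disagreements,
    )
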
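"""Shared fixtures: small simulated cohorts and a synthetic tester-design matrix."""

from __future__ import annotations

import numpy as np
import pytest

import cpkin as ck
from cpkin.matrix import GenotypeMatrix, Locus


@pytest.fixture(scope="session")
def small_ref():
    return ck.simulate_reference(5000, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_ref):
    """Six parents (3 mothers, 3 fathers) segregating at 12 sites."""
    haps, sites = ck.simulate_parents(small_ref, 6, 12, seed=12, prefix="")
    mothers, fathers = ["101", "102", "103"], ["201", "202", "203"]
    renamed = {new: haps[old] for new, old in zip(mothers + fathers, haps)}
    return renamed, sites, mothers, fathers


# ---------------------------------------------------------------------------
# Synthetic reconstruction of a 9 x 5 tester design (75 samples x 19 SNPs).
#
# This is a synthetic stand-in, not real genotype data: it is constructed to
# exhibit the family structure such a design produces — 30 parental ramets
# (8 maternal clones with one ramet each; paternal
# clones W03 x1, N4 x7, S1 x7, 222 x7; paternal clone S2 unsampled) and 45
# progeny, of which 11 carry the W03 haplotype (the 8 S1-family progeny, two
# stray N4-family progeny, and W03's own offspring), the 222 family matches
# the 222 consensus, the S2 family shares a private uniform haplotype, and
# nine progeny carry three external (contaminant) haplotypes.  One 222 ramet
# (222 I4-15) deviates from its clone mates at position 101157 only.

TESTER_POSITIONS = [
    10348, 14321, 23167, 23593, 29449, 37238, 45193, 68985, 97585, 98314,
    101103, 101121, 101130, 101139, 101148, 101157, 118329, 119153, 119714,
]
_TESTER_REF = list("TGGCTTGGTGTTTGGTCGC")
_TESTER_ALT = list("ATAAGATTGTGGGTTGATT")

# carried alt-site indices per haplotype lineage
_LINEAGES = {
    "W03": {0, 10, 11},
    "N4": {1, 12},
    "S1": {2, 13},
    "222": {3, 14},
    "222_I4_15": {3, 14, 15},  # ramet-private deviation at 101157
    "S2grp": {4, 16},
    "ext1": {5, 8},
    "ext2": {5, 9},
    "ext3": {8, 9},
}
_MOTHER_CLONES = ["014", "017", "201", "202", "243", "259", "288", "P100"]


def _tester_row(pattern: set[int]) -> list[str]:
    return [_TESTER_ALT[j] if j in pattern else "-" for j in range(19)]


def build_tester_matrix() -> GenotypeMatrix:
    samples, rows = [], []

    def add(sample: str, pattern: set[int]) -> None:
        samples.append(sample)
        rows.append(_tester_row(pattern))

    # maternal ramets: each mother distinct, sharing the near-fixed alts (6, 7)
    for i, m in enumerate(_MOTHER_CLONES):
        add(f"{m} K1-1-{i + 1}", {6, 7, i})
    # paternal ramets
    add("W03 L1-1-1", _LINEAGES["W03"])
    for i in range(7):
        add(f"N4 L2-1-{i + 1}", _LINEAGES["N4"])
    for i in range(7):
        add(f"S1 L1-3-{i + 1}", _LINEAGES["S1"])
    add("222 I7-2", _LINEAGES["222"])
    add("222 I4-15", _LINEAGES["222_I4_15"])
    for i in range(5):
        add(f"222 I1-{i + 1}", _LINEAGES["222"])

    mothers = _MOTHER_CLONES + ["W16"]  # ninth mother unsampled

    def prog(father: str, k: int, pattern: set[int], mother: str) -> None:
        add(f"F{father}_M{mother}_{k}", pattern)

    for i in range(7):  # N4 family: true paternal
        prog("N4", i + 1, _LINEAGES["N4"], mothers[i % 9])
    for i in range(2):  # two stray N4-family progeny sired by W03
        prog("N4", i + 8, _LINEAGES["W03"], mothers[(7 + i) % 9])
    for i in range(8):  # S1 family: all carry the W03 haplotype
        prog("S1", i + 1, _LINEAGES["W03"], mothers[i % 9])
    prog("W03", 1, _LINEAGES["W03"], mothers[0])  # W03's own offspring
    for i in range(9):  # 222 family: match the clone consensus
        prog("222", i + 1, _LINEAGES["222"], mothers[i % 9])
    for i in range(9):  # S2 family: father unsampled, uniform private haplotype
        prog("S2", i + 1, _LINEAGES["S2grp"], mothers[i % 9])
    for i in range(9):  # contaminant progeny from three external donors
        father = ["N4", "222", "S2"][i % 3]
        prog(father, 10 + i // 3, _LINEAGES[f"ext{i % 3 + 1}"], mothers[i % 9])

    loci = [
        Locus(p, r, a) for p, r, a in zip(TESTER_POSITIONS, _TESTER_REF, _TESTER_ALT)
    ]
    return GenotypeMatrix(samples, loci, rows)


@pytest.fixture(scope="session")
def tester_matrix() -> GenotypeMatrix:
    return build_tester_matrix()


@pytest.fixture(scope="session")
def tester_pedigree_obj(tester_matrix) -> ck.Pedigree:
    return ck.pedigree_from_labels(tester_matrix.samples)


@pytest.fixture(scope="session")
def noiseless_config():
    return ck.SimulationConfig(
        n_mothers=3,
        n_fathers=3,
        contamination_rate=0.0,
        leakage_rate=0.0,
        de_novo_mu=0.0,
        genome_length=5000,
        depth_mean=10.0,
        read_length=100,
        base_error_rate=0.0,
        frac_low_mapq=0.0,
        seed=5,
    )
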
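"""Haplotype matching, parentage classification, and discordance statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cpkin as ck
from cpkin.kinship import (
    InsufficientCandidatesError,
    clone_consensus,
    family_uniformity,
    reports_to_tsv,
)
from cpkin.matrix import GenotypeMatrix, Locus


def _mat(rows: dict, refs="AAAA", alts="CCCC"):
    loci = [Locus(10 * (j + 1), refs[j], alts[j]) for j in range(len(refs))]
    return GenotypeMatrix(list(rows), loci, [list(r) for r in rows.values()])


class TestDistance:
    def test_identity(self):
        m = _mat({"a": "-C-N", "b": "-C-N"})
        assert ck.haplotype_distance(m.row("a"), m.row("b")) == (4, 0)

    def test_single_mismatch(self):
        m = _mat({"a": "----", "b": "--C-"})
        assert ck.haplotype_distance(m.row("a"), m.row("b")) == (4, 1)

    def test_n_treated_as_reference(self):
        m = _mat({"a": "N---", "b": "----"})
        assert ck.haplotype_distance(m.row("a"), m.row("b")) == (4, 0)
        # but N vs a carried alt IS a mismatch under as-reference
        m2 = _mat({"a": "N---", "b": "C---"})
        assert ck.haplotype_distance(m2.row("a"), m2.row("b")) == (4, 1)

    def test_pairwise_drop_policy(self):
        m = _mat({"a": "N--C", "b": "C--C"})
        assert ck.haplotype_distance(m.row("a"), m.row("b"), "pairwise-drop") == (3, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ck.kinship.IncompatibleMatricesError):
            ck.haplotype_distance(["-"], ["-", "-"])

    @given(st.integers(1, 30).flatmap(
        lambda n: st.tuples(*[st.lists(st.sampled_from("ACGT-N"), min_size=n, max_size=n)] * 3)
    ))
    @settings(max_examples=150, derandomize=True)
    def test_pseudometric(self, rows):
        """Symmetry, zero self-distance, triangle inequality."""
        a, b, c = rows
        dab = ck.haplotype_distance(a, b)[1]
        dba = ck.haplotype_distance(b, a)[1]
        dac = ck.haplotype_distance(a, c)[1]
        dcb = ck.haplotype_distance(c, b)[1]
        assert dab == dba
        assert ck.haplotype_distance(a, a)[1] == 0
        assert dab <= dac + dcb


class TestClassification:
    def test_s1_family_reassigned_to_w03(self, tester_matrix, tester_pedigree_obj):
        """Progeny recorded under S1 but carrying the W03 haplotype come out as
        ALTERNATE_FATHER with W03 as the assigned donor."""
        for i in range(1, 9):
            r = ck.classify_progeny(f"FS1_M{['014','017','201','202','243','259','288','P100','W16'][(i-1) % 9]}_{i}", tester_pedigree_obj, tester_matrix)
            assert r.mode == ck.ALTERNATE_FATHER
            assert r.assigned_donor == "W03"

    def test_paternal_match_families(self, tester_matrix, tester_pedigree_obj):
        reports = ck.classify_cohort(tester_pedigree_obj, tester_matrix)
        by_id = {r.progeny_id: r for r in reports}
        n4_true = [r for r in reports if r.recorded_father == "N4" and r.mode == ck.PATERNAL_MATCH]
        assert len(n4_true) == 7
        two22 = [r for r in reports if r.recorded_father == "222" and r.mode == ck.PATERNAL_MATCH]
        assert len(two22) == 9

    def test_unsampled_father_family_is_novel_but_uniform(self, tester_matrix, tester_pedigree_obj):
        s2 = [p.progeny_id for p in tester_pedigree_obj.progeny
              if p.father == "S2" and "_10" not in p.progeny_id and "_11" not in p.progeny_id and "_12" not in p.progeny_id]
        assert len(s2) == 9
        for pid in s2:
            assert ck.classify_progeny(pid, tester_pedigree_obj, tester_matrix).mode == ck.NOVEL
        assert all(mm == 0 for mm in family_uniformity(s2, tester_matrix).values())

    def test_no_progeny_matches_its_mother(self, tester_matrix, tester_pedigree_obj):
        reports = ck.classify_cohort(tester_pedigree_obj, tester_matrix)
        assert all(r.mode != ck.MATERNAL_MATCH for r in reports)

    def test_simulated_contamination_is_novel(self, small_panel):
        parents, sites, mothers, fathers = small_panel
        cfg = ck.SimulationConfig(
            n_mothers=3, n_fathers=3, contamination_rate=1.0, leakage_rate=0.0,
            de_novo_mu=0.0, genome_length=5000, seed=60,
        )
        ped = ck.tester_pedigree(mothers, fathers)
        progeny, truth = ck.simulate_cross(parents, ped, cfg)
        ref = ck.simulate_reference(5000, seed=11)
        # genotype panel must include the external donors' marker sites
        all_sites = sorted(
            set(sites)
            | {i + 1 for h in progeny.values() for i in range(len(h)) if h[i] != ref.sequence[i]}
        )
        gm = ck.haplotypes_to_matrix({**parents, **progeny}, ref, all_sites)
        pedo = ck.pedigree_from_labels(gm.samples)
        for pid, *_ in ped:
            assert ck.classify_progeny(pid, pedo, gm).mode == ck.NOVEL

    def test_missing_progeny_and_empty_candidates(self, tester_matrix, tester_pedigree_obj):
        with pytest.raises(KeyError):
            ck.classify_progeny("nope", tester_pedigree_obj, tester_matrix)
        lone = GenotypeMatrix(["FS1_M014_1"], tester_matrix.loci,
                              [tester_matrix.row("FS1_M014_1")])
        with pytest.raises(InsufficientCandidatesError):
            ck.classify_progeny("FS1_M014_1", tester_pedigree_obj, lone)

    def test_report_tsv_lists_every_progeny(self, tester_matrix, tester_pedigree_obj):
        reports = ck.classify_cohort(tester_pedigree_obj, tester_matrix)
        text = reports_to_tsv(reports)
        assert len(text.splitlines()) == len(reports) + 1


class TestRamets:
    def test_identical_ramets_no_conflict(self, tester_matrix, tester_pedigree_obj):
        assert ck.ramet_consistency("N4", tester_matrix, tester_pedigree_obj) == []

    def test_222_conflict_only_at_101157(self, tester_matrix, tester_pedigree_obj):
        conflicts = ck.ramet_consistency("222", tester_matrix, tester_pedigree_obj)
        assert [c.position for c in conflicts] == [101157]
        assert conflicts[0].cells["222 I4-15"] == "G"

    def test_injected_error_recovered(self, tester_matrix, tester_pedigree_obj):
        cells = tester_matrix.cells.copy()
        i = tester_matrix.samples.index("N4 L2-1-3")
        j = tester_matrix.positions.index(23167)
        cells[i, j] = "A"
        noisy = GenotypeMatrix(tester_matrix.samples, tester_matrix.loci, cells)
        conflicts = ck.ramet_consistency("N4", noisy, tester_pedigree_obj)
        assert [c.position for c in conflicts] == [23167]

    def test_conflicting_locus_masked_for_classification(self, tester_matrix, tester_pedigree_obj):
        # the 222 family still matches its father despite the deviant ramet
        r = ck.classify_progeny("F222_M014_1", tester_pedigree_obj, tester_matrix)
        assert r.mode == ck.PATERNAL_MATCH
        consensus, mask = clone_consensus("222", tester_matrix, tester_pedigree_obj)
        assert not mask[tester_matrix.positions.index(101157)]

    def test_single_ramet_rejected(self, tester_matrix, tester_pedigree_obj):
        with pytest.raises(InsufficientCandidatesError):
            ck.ramet_consistency("W03", tester_matrix, tester_pedigree_obj)


class TestLabels:
    def test_progeny_label(self):
        info = ck.parse_sample_label("F222_M014_5")
        assert info == {"kind": "progeny", "father": "222", "mother": "014", "index": "5"}

    def test_parent_label(self):
        info = ck.parse_sample_label("014 K1-9-10")
        assert info["kind"] == "parent" and info["clone"] == "014"
        assert ck.parse_sample_label("222-I4-15")["clone"] == "222"


class TestExpectations:
    def test_de_novo_expectation_value(self):
        e = ck.expected_de_novo(0.2e-9, 121_000, 25.0)
        assert e.expected_count == pytest.approx(6.05e-4, rel=1e-12)
        assert e.expected_count < 0.02

    def test_zero_rate(self):
        e = ck.expected_de_novo(0.0, 121_000, 25.0, k=1)
        assert e.expected_count == 0.0 and e.p_ge_k == 0.0

    def test_poisson_tail_matches_series_sum(self):
        lam = 6.05e-4
        e = ck.expected_de_novo(0.2e-9, 121_000, 25.0, k=3)
        brute = 1.0 - sum(math.exp(-lam) * lam**i / math.factorial(i) for i in range(3))
        assert e.p_ge_k == pytest.approx(brute, abs=1e-12)
        assert e.p_ge_k == pytest.approx(3.7e-11, rel=0.02)

    def test_linearity(self):
        base = ck.expected_de_novo(0.2e-9, 121_000, 25.0).expected_count
        assert ck.expected_de_novo(0.4e-9, 121_000, 25.0).expected_count == pytest.approx(2 * base)
        assert ck.expected_de_novo(0.2e-9, 242_000, 25.0).expected_count == pytest.approx(2 * base)
        assert ck.expected_de_novo(0.2e-9, 121_000, 50.0).expected_count == pytest.approx(2 * base)

    def test_tail_monotone_in_k(self):
        ps = [ck.expected_de_novo(0.2e-9, 121_000, 25.0, k=k).p_ge_k for k in range(1, 5)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ck.expected_de_novo(0.2e-9, 0, 25.0)


class TestLeakage:
    def test_observed_fraction(self):
        t = ck.leakage_test(9, 45, 0.01)
        assert t.observed_fraction == pytest.approx(0.20)
        assert 0.0 < t.p_value < 1e-8  # far beyond the 1% leakage null

    def test_nothing_discordant(self):
        assert ck.leakage_test(0, 45).p_value == pytest.approx(1.0)

    def test_exact_tail_formula(self):
        t = ck.leakage_test(9, 45, 0.01)
        brute = sum(
            math.comb(45, k) * 0.01**k * 0.99 ** (45 - k) for k in range(9, 46)
        )
        assert t.p_value == pytest.approx(brute, rel=1e-9)

    def test_monte_carlo_agreement(self):
        """Exact binomial tail within 3 s.e. of a seeded Monte-Carlo estimate."""
        t = ck.leakage_test(3, 45, 0.05)
        rng = np.random.default_rng(7)
        draws = rng.binomial(45, 0.05, size=10**6)
        mc = float(np.mean(draws >= 3))
        se = math.sqrt(max(mc * (1 - mc), 1e-12) / 10**6)
        assert abs(t.p_value - mc) <= 3 * se

    def test_invalid(self):
        with pytest.raises(ValueError):
            ck.leakage_test(1, 0)
        with pytest.raises(ValueError):
            ck.leakage_test(5, 4)


class TestConcordance:
    def test_self_agreement(self, tester_matrix):
        rep = ck.concordance(tester_matrix, tester_matrix)
        assert rep.overall == 1.0
        assert all(v == 1.0 for v in rep.per_locus.values())
        assert rep.disagreements == []

    def test_single_flip(self, tester_matrix):
        sub = tester_matrix.subset(tester_matrix.samples[:10], tester_matrix.positions[:10])
        cells = sub.cells.copy()
        cells[0, 0] = "A" if cells[0, 0] != "A" else "T"
        other = GenotypeMatrix(sub.samples, sub.loci, cells)
        rep = ck.concordance(sub, other)
        assert rep.overall == pytest.approx(0.99)
        assert len(rep.disagreements) == 1

    def test_n_cells_excluded(self):
        a = _mat({"s": "----"})
        b = _mat({"s": "N---"})
        rep = ck.concordance(a, b)
        assert rep.overall == 1.0
        assert rep.per_sample["s"] == 1.0

    def test_disjoint_matrices_rejected(self, tester_matrix):
        other = _mat({"zzz": "----"})
        with pytest.raises(ck.kinship.IncompatibleMatricesError):
            ck.concordance(tester_matrix, other)
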
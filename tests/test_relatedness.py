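"""Allele frequencies, Queller-Goodnight estimation, maternity, predictors."""

import numpy as np
import pytest

from kinnet import (
    Individual,
    InvariantError,
    UndefinedDyadError,
    VocabularyError,
    allele_frequencies,
    homophily_matrix,
    maternity_by_exclusion,
    mother_offspring_matrix,
    queller_goodnight,
    relatedness_matrix,
)
from kinnet.core import derive_rng
from kinnet.relatedness import count_mismatches
from kinnet.simulate import (
    SyntheticScenario,
    _draw_locus_frequencies,
    _founder_genotype,
    _offspring_genotype,
)


class TestAlleleFrequencies:
    def test_counting_two_individuals(self):
        geno = {"X": {"L1": ("A", "A")}, "Y": {"L1": ("A", "B")}}
        freqs = allele_frequencies(geno, ["X", "Y"])
        assert freqs.freqs["L1"] == {"A": 0.75, "B": 0.25}

    def test_monomorphic_locus_flagged(self):
        geno = {"X": {"L1": ("A", "A")}, "Y": {"L1": ("A", "A")}}
        freqs = allele_frequencies(geno, ["X", "Y"])
        assert freqs.freqs["L1"] == {"A": 1.0}
        assert freqs.monomorphic_loci() == ["L1"]

    def test_frequencies_sum_to_one_on_random_panels(self, rng):
        sc = SyntheticScenario()
        lf = _draw_locus_frequencies(sc, rng)
        geno = {f"P{i}": _founder_genotype(lf, rng) for i in range(20)}
        freqs = allele_frequencies(geno, list(geno))
        for locus, table in freqs.freqs.items():
            assert sum(table.values()) == pytest.approx(1.0, abs=1e-9)

    def test_untyped_panel_member_and_empty_panel(self):
        geno = {"X": {"L1": ("A", "B")}}
        with pytest.raises(InvariantError):
            allele_frequencies(geno, [])
        freqs = allele_frequencies(geno, ["X", "untyped"])
        assert set(freqs.freqs) == {"L1"}


class TestQuellerGoodnight:
    def test_identical_heterozygotes_are_clones(self):
        """Two identical heterozygotes at every locus estimate r = 1
        regardless of the allele frequencies."""
        geno = {
            "x": {f"L{i}": ("a", "b") for i in range(5)},
            "y": {f"L{i}": ("a", "b") for i in range(5)},
        }
        panel = {
            "p1": {f"L{i}": ("a", "b") for i in range(5)},
            "p2": {f"L{i}": ("a", "c") for i in range(5)},
            "p3": {f"L{i}": ("b", "c") for i in range(5)},
            "p4": {f"L{i}": ("c", "c") for i in range(5)},
        }
        freqs = allele_frequencies(panel, list(panel))
        assert queller_goodnight(geno | panel, freqs, ("x", "y")) == pytest.approx(1.0)

    def test_allele_relabeling_invariance(self, rng):
        sc = SyntheticScenario()
        lf = _draw_locus_frequencies(sc, rng)
        geno = {f"I{i}": _founder_genotype(lf, rng) for i in range(10)}
        freqs = allele_frequencies(geno, list(geno))
        r1 = queller_goodnight(geno, freqs, ("I0", "I1"))

        relabel = lambda a: f"z{a}"
        geno2 = {
            iid: {loc: (relabel(a1), relabel(a2)) for loc, (a1, a2) in g.items()}
            for iid, g in geno.items()
        }
        freqs2 = allele_frequencies(geno2, list(geno2))
        r2 = queller_goodnight(geno2, freqs2, ("I0", "I1"))
        assert r2 == pytest.approx(r1, abs=1e-12)

    def test_estimator_ordering_across_relationship_classes(self):
        """Mean r over simulated dyads orders unrelated < half-sib <
        parent-offspring ~ full-sib, near 0, 0.25, 0.5, 0.5."""
        rng = derive_rng(11, "qg-ordering")
        sc = SyntheticScenario()
        lf = _draw_locus_frequencies(sc, rng)
        panel = {f"P{i}": _founder_genotype(lf, rng) for i in range(60)}
        freqs = allele_frequencies(panel, list(panel))
        means = {}
        n = 300
        for kind in ("unrelated", "half_sib", "parent_offspring", "full_sib"):
            vals = []
            for _ in range(n):
                mom = _founder_genotype(lf, rng)
                dad = _founder_genotype(lf, rng)
                if kind == "unrelated":
                    a, b = _founder_genotype(lf, rng), _founder_genotype(lf, rng)
                elif kind == "half_sib":
                    a = _offspring_genotype(mom, lf, rng)
                    b = _offspring_genotype(mom, lf, rng)
                elif kind == "parent_offspring":
                    a = mom
                    b = _offspring_genotype(mom, lf, rng)
                else:
                    a = {l: tuple(sorted((mom[l][rng.integers(2)],
                                          dad[l][rng.integers(2)])))
                         for l in lf}
                    b = {l: tuple(sorted((mom[l][rng.integers(2)],
                                          dad[l][rng.integers(2)])))
                         for l in lf}
                vals.append(queller_goodnight({"a": a, "b": b}, freqs, ("a", "b")))
            arr = np.array(vals)
            means[kind] = (arr.mean(), 3 * arr.std(ddof=1) / np.sqrt(n))
        assert abs(means["unrelated"][0]) < means["unrelated"][1]
        assert abs(means["half_sib"][0] - 0.25) < means["half_sib"][1]
        assert abs(means["parent_offspring"][0] - 0.5) < means["parent_offspring"][1]
        assert abs(means["full_sib"][0] - 0.5) < means["full_sib"][1]
        assert (means["unrelated"][0] < means["half_sib"][0]
                < means["parent_offspring"][0])

    def test_no_shared_informative_locus_is_undefined(self):
        geno = {"x": {"L1": ("a", "a")}, "y": {"L2": ("a", "a")},
                "p": {"L1": ("a", "b"), "L2": ("a", "b")}}
        freqs = allele_frequencies(geno, ["p"])
        with pytest.raises(UndefinedDyadError):
            queller_goodnight(geno, freqs, ("x", "y"))

    def test_exclude_pair_from_freqs_changes_panel(self):
        geno = {
            "x": {"L1": ("a", "b")}, "y": {"L1": ("a", "b")},
            "p1": {"L1": ("a", "c")}, "p2": {"L1": ("b", "c")},
        }
        freqs = allele_frequencies(geno, ["x", "y", "p1", "p2"])
        r_in = queller_goodnight(geno, freqs, ("x", "y"),
                                 exclude_pair_from_freqs=False)
        r_ex = queller_goodnight(geno, freqs, ("x", "y"),
                                 exclude_pair_from_freqs=True)
        assert r_in == pytest.approx(1.0)  # clones regardless of panel
        assert r_ex == pytest.approx(1.0)


class TestRelatednessMatrix:
    def _clone_roster(self):
        return [Individual(f"I{k}", "F", "adult", "G1", 2003) for k in range(4)]

    def test_group_of_clones_all_one(self):
        roster = self._clone_roster()
        geno = {r.id: {f"L{i}": ("a", "b") for i in range(6)} for r in roster}
        extra = {"p": {f"L{i}": ("a", "c") for i in range(6)}}
        freqs = allele_frequencies(geno | extra, [r.id for r in roster] + ["p"])
        m = relatedness_matrix(geno | extra, freqs, roster)
        off = ~np.eye(m.n, dtype=bool)
        assert np.allclose(m.values[off], 1.0)

    def test_symmetric(self, rng):
        sc = SyntheticScenario()
        lf = _draw_locus_frequencies(sc, rng)
        roster = self._clone_roster()
        geno = {r.id: _founder_genotype(lf, rng) for r in roster}
        freqs = allele_frequencies(geno, list(geno))
        m = relatedness_matrix(geno, freqs, roster)
        assert np.allclose(m.values, m.values.T, atol=1e-12)


class TestMaternityByExclusion:
    def _family(self, rng, n_loci=15):
        sc = SyntheticScenario(n_loci=n_loci)
        lf = _draw_locus_frequencies(sc, rng)
        mom = _founder_genotype(lf, rng)
        kid = _offspring_genotype(mom, lf, rng)
        others = {f"F{i}": _founder_genotype(lf, rng) for i in range(3)}
        return lf, mom, kid, others

    def test_true_mother_has_zero_mismatches(self, rng):
        _, mom, kid, others = self._family(rng)
        geno = {"mom": mom, "kid": kid, **others}
        assert count_mismatches(kid, mom) == 0
        assignment = maternity_by_exclusion(
            geno, ["kid"], ["mom", *others], max_mismatch=0
        )
        # unique assignment only when all other candidates mismatch somewhere
        if all(count_mismatches(kid, others[f]) > 0 for f in others):
            assert assignment.mothers["kid"] == "mom"

    def test_all_candidates_mismatching_leaves_unassigned(self):
        kid = {"L1": ("a", "a"), "L2": ("a", "a")}
        cand = {"L1": ("b", "b"), "L2": ("a", "a")}
        geno = {"kid": kid, "c1": cand}
        out = maternity_by_exclusion(geno, ["kid"], ["c1"], max_mismatch=0)
        assert out.mothers["kid"] is None
        assert out.mismatches[("kid", "c1")] == 1

    def test_mismatch_tolerance_absorbs_single_error(self):
        kid = {"L1": ("a", "a"), "L2": ("a", "a")}
        cand = {"L1": ("b", "b"), "L2": ("a", "a")}
        geno = {"kid": kid, "c1": cand}
        out = maternity_by_exclusion(geno, ["kid"], ["c1"], max_mismatch=1)
        assert out.mothers["kid"] == "c1"

    def test_multiple_passers_ambiguous(self):
        kid = {"L1": ("a", "b")}
        geno = {"kid": kid, "c1": {"L1": ("a", "c")}, "c2": {"L1": ("b", "c")}}
        out = maternity_by_exclusion(geno, ["kid"], ["c1", "c2"])
        assert out.mothers["kid"] is None


class TestPredictorMatrices:
    def _roster(self):
        return [
            Individual("mom", "F", "adult", "G1", 2003),
            Individual("juv", "F", "juvenile", "G1", 2003),
            Individual("sub", "M", "subadult", "G1", 2003),
            Individual("juv2", "M", "juvenile", "G1", 2003),
        ]

    def test_mother_juvenile_coded_one_mother_subadult_zero(self):
        roster = self._roster()
        maternity = {"juv": "mom", "sub": "mom"}
        m = mother_offspring_matrix(maternity, roster)
        assert m.value("mom", "juv") == 1.0
        assert m.value("mom", "sub") == 0.0
        assert m.values.sum() == 2.0  # one symmetric dyad

    def test_no_assigned_maternity_gives_zero_matrix(self):
        m = mother_offspring_matrix({"juv": None}, self._roster())
        assert not m.values.any()

    def test_entry_count_matches_assigned_juvenile_maternities(self):
        roster = self._roster()
        maternity = {"juv": "mom", "juv2": "mom"}
        m = mother_offspring_matrix(maternity, roster)
        assert m.values.sum() == 2 * 2

    def test_juvenile_homophily_combinatorics(self):
        roster = self._roster()
        m = homophily_matrix(roster, "juvenile")
        k = 2  # juveniles
        assert m.values.sum() / 2 == k * (k - 1) / 2
        assert m.value("juv", "juv2") == 1.0
        assert m.value("mom", "juv") == 0.0

    def test_sex_homophily_all_female(self):
        roster = [Individual(f"F{i}", "F", "adult", "G1", 2003) for i in range(3)]
        m = homophily_matrix(roster, "sex")
        off = ~np.eye(3, dtype=bool)
        assert np.all(m.values[off] == 1.0)

    def test_unknown_attribute_rejected(self):
        with pytest.raises(VocabularyError):
            homophily_matrix(self._roster(), "rank")
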
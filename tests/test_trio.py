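"""STR trio segregation analysis and androgenetic verification."""

from collections import Counter
from itertools import combinations_with_replacement, product

import pytest

from imprintkit import InsufficientDataError, InvalidInputError
from imprintkit.trio import (BIALLELIC_21, INCONSISTENT, INDETERMINATE,
                             MATERNAL, MT21, OTHER, PATERNAL, PT21,
                             TRIALLELIC_111, UNINFORMATIVE, LocusGenotype,
                             SegregationCall, aggregate_origin, call_families,
                             call_locus_segregation, dosage_from_peaks,
                             verify_uniparental)
from imprintkit.simulate import N21, SimConfig, sim_trio, sim_trios_table


def geno(person, *labels, locus="STR1", area=1000.0):
    counts = Counter(labels)
    return LocusGenotype(locus_id=locus, person=person,
                         alleles=tuple((lab, area * n)
                                       for lab, n in sorted(counts.items())))


class TestDosageFromPeaks:
    def test_two_to_one_ratio_within_window(self):
        pattern, dosage = dosage_from_peaks([("a", 1000.0), ("c", 500.0)])
        assert pattern == BIALLELIC_21 and dosage == {"a": 2, "c": 1}

    def test_near_equal_triallelic(self):
        pattern, dosage = dosage_from_peaks(
            [("a", 300.0), ("b", 310.0), ("c", 295.0)])
        assert pattern == TRIALLELIC_111
        assert dosage == {"a": 1, "b": 1, "c": 1}

    def test_one_to_one_incompatible_with_trisomy(self):
        pattern, dosage = dosage_from_peaks([("a", 1000.0), ("c", 990.0)])
        assert pattern == OTHER and dosage is None

    @pytest.mark.parametrize("alleles", [
        [("a", 0.0), ("b", 100.0)],
        [("a", -5.0)],
        [("a", 1.0), ("b", 1.0), ("c", 1.0), ("d", 1.0)],
    ])
    def test_invalid_inputs_rejected(self, alleles):
        with pytest.raises(InvalidInputError):
            dosage_from_peaks(alleles)


class TestLocusSegregation:
    def test_triallelic_child_identifies_maternal_pair(self):
        call = call_locus_segregation(
            geno("mother", "a", "b"), geno("father", "c", "d"),
            geno("child", "a", "b", "c"))
        assert call.pattern == TRIALLELIC_111 and call.origin == MATERNAL

    def test_doubled_paternal_allele(self):
        call = call_locus_segregation(
            geno("mother", "a", "b"), geno("father", "c", "d"),
            geno("child", "c", "c", "a"))
        assert call.pattern == BIALLELIC_21 and call.origin == PATERNAL

    def test_shared_allele_uninformative(self):
        # a,a from mother or a + a,b from father both explain {a:2, b:1}
        call = call_locus_segregation(
            geno("mother", "a", "a"), geno("father", "a", "b"),
            geno("child", "a", "a", "b"))
        assert call.origin == UNINFORMATIVE

    def test_foreign_allele_flagged_inconsistent(self):
        call = call_locus_segregation(
            geno("mother", "a", "b"), geno("father", "c", "d"),
            geno("child", "a", "a", "e"))
        assert call.origin == INCONSISTENT

    def test_disomic_child_mendelian_check_only(self):
        ok = call_locus_segregation(
            geno("mother", "a", "b"), geno("father", "c", "d"),
            geno("child", "a", "c"), child_ploidy=2)
        bad = call_locus_segregation(
            geno("mother", "a", "b"), geno("father", "c", "d"),
            geno("child", "a", "e"), child_ploidy=2)
        assert ok.origin == UNINFORMATIVE and bad.origin == INCONSISTENT


def brute_force_origin(mother: set, father: set, child: Counter) -> str:
    """Enumerate every (gamete, gamete) pair from each candidate origin
    parent plus one gamete from the other; classify by which origins can
    produce the child multiset."""
    def reachable(origin_alleles, other_alleles):
        for g1, g2, g3 in product(origin_alleles, origin_alleles, other_alleles):
            if Counter([g1, g2, g3]) == child:
                return True
        return False

    mat = reachable(mother, father)
    pat = reachable(father, mother)
    if mat and pat:
        return UNINFORMATIVE
    if mat:
        return MATERNAL
    if pat:
        return PATERNAL
    return INCONSISTENT


def test_segregation_matches_brute_force_on_exhaustive_configurations():
    """Every 4-allele trio configuration agrees with gamete enumeration."""
    alleles = "abcd"
    parents = list(combinations_with_replacement(alleles, 2))
    children = list(combinations_with_replacement(alleles, 3))
    checked = 0
    for m, f, ch in product(parents, parents, children):
        child_counter = Counter(ch)
        call = call_locus_segregation(geno("mother", *m), geno("father", *f),
                                      geno("child", *ch))
        # clean areas (1000 per copy) always resolve dosage, so every
        # configuration is comparable against the oracle
        expected = brute_force_origin(set(m), set(f), child_counter)
        assert call.origin == expected, (m, f, ch)
        checked += 1
    assert checked == len(parents) ** 2 * len(children)


class TestAggregateOrigin:
    def mk(self, *origins):
        return [SegregationCall(f"STR{i}", TRIALLELIC_111, o)
                for i, o in enumerate(origins)]

    def test_three_unanimous_informative_loci_give_verdict(self):
        call = aggregate_origin(self.mk(MATERNAL, MATERNAL, MATERNAL,
                                        UNINFORMATIVE))
        assert call.verdict == MT21 and call.n_informative == 3

    def test_below_minimum_is_indeterminate(self):
        assert aggregate_origin(self.mk(MATERNAL, MATERNAL)).verdict == \
            INDETERMINATE

    def test_conflicting_parents_flagged(self):
        assert aggregate_origin(
            self.mk(MATERNAL, PATERNAL, MATERNAL)).verdict == INCONSISTENT

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            aggregate_origin([])


class TestSimulatedTrios:
    def test_verdicts_never_wrong_parent_over_500_trios(self):
        cfg = SimConfig(seed=11, n_families=500, n_str_loci=5,
                        str_allele_count=8)
        genotypes, manifest = sim_trios_table(cfg)
        ploidy = dict(zip(manifest.family_id, manifest.child_ploidy))
        _, families = call_families(genotypes, ploidy=ploidy)
        merged = families.merge(manifest, on="family_id")
        decided = merged[merged.verdict.isin([MT21, PT21])]
        assert len(decided) > 0
        assert (decided.verdict == decided.truth).all()
        # disomic controls can never acquire a trisomy verdict
        assert not merged[merged.truth == N21].verdict.isin([MT21, PT21]).any()

    def test_parent_relabel_symmetry(self):
        cfg = SimConfig(seed=13, n_families=60)
        genotypes, manifest = sim_trios_table(cfg)
        ploidy = dict(zip(manifest.family_id, manifest.child_ploidy))
        _, fams = call_families(genotypes, ploidy=ploidy)
        swapped = genotypes.copy()
        swapped["person"] = swapped["person"].map(
            {"mother": "father", "father": "mother", "child": "child"})
        _, fams_swapped = call_families(swapped, ploidy=ploidy)
        flip = {MT21: PT21, PT21: MT21}
        merged = fams.merge(fams_swapped, on="family_id", suffixes=("", "_sw"))
        for rec in merged.itertuples():
            assert rec.verdict_sw == flip.get(rec.verdict, rec.verdict)


class TestVerifyUniparental:
    def donor(self):
        return {f"L{i}": {"a", "b"} for i in range(10)} | \
               {f"L{i}": {"c"} for i in range(10, 15)}

    def test_androgenetic_consistent_sample(self):
        donor = self.donor()
        sample = {f"L{i}": {"a"} for i in range(10)} | \
                 {f"L{i}": {"c"} for i in range(10, 15)}
        rep = verify_uniparental(sample, donor)
        assert rep.androgenetic_consistent
        assert rep.n_homozygous == 15 and rep.n_informative == 10

    def test_heterozygous_sample_rejected(self):
        donor = self.donor()
        sample = {f"L{i}": {"a"} for i in range(15)}
        sample["L3"] = {"a", "b"}
        assert not verify_uniparental(sample, donor).androgenetic_consistent

    def test_sample_identical_to_donor_not_androgenetic(self):
        donor = self.donor()
        rep = verify_uniparental(donor, donor)
        assert not rep.androgenetic_consistent  # heterozygous at 10 loci

    def test_too_few_shared_loci(self):
        with pytest.raises(InsufficientDataError):
            verify_uniparental({"L1": {"a"}}, {"L1": {"a", "b"}})
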
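"""Parental origin of a supernumerary chromosome from STR trio genotypes.

The extra chromosome 21 in free trisomy arises from a nondisjunction error in
one parent's meiosis, so the child carries two chromatids from that parent
and one from the other. At a highly polymorphic short tandem repeat (STR)
this shows up either as a triallelic genotype with ~1:1:1 peak areas or as a
biallelic genotype with a consistent 2:1 dosage. Comparing the child's
dosage-resolved genotype with the parental genotypes identifies, locus by
locus, which parent contributed the doubled pair; a verdict for the family
requires at least three informative loci that agree unanimously.

Allele labels are opaque strings — no repeat-length arithmetic or stutter
modelling is attempted.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InsufficientDataError, InvalidInputError

# segregation patterns
TRIALLELIC_111 = "triallelic_111"
BIALLELIC_21 = "biallelic_21"
BIALLELIC_11 = "biallelic_11"
OTHER = "other"

# per-locus origin calls
MATERNAL = "maternal"
PATERNAL = "paternal"
UNINFORMATIVE = "uninformative"
INCONSISTENT = "inconsistent"

# family verdicts
MT21 = "MT21"
PT21 = "PT21"
INDETERMINATE = "indeterminate"

#: Peak-ratio window (larger/smaller) accepted as a 2:1 dosage.
RATIO_21_WINDOW = (1.5, 3.0)
#: Max/min peak-ratio ceiling accepted as 1:1:1 in a triallelic genotype.
RATIO_111_MAX = 1.6
#: Minimum count of unanimous informative loci for a family verdict.
MIN_INFORMATIVE = 3


@dataclass(frozen=True)
class LocusGenotype:
    """One person's alleles (with peak areas) at one STR locus."""

    locus_id: str
    person: str  # mother | father | child
    alleles: tuple[tuple[str, float], ...]  # (label, peak area)

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.alleles]
        if not 1 <= len(set(labels)) <= 3 or len(labels) != len(set(labels)):
            raise InvalidInputError(
                f"{self.locus_id}/{self.person}: need 1-3 distinct alleles")
        for lab, area in self.alleles:
            if not math.isfinite(area) or area < 0:
                raise InvalidInputError(
                    f"{self.locus_id}/{self.person}: bad peak area for {lab}")

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(lab for lab, _ in self.alleles)


@dataclass(frozen=True)
class SegregationCall:
    locus_id: str
    pattern: str
    origin: str


@dataclass(frozen=True)
class OriginCall:
    verdict: str
    n_informative: int
    n_maternal: int
    n_paternal: int


def dosage_from_peaks(alleles: Sequence[tuple[str, float]], *, ploidy: int = 3,
                      ratio_21_window: tuple[float, float] = RATIO_21_WINDOW,
                      ratio_111_max: float = RATIO_111_MAX,
                      ) -> tuple[str, dict[str, int] | None]:
    """Resolve allele copy numbers from peak areas.

    Fluorescence area is roughly proportional to template copy number, so in
    a trisomic sample a doubled allele shows about twice the area of a single
    one. Returns ``(pattern, dosage)`` where ``dosage`` maps each label to
    its copy number, or ``(OTHER, None)`` when the areas fit no expected
    ratio within the configured windows.
    """
    if not 1 <= len(alleles) <= 3:
        raise InvalidInputError("expect 1-3 alleles per locus")
    for lab, area in alleles:
        if not math.isfinite(area) or area <= 0:
            raise InvalidInputError(f"allele {lab}: peak area must be positive")
    labels = [lab for lab, _ in alleles]
    if len(set(labels)) != len(labels):
        raise InvalidInputError("duplicate allele labels")

    if ploidy == 2:
        if len(alleles) == 1:
            return OTHER, {alleles[0][0]: 2}
        if len(alleles) == 2:
            return BIALLELIC_11, {lab: 1 for lab, _ in alleles}
        return OTHER, None

    if ploidy != 3:
        raise InvalidInputError(f"unsupported ploidy {ploidy}")
    if len(alleles) == 1:
        return OTHER, {alleles[0][0]: 3}
    if len(alleles) == 2:
        (lab1, a1), (lab2, a2) = alleles
        big, small = ((lab1, a1), (lab2, a2)) if a1 >= a2 else ((lab2, a2), (lab1, a1))
        ratio = big[1] / small[1]
        lo, hi = ratio_21_window
        if lo <= ratio <= hi:
            return BIALLELIC_21, {big[0]: 2, small[0]: 1}
        return OTHER, None
    areas = [area for _, area in alleles]
    if max(areas) / min(areas) <= ratio_111_max:
        return TRIALLELIC_111, {lab: 1 for lab, _ in alleles}
    return OTHER, None


def _splits(child: Counter, origin_parent: frozenset[str],
            other_parent: frozenset[str]) -> bool:
    """Is the trisomic child genotype consistent with nondisjunction in
    ``origin_parent``: two independent gametes from it plus one gamete from
    the other parent?"""
    items = list(child.elements())  # 3 alleles with multiplicity
    if len(items) != 3:
        return False
    # choose which of the three copies is the other parent's single gamete
    for i in range(3):
        single = items[i]
        pair = items[:i] + items[i + 1:]
        if single in other_parent and all(x in origin_parent for x in pair):
            return True
    return False


def call_locus_segregation(mother: LocusGenotype, father: LocusGenotype,
                           child: LocusGenotype, child_ploidy: int = 3,
                           **dosage_kw) -> SegregationCall:
    """Per-locus origin of the nondisjoined pair by segregation analysis.

    The child's dosage-resolved genotype is split into a doubled parental
    contribution (two independent gametes from the nondisjoining parent) and
    a single gamete from the other parent. The locus is informative only
    when every Mendelian-consistent split attributes the doubled
    contribution to the same parent.
    """
    if not (mother.locus_id == father.locus_id == child.locus_id):
        raise InvalidInputError("genotypes refer to different loci")
    pattern, dosage = dosage_from_peaks(child.alleles, ploidy=child_ploidy,
                                        **dosage_kw)
    if child_ploidy == 2:
        # disomic control: check Mendelian consistency only
        if dosage is None:
            return SegregationCall(child.locus_id, pattern, UNINFORMATIVE)
        geno = Counter(dosage)
        ok = any(
            Counter([m, f]) == geno
            for m, f in product(mother.labels, father.labels))
        origin = UNINFORMATIVE if ok else INCONSISTENT
        return SegregationCall(child.locus_id, pattern, origin)

    if dosage is None:
        return SegregationCall(child.locus_id, pattern, UNINFORMATIVE)
    geno = Counter(dosage)
    if not set(geno) <= (mother.labels | father.labels):
        return SegregationCall(child.locus_id, pattern, INCONSISTENT)
    from_mother = _splits(geno, mother.labels, father.labels)
    from_father = _splits(geno, father.labels, mother.labels)
    if from_mother and from_father:
        origin = UNINFORMATIVE
    elif from_mother:
        origin = MATERNAL
    elif from_father:
        origin = PATERNAL
    else:
        origin = INCONSISTENT
    return SegregationCall(child.locus_id, pattern, origin)


def aggregate_origin(calls: Sequence[SegregationCall], *,
                     min_informative: int = MIN_INFORMATIVE) -> OriginCall:
    """Family-level verdict from per-locus calls.

    MT21/PT21 require at least ``min_informative`` informative loci and
    unanimity; any maternal/paternal conflict is flagged inconsistent rather
    than resolved by majority.
    """
    if not calls:
        raise InvalidInputError("no locus calls")
    n_mat = sum(1 for c in calls if c.origin == MATERNAL)
    n_pat = sum(1 for c in calls if c.origin == PATERNAL)
    n_inf = n_mat + n_pat
    if any(c.origin == INCONSISTENT for c in calls) or (n_mat and n_pat):
        verdict = INCONSISTENT
    elif n_mat >= min_informative:
        verdict = MT21
    elif n_pat >= min_informative:
        verdict = PT21
    else:
        verdict = INDETERMINATE
    return OriginCall(verdict=verdict, n_informative=n_inf,
                      n_maternal=n_mat, n_paternal=n_pat)


@dataclass(frozen=True)
class UniparentalReport:
    """Outcome of androgenetic (paternal-only) genome verification."""

    n_loci: int
    n_homozygous: int
    n_informative: int  # donor-heterozygous loci where one donor allele is absent
    all_alleles_from_donor: bool
    androgenetic_consistent: bool
    per_locus: dict[str, dict] = field(repr=False, default_factory=dict)


def verify_uniparental(sample: Mapping[str, frozenset[str] | set[str]],
                       donor: Mapping[str, frozenset[str] | set[str]],
                       *, min_loci: int = 10,
                       min_informative: int = 3) -> UniparentalReport:
    """Verify that a specimen is homogenously androgenetic.

    A complete hydatidiform mole of androgenetic origin duplicates a single
    paternal (donor) gamete: it is homozygous at every locus, each allele is
    carried by the donor, and at donor-heterozygous loci exactly one donor
    allele appears — the consistent absence of the other donor allele (and
    of any non-donor, would-be maternal allele) excludes biparental origin.
    """
    shared = sorted(set(sample) & set(donor))
    if len(shared) < min_loci:
        raise InsufficientDataError(
            f"only {len(shared)} shared loci; need >= {min_loci}")
    per_locus: dict[str, dict] = {}
    n_hom = 0
    n_informative = 0
    all_from_donor = True
    for locus in shared:
        s = frozenset(sample[locus])
        d = frozenset(donor[locus])
        hom = len(s) == 1
        from_donor = s <= d
        informative = hom and from_donor and len(d) > 1
        n_hom += hom
        n_informative += informative
        all_from_donor &= from_donor
        per_locus[locus] = {"homozygous": hom, "alleles_from_donor": from_donor,
                            "informative": informative}
    consistent = (n_hom == len(shared) and all_from_donor
                  and n_informative >= min_informative)
    return UniparentalReport(n_loci=len(shared), n_homozygous=n_hom,
                             n_informative=n_informative,
                             all_alleles_from_donor=all_from_donor,
                             androgenetic_consistent=consistent,
                             per_locus=per_locus)


# ---------------------------------------------------------------------------
# tabular interface

def trios_from_table(df: pd.DataFrame) -> dict[str, dict[str, dict[str, LocusGenotype]]]:
    """Group a long-format genotype table into family -> locus -> person.

    Expects columns ``family_id, locus_id, person, allele, peak_area``.
    """
    required = {"family_id", "locus_id", "person", "allele", "peak_area"}
    if missing := required - set(df.columns):
        raise InvalidInputError(f"missing columns: {sorted(missing)}")
    out: dict[str, dict[str, dict[str, LocusGenotype]]] = {}
    for (fam, locus, person), grp in df.groupby(
            ["family_id", "locus_id", "person"], sort=True):
        alleles = tuple((str(a), float(p))
                        for a, p in zip(grp["allele"], grp["peak_area"]))
        out.setdefault(str(fam), {}).setdefault(str(locus), {})[str(person)] = \
            LocusGenotype(locus_id=str(locus), person=str(person), alleles=alleles)
    return out


def call_families(df: pd.DataFrame, ploidy: Mapping[str, int] | int = 3,
                  **kw) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run segregation analysis over a genotype table.

    ``ploidy`` is the child ploidy, either one integer for all families or a
    mapping family_id -> ploidy. Returns (per-locus table, per-family table).
    """
    trios = trios_from_table(df)
    locus_rows, family_rows = [], []
    for fam, loci in trios.items():
        pl = ploidy if isinstance(ploidy, int) else int(ploidy[fam])
        calls = []
        for locus, persons in loci.items():
            if {"mother", "father", "child"} - set(persons):
                continue
            call = call_locus_segregation(persons["mother"], persons["father"],
                                          persons["child"], child_ploidy=pl, **kw)
            calls.append(call)
            locus_rows.append({"family_id": fam, "locus_id": locus,
                               "pattern": call.pattern, "origin": call.origin})
        if calls:
            agg = aggregate_origin(calls)
            family_rows.append({"family_id": fam, "verdict": agg.verdict,
                                "n_informative": agg.n_informative,
                                "n_maternal": agg.n_maternal,
                                "n_paternal": agg.n_paternal})
    return pd.DataFrame(locus_rows), pd.DataFrame(family_rows)
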
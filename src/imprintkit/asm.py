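"""Allele-specific methylation calls from enzyme-digest SNuPE genotypes.

The logic exploits two endonucleases with complementary specificities: HhaI
cuts only unmethylated GCGC sites, so the allele still genotypable after HhaI
digestion is the methylated one; McrBC cuts only methylated DNA, so the
McrBC-surviving allele must be the unmethylated one. At a heterozygous SNP
inside a differentially methylated region the two digests therefore reveal
opposite alleles, and trio genotypes turn the methylated allele into a
parental label.

For trisomic samples the percent-methylation value alone separates maternal
from paternal origin of the extra chromosome: with a maternally methylated
imprint, two of three alleles are methylated when the doubled pair is
maternal (expected 200/3 %) and one of three when it is paternal (100/3 %).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

from .errors import InconsistencyError, InvalidInputError, UninformativeSNPError
from .trio import INDETERMINATE, MATERNAL, MT21, PATERNAL, PT21

TREATMENT_NONE = "none"
TREATMENT_HHAI = "HhaI"
TREATMENT_MCRBC = "McrBC"

BOTH = "both"
NONE = "none"
AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"

#: Minimum signal relative to the major peak for an allele to count as
#: detected in a digest genotype (instrument noise floor).
MIN_RELATIVE_SIGNAL = 0.10

#: MT21/PT21 decision thresholds on percent methylation: midpoints between
#: the disomic expectation (50) and the trisomic expectations 200/3 and 100/3.
MT21_MIN = 58.3
PT21_MAX = 41.7


@dataclass(frozen=True)
class DigestGenotype:
    """Alleles still genotypable after a given digestion treatment."""

    snp_id: str
    treatment: str
    detected_alleles: frozenset[str]

    def __post_init__(self) -> None:
        if self.treatment not in (TREATMENT_NONE, TREATMENT_HHAI, TREATMENT_MCRBC):
            raise InvalidInputError(f"unknown treatment {self.treatment!r}")


def detect_alleles(signals: Mapping[str, float], *,
                   min_relative_signal: float = MIN_RELATIVE_SIGNAL) -> frozenset[str]:
    """Apply the relative-signal noise floor to raw per-allele signals."""
    if not signals:
        return frozenset()
    peak = max(signals.values())
    if peak <= 0:
        return frozenset()
    return frozenset(a for a, s in signals.items()
                     if s >= min_relative_signal * peak)


@dataclass(frozen=True)
class ASMCall:
    """Which allele (and optionally which parent) carries the methylation."""

    snp_id: str
    methylated_allele: str  # an allele label, or both/none/ambiguous
    methylated_parent: str = UNASSIGNED
    cross_enzyme_consistent: bool | None = None


@dataclass(frozen=True)
class EpigeneticOriginCall:
    percent_meth: float
    verdict: str


def call_allele_methylation(untreated: DigestGenotype, hhai: DigestGenotype,
                            mcrbc: DigestGenotype | None = None) -> ASMCall:
    """Identify the methylated allele at a heterozygous SNP.

    The methylated allele is the single allele surviving the
    methylation-sensitive (HhaI) digest. With McrBC data the complementary
    allele must survive there; any overlap or mismatch marks the call
    ambiguous. Both alleles surviving HhaI means a hypermethylated locus or
    digest failure (``both``); neither surviving means no methylated
    template (``none``).
    """
    if untreated.treatment != TREATMENT_NONE:
        raise InvalidInputError("first genotype must be the untreated one")
    if hhai.treatment != TREATMENT_HHAI:
        raise InvalidInputError("second genotype must be the HhaI digest")
    if len(untreated.detected_alleles) != 2:
        raise UninformativeSNPError(
            f"{untreated.snp_id}: untreated genotype is not heterozygous")
    if {hhai.snp_id} | ({mcrbc.snp_id} if mcrbc else set()) != {untreated.snp_id}:
        raise InvalidInputError("treatments refer to different SNPs")
    if not hhai.detected_alleles <= untreated.detected_alleles:
        raise InvalidInputError("digest shows alleles absent from the "
                                "untreated genotype")

    surviving = hhai.detected_alleles
    if len(surviving) == 2:
        meth = BOTH
    elif len(surviving) == 0:
        meth = NONE
    else:
        meth = next(iter(surviving))

    consistent: bool | None = None
    if mcrbc is not None:
        if mcrbc.treatment != TREATMENT_MCRBC:
            raise InvalidInputError("third genotype must be the McrBC digest")
        expected = untreated.detected_alleles - surviving
        consistent = mcrbc.detected_alleles == expected
        if meth not in (BOTH, NONE) and not consistent:
            meth = AMBIGUOUS
    return ASMCall(snp_id=untreated.snp_id, methylated_allele=meth,
                   cross_enzyme_consistent=consistent)


def assign_parent(asm: ASMCall, mother_alleles: set[str] | frozenset[str],
                  father_alleles: set[str] | frozenset[str],
                  child_alleles: set[str] | frozenset[str]) -> ASMCall:
    """Attach a parental label to the methylated allele via trio genotypes.

    The parent is assigned only when transmission is unambiguous: the
    methylated allele is carried by exactly one parent (and the child is
    heterozygous, so the other allele accounts for the other parent's
    gamete).
    """
    if len(child_alleles) != 2:
        raise InvalidInputError("child must be heterozygous")
    meth = asm.methylated_allele
    if meth in (BOTH, NONE, AMBIGUOUS):
        raise InvalidInputError("methylated allele is not a single allele")
    if meth not in child_alleles:
        raise InconsistencyError(
            f"methylated allele {meth!r} not in the child genotype")
    in_mother = meth in mother_alleles
    in_father = meth in father_alleles
    if not in_mother and not in_father:
        raise InconsistencyError(
            f"methylated allele {meth!r} absent from both parents")
    if in_mother and in_father:
        parent = UNASSIGNED
    else:
        parent = MATERNAL if in_mother else PATERNAL
    return replace(asm, methylated_parent=parent)


def epigenetic_origin(percent_meth: float, *, mt21_min: float = MT21_MIN,
                      pt21_max: float = PT21_MAX) -> EpigeneticOriginCall:
    """Parental origin of a trisomy from percent methylation alone.

    Applicable when the queried region carries a maternal germline imprint
    and the sample is known trisomic: the maternal-methylation dosage is 2/3
    for a maternal extra chromosome and 1/3 for a paternal one. The
    indeterminate band deliberately covers the disomic expectation of 50%.
    """
    if not math.isfinite(percent_meth) or not 0.0 <= percent_meth <= 100.0:
        raise InvalidInputError(f"percent_meth={percent_meth!r} outside [0, 100]")
    if percent_meth >= mt21_min:
        verdict = MT21
    elif percent_meth <= pt21_max:
        verdict = PT21
    else:
        verdict = INDETERMINATE
    return EpigeneticOriginCall(percent_meth=percent_meth, verdict=verdict)
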
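"""Monoallelic vs biallelic expression screen from read-level allele counts.

Instead of full alignment, each SNP is interrogated with a 29-character
substring of its flanking transcript sequence carrying a single biallelic
IUPAC ambiguity code at the SNP position. The query expands into two concrete
29-mers, one per allele; a read supports an allele when it contains that
allele's 29-mer on either strand. Reads are gated by a per-read Phred filter
first, counts by a minimum depth, and the allele fraction maps onto
monoallelic / biallelic / biallelic-imbalance categories, with a chi-square
test against the balanced 50/50 expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy.stats import chi2 as _chi2_dist

from .errors import InvalidInputError, InvalidQueryError

MONOALLELIC = "monoallelic"
BIALLELIC = "biallelic"
BIALLELIC_IMBALANCE = "biallelic_imbalance"
INSUFFICIENT_DEPTH = "insufficient_depth"

QUERY_LENGTH = 29
MIN_DEPTH = 80
MONO_LOW, MONO_HIGH = 0.15, 0.85  # exclusive bounds for monoallelic
BI_LOW, BI_HIGH = 0.35, 0.65      # inclusive bounds for biallelic

#: per-read quality gate: >= min_fraction of bases at Phred >= min_quality
READ_MIN_QUALITY = 25
READ_MIN_FRACTION = 0.90

#: IUPAC codes encoding exactly two bases, as used at the SNP position.
BIALLELIC_IUPAC = {
    "R": ("A", "G"), "Y": ("C", "T"), "S": ("C", "G"),
    "W": ("A", "T"), "K": ("G", "T"), "M": ("A", "C"),
}


@dataclass(frozen=True)
class SNPQuery:
    """A 29-mer substring query with one biallelic IUPAC position."""

    snp_id: str
    substring: str

    def __post_init__(self) -> None:
        sub = self.substring.upper()
        object.__setattr__(self, "substring", sub)
        if len(sub) != QUERY_LENGTH:
            raise InvalidQueryError(
                f"{self.snp_id}: substring must be {QUERY_LENGTH} characters, "
                f"got {len(sub)}")
        ambiguous = [i for i, ch in enumerate(sub) if ch not in "ACGT"]
        if len(ambiguous) != 1:
            raise InvalidQueryError(
                f"{self.snp_id}: need exactly one IUPAC ambiguity character, "
                f"found {len(ambiguous)}")
        code = sub[ambiguous[0]]
        if code not in BIALLELIC_IUPAC:
            raise InvalidQueryError(
                f"{self.snp_id}: code {code!r} does not encode exactly 2 bases")

    @property
    def ambiguity_position(self) -> int:
        """0-based index of the IUPAC code within the substring."""
        return next(i for i, ch in enumerate(self.substring) if ch not in "ACGT")

    @property
    def allele_a(self) -> str:
        """Alphabetically first base of the ambiguity code."""
        return BIALLELIC_IUPAC[self.substring[self.ambiguity_position]][0]

    @property
    def allele_b(self) -> str:
        return BIALLELIC_IUPAC[self.substring[self.ambiguity_position]][1]


@dataclass(frozen=True)
class AlleleCounts:
    """Per-allele read support; depth excludes ambiguous (double-hit) reads."""

    n_a: int
    n_b: int
    n_ambiguous: int = 0

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b, self.n_ambiguous) < 0:
            raise InvalidInputError("counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.n_a + self.n_b


@dataclass(frozen=True)
class ExpressionCall:
    fraction: float | None
    category: str
    chi2: float | None = None
    p_value: float | None = None


def expand_query(q: SNPQuery) -> tuple[str, str]:
    """The two concrete 29-mers encoded by the query, one per allele."""
    i = q.ambiguity_position
    return (q.substring[:i] + q.allele_a + q.substring[i + 1:],
            q.substring[:i] + q.allele_b + q.substring[i + 1:])


def read_passes_quality(qualities: Sequence[int], *,
                        min_quality: int = READ_MIN_QUALITY,
                        min_fraction: float = READ_MIN_FRACTION) -> bool:
    if not qualities:
        raise InvalidInputError("read has no base qualities")
    good = sum(1 for q in qualities if q >= min_quality)
    return good >= min_fraction * len(qualities)


def filter_reads(records: Iterable, *, min_quality: int = READ_MIN_QUALITY,
                 min_fraction: float = READ_MIN_FRACTION) -> list:
    """Keep reads whose bases are predominantly high quality.

    A read passes when at least ``min_fraction`` (default 90%) of its bases
    have Phred quality >= ``min_quality`` (default 25); both boundaries are
    inclusive. ``records`` are Biopython SeqRecords with
    ``letter_annotations["phred_quality"]``.
    """
    out = []
    for rec in records:
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None:
            raise InvalidInputError(f"read {rec.id}: missing base qualities")
        if read_passes_quality(quals, min_quality=min_quality,
                               min_fraction=min_fraction):
            out.append(rec)
    return out


def count_alleles(records: Iterable, q: SNPQuery) -> AlleleCounts:
    """Count reads containing each allele's 29-mer on either strand.

    Matching is exact substring containment of the expanded query in the
    read sequence or its reverse complement. A read matching both allele
    substrings (possible only through tandem or chimeric content) is counted
    ambiguous and excluded from depth.
    """
    sub_a, sub_b = expand_query(q)
    rc_a = str(Seq(sub_a).reverse_complement())
    rc_b = str(Seq(sub_b).reverse_complement())
    n_a = n_b = n_amb = 0
    for rec in records:
        seq = str(rec.seq).upper()
        has_a = sub_a in seq or rc_a in seq
        has_b = sub_b in seq or rc_b in seq
        if has_a and has_b:
            n_amb += 1
        elif has_a:
            n_a += 1
        elif has_b:
            n_b += 1
    return AlleleCounts(n_a=n_a, n_b=n_b, n_ambiguous=n_amb)


def chisq_5050(c: AlleleCounts) -> tuple[float, float]:
    """Chi-square goodness of fit of the allele counts against 50/50.

    One degree of freedom, no continuity correction; the statistic reduces
    to ``(n_a - n_b)^2 / depth``.
    """
    if c.depth == 0:
        raise InvalidInputError("chi-square undefined at depth 0")
    stat = (c.n_a - c.n_b) ** 2 / c.depth
    return stat, float(_chi2_dist.sf(stat, df=1))


def classify_expression(c: AlleleCounts, *, min_depth: int = MIN_DEPTH,
                        mono_low: float = MONO_LOW, mono_high: float = MONO_HIGH,
                        bi_low: float = BI_LOW, bi_high: float = BI_HIGH,
                        ) -> ExpressionCall:
    """Categorise the allele fraction and test deviation from balance.

    Below ``min_depth`` reads no category is assigned. Otherwise the
    fraction n_a/depth is monoallelic strictly outside (mono_low, mono_high),
    biallelic inside [bi_low, bi_high] inclusive, and biallelic-imbalance in
    between (the boundary fractions 0.15 and 0.85 themselves fall in the
    imbalance band).
    """
    if c.depth < min_depth:
        frac = c.n_a / c.depth if c.depth else None
        return ExpressionCall(fraction=frac, category=INSUFFICIENT_DEPTH)
    frac = c.n_a / c.depth
    if frac < mono_low or frac > mono_high:
        category = MONOALLELIC
    elif bi_low <= frac <= bi_high:
        category = BIALLELIC
    else:
        category = BIALLELIC_IMBALANCE
    stat, p = chisq_5050(c)
    return ExpressionCall(fraction=frac, category=category, chi2=stat, p_value=p)


def expected_heterozygosity(maf: float) -> float:
    """Hardy-Weinberg heterozygosity ``2p(1-p)`` for a biallelic SNP.

    Used when selecting screen SNPs by minor-allele frequency: a MAF
    threshold of 0.1 implies an expected global heterozygosity of 0.18, the
    fraction of donors informative for the allele-fraction readout.
    """
    if not 0.0 <= maf <= 0.5:
        raise InvalidInputError(f"minor-allele frequency {maf!r} outside [0, 0.5]")
    return 2.0 * maf * (1.0 - maf)


# ---------------------------------------------------------------------------
# file-level interface

def read_fastq(path) -> list:
    return list(SeqIO.parse(path, "fastq"))


def queries_from_table(df: pd.DataFrame) -> list[SNPQuery]:
    """Build queries from a table with columns ``snp_id, substring``.

    An optional 1-based ``ambiguity_position`` column is validated against
    the substring when present.
    """
    if missing := {"snp_id", "substring"} - set(df.columns):
        raise InvalidInputError(f"missing columns: {sorted(missing)}")
    queries = []
    for rec in df.itertuples(index=False):
        q = SNPQuery(snp_id=str(rec.snp_id), substring=str(rec.substring))
        if "ambiguity_position" in df.columns:
            stated = int(rec.ambiguity_position) - 1
            if stated != q.ambiguity_position:
                raise InvalidQueryError(
                    f"{q.snp_id}: stated ambiguity position {stated + 1} does "
                    f"not match the substring")
        queries.append(q)
    return queries


def screen_snps(records: Sequence, queries: Iterable[SNPQuery],
                **classify_kw) -> pd.DataFrame:
    """Full screen: quality filter once, then count and classify per SNP."""
    passing = filter_reads(records)
    rows = []
    for q in queries:
        counts = count_alleles(passing, q)
        call = classify_expression(counts, **classify_kw)
        rows.append({"snp_id": q.snp_id, "n_a": counts.n_a, "n_b": counts.n_b,
                     "n_ambiguous": counts.n_ambiguous, "depth": counts.depth,
                     "fraction": call.fraction, "category": call.category,
                     "chi2": call.chi2, "p_value": call.p_value})
    return pd.DataFrame(rows)
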
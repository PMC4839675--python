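"""Synthetic inputs with the statistical structure each pipeline stage assumes.

Four generators emulate the study designs the analysis stages were built for:

* STR trio genotypes under disomy or maternal/paternal trisomy, with peak
  areas proportional to allele copy number plus multiplicative noise;
* MSRE-PCR peak-area quartets around a known true methylation fraction, with
  configurable query/reference amplification imbalance;
* allele-specific read sets where each read embeds one allele's 29-mer at a
  random offset in random flanking sequence, with per-base errors;
* sequences carrying k tandem copies of a degenerate consensus at constant
  start-to-start spacing.

Every generator takes a :class:`SimConfig` whose ``seed`` fully determines
the output: identical configurations produce identical data. Noise models
are multiplicative lognormal for fluorescence areas (positive, roughly
proportional signals), binomial sampling for allele choice in reads, and
uniform random bases for flanks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ase import SNPQuery
from .errors import InvalidConfigError, InvalidInputError
from .motifs import IUPACMotif, _EXPANSION
from .msre import AmplimerQuartet
from .trio import MT21, PT21, LocusGenotype

N21 = "N21"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters shared by the generators; see module docstring for models."""

    seed: int = 0
    n_families: int = 500
    origin_mix: tuple[float, float, float] = (0.2, 0.6, 0.2)  # N21, MT21, PT21
    n_str_loci: int = 5
    str_allele_count: int = 8
    str_peak_cv: float = 0.05
    meth_noise_cv: float = 0.03
    assay_imbalance: float = 1.0  # true undigested query:reference ratio A/B
    read_depth: int = 100
    base_error_rate: float = 0.001
    read_length: int = 50
    motif_units: int = 7
    motif_spacing: int = 62

    def __post_init__(self) -> None:
        if abs(sum(self.origin_mix) - 1.0) > 1e-9:
            raise InvalidConfigError("origin_mix must sum to 1")
        for name in ("str_peak_cv", "meth_noise_cv", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")
        if self.assay_imbalance <= 0:
            raise InvalidConfigError("assay_imbalance must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# STR trios

def sim_trio(cfg: SimConfig, origin: str | None = None,
             rng: np.random.Generator | None = None,
             ) -> tuple[dict[str, dict[str, LocusGenotype]], str]:
    """One nuclear trio under a known origin of the (possible) trisomy.

    Parents draw two alleles per locus from a uniform allele pool. Under
    MT21/PT21 the child receives two independent gametes from the origin
    parent — nondisjunction without meiotic-stage structure — plus one from
    the other parent; under N21, one gamete from each. Peak areas are
    proportional to copy number with lognormal noise (CV ``str_peak_cv``).

    Returns ``(genotypes, truth)`` with ``genotypes[locus][person]``.
    """
    if cfg.str_allele_count < 2:
        raise InvalidConfigError("need at least 2 alleles per locus")
    if rng is None:
        rng = cfg.rng()
    if origin is None:
        origin = str(rng.choice([N21, MT21, PT21], p=cfg.origin_mix))
    if origin not in (N21, MT21, PT21):
        raise InvalidInputError(f"unknown origin {origin!r}")

    labels = [f"a{i}" for i in range(cfg.str_allele_count)]
    base_area = 1000.0
    out: dict[str, dict[str, LocusGenotype]] = {}
    for li in range(cfg.n_str_loci):
        locus = f"STR{li + 1}"
        mother = list(rng.choice(labels, size=2))
        father = list(rng.choice(labels, size=2))
        m_gamete = lambda: mother[rng.integers(2)]  # noqa: E731
        f_gamete = lambda: father[rng.integers(2)]  # noqa: E731
        if origin == N21:
            child = [m_gamete(), f_gamete()]
        elif origin == MT21:
            child = [m_gamete(), m_gamete(), f_gamete()]
        else:
            child = [f_gamete(), f_gamete(), m_gamete()]
        out[locus] = {}
        for person, geno in (("mother", mother), ("father", father),
                             ("child", child)):
            counts: dict[str, int] = {}
            for al in geno:
                counts[al] = counts.get(al, 0) + 1
            alleles = tuple(
                (al, base_area * n * _lognormal_factor(rng, cfg.str_peak_cv))
                for al, n in sorted(counts.items()))
            out[locus][person] = LocusGenotype(locus_id=locus, person=person,
                                               alleles=alleles)
    return out, origin


def sim_trios_table(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """``cfg.n_families`` trios in long format plus a truth manifest.

    Returns ``(genotype table, manifest)`` where the genotype table has
    columns ``family_id, locus_id, person, allele, peak_area`` and the
    manifest has ``family_id, truth, child_ploidy``.
    """
    rng = cfg.rng()
    geno_rows, manifest_rows = [], []
    for fi in range(cfg.n_families):
        fam = f"F{fi + 1:04d}"
        trio, truth = sim_trio(cfg, rng=rng)
        for locus, persons in trio.items():
            for person, geno in persons.items():
                for allele, area in geno.alleles:
                    geno_rows.append({"family_id": fam, "locus_id": locus,
                                      "person": person, "allele": allele,
                                      "peak_area": area})
        manifest_rows.append({"family_id": fam, "truth": truth,
                              "child_ploidy": 2 if truth == N21 else 3})
    return pd.DataFrame(geno_rows), pd.DataFrame(manifest_rows)


# ---------------------------------------------------------------------------
# MSRE-PCR quartets

def sim_msre(true_meth: float, cfg: SimConfig,
             rng: np.random.Generator | None = None) -> AmplimerQuartet:
    """A peak-area quartet around a true methylation fraction.

    The undigested query:reference ratio A/B equals ``assay_imbalance``; the
    expected digested query area is the methylated (enzyme-resistant)
    template fraction, C = A * true_meth/100, with D matched to B. All four
    areas then receive independent multiplicative lognormal noise with
    CV ``meth_noise_cv``.
    """
    if not 0.0 <= true_meth <= 100.0:
        raise InvalidInputError(f"true_meth={true_meth!r} outside [0, 100]")
    if rng is None:
        rng = cfg.rng()
    b0 = 1000.0
    a0 = b0 * cfg.assay_imbalance
    c0 = a0 * true_meth / 100.0
    d0 = b0
    a, b, c, d = (x * _lognormal_factor(rng, cfg.meth_noise_cv)
                  for x in (a0, b0, c0, d0))
    return AmplimerQuartet(a=float(a), b=float(b), c=float(c), d=float(d))


# ---------------------------------------------------------------------------
# allele-specific reads

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n)) if n > 0 else ""


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            alternatives = [b for b in "ACGT" if b != chars[i]]
            chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def sim_reads(q: SNPQuery, allele_fraction: float, cfg: SimConfig,
              rng: np.random.Generator | None = None) -> list[SeqRecord]:
    """Reads embedding one allele's 29-mer each, as Biopython SeqRecords.

    Each of ``read_depth`` reads carries allele a's substring with
    probability ``allele_fraction`` (allele b otherwise) at a random offset
    inside uniform random flanks, possibly reverse-complemented, then
    per-base substitution errors at ``base_error_rate``. Qualities are drawn
    uniformly in Q30-Q40 so reads pass the default per-read filter.
    """
    if not 0.0 <= allele_fraction <= 1.0:
        raise InvalidInputError("allele_fraction outside [0, 1]")
    if cfg.read_length < len(q.substring):
        raise InvalidConfigError("read_length shorter than the query substring")
    if rng is None:
        rng = cfg.rng()
    from .ase import expand_query
    sub_a, sub_b = expand_query(q)
    reads = []
    for i in range(cfg.read_depth):
        insert = sub_a if rng.random() < allele_fraction else sub_b
        offset = int(rng.integers(cfg.read_length - len(insert) + 1))
        seq = (_random_seq(rng, offset) + insert
               + _random_seq(rng, cfg.read_length - offset - len(insert)))
        if rng.random() < 0.5:
            seq = str(Seq(seq).reverse_complement())
        seq = _mutate(seq, cfg.base_error_rate, rng)
        quals = [int(x) for x in rng.integers(30, 41, size=len(seq))]
        rec = SeqRecord(Seq(seq), id=f"read{i + 1}", description="")
        rec.letter_annotations["phred_quality"] = quals
        reads.append(rec)
    return reads


# ---------------------------------------------------------------------------
# motif-bearing sequences

@dataclass(frozen=True)
class MotifTruth:
    starts: tuple[int, ...]
    motif_length: int

    @property
    def n_units(self) -> int:
        return len(self.starts)

    @property
    def span_bp(self) -> int:
        return self.starts[-1] + self.motif_length - self.starts[0]


def sim_motif_seq(motif: IUPACMotif | str, n_units: int, spacing: int,
                  cfg: SimConfig, rng: np.random.Generator | None = None,
                  flank: int = 200) -> tuple[str, MotifTruth]:
    """A sequence with ``n_units`` concrete motif instances at fixed spacing.

    Degenerate consensus positions are resolved uniformly at random per
    unit; spacers and flanks are uniform random sequence. ``spacing`` is the
    start-to-start distance and must be at least the motif length (unit
    overlap is not modelled).
    """
    if isinstance(motif, str):
        motif = IUPACMotif(motif)
    if n_units < 1:
        raise InvalidConfigError("n_units must be >= 1")
    if spacing < len(motif):
        raise InvalidConfigError("spacing below motif length (overlap not modelled)")
    if rng is None:
        rng = cfg.rng()
    parts = [_random_seq(rng, flank)]
    starts = []
    pos = flank
    for u in range(n_units):
        unit = "".join(
            ch if ch in "ACGT" else str(rng.choice(sorted(_EXPANSION[ch])))
            for ch in motif.consensus)
        parts.append(unit)
        starts.append(pos)
        if u < n_units - 1:
            parts.append(_random_seq(rng, spacing - len(motif)))
            pos += spacing
    parts.append(_random_seq(rng, flank))
    return "".join(parts), MotifTruth(starts=tuple(starts),
                                      motif_length=len(motif))
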
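"""Degenerate IUPAC motif scanning and tandem-array detection.

Scans a DNA sequence for matches to a degenerate consensus such as
AGGYGBYSYAGGACT on both strands, allowing an optional mismatch budget, then
chains same-strand hits at short regular spacing into tandem arrays. The
default consensus is the repeat unit found clustered in the differentially
methylated CpG island upstream of the short WRB transcript variant.

Coordinates are 0-based half-open internally; report writers convert to
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .errors import InvalidInputError

#: Repeat unit clustered at the WRB DMR (CGI-2).
WRB_DMR_CONSENSUS = "AGGYGBYSYAGGACT"

#: Maximum gap (bp) beyond the motif length between consecutive unit starts
#: for hits to chain into one array.
DEFAULT_MAX_GAP = 60

_EXPANSION = {code: frozenset(bases)
              for code, bases in ambiguous_dna_values.items()}


@dataclass(frozen=True)
class IUPACMotif:
    consensus: str

    def __post_init__(self) -> None:
        cons = self.consensus.upper()
        object.__setattr__(self, "consensus", cons)
        if not cons:
            raise InvalidInputError("empty consensus")
        bad = set(cons) - set(_EXPANSION)
        if bad:
            raise InvalidInputError(f"invalid IUPAC characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class MotifHit:
    start: int      # 0-based, half-open [start, start + len(motif))
    strand: str     # "+" or "-"
    mismatches: int

    def end(self, motif_length: int) -> int:
        return self.start + motif_length


@dataclass(frozen=True)
class TandemArray:
    hits: tuple[MotifHit, ...]
    motif_length: int

    @property
    def n_units(self) -> int:
        return len(self.hits)

    @property
    def start(self) -> int:
        return self.hits[0].start

    @property
    def span_bp(self) -> int:
        return self.hits[-1].end(self.motif_length) - self.hits[0].start


def iupac_match(pattern_char: str, base: str) -> bool:
    """True iff ``base`` belongs to the expansion of the IUPAC ``pattern_char``."""
    try:
        allowed = _EXPANSION[pattern_char.upper()]
    except KeyError:
        raise InvalidInputError(f"invalid IUPAC code {pattern_char!r}") from None
    if base.upper() not in "ACGT":
        raise InvalidInputError(f"invalid base {base!r}")
    return base.upper() in allowed


def _mismatches(window: str, consensus: str, budget: int) -> int | None:
    """Mismatch count of window vs consensus, or None once over budget.

    N in the sequence never matches any consensus position.
    """
    mm = 0
    for w, c in zip(window, consensus):
        if w == "N" or w not in _EXPANSION[c]:
            mm += 1
            if mm > budget:
                return None
    return mm


def scan_sequence(seq: str, motif: IUPACMotif | str = WRB_DMR_CONSENSUS,
                  max_mismatches: int = 0) -> list[MotifHit]:
    """All windows of ``seq`` matching the motif on either strand.

    Both the consensus and its reverse complement are slid along the forward
    sequence; a minus-strand hit's ``start`` is the leftmost forward-strand
    coordinate of the window. Hits are sorted by start, then strand.
    """
    if isinstance(motif, str):
        motif = IUPACMotif(motif)
    if max_mismatches >= len(motif):
        raise InvalidInputError("max_mismatches must be < motif length")
    seq = seq.upper()
    if bad := set(seq) - set("ACGTN"):
        raise InvalidInputError(f"invalid sequence characters: {sorted(bad)}")
    cons_fwd = motif.consensus
    cons_rev = str(Seq(cons_fwd).reverse_complement())
    m = len(motif)
    hits: list[MotifHit] = []
    for start in range(len(seq) - m + 1):
        window = seq[start:start + m]
        mm = _mismatches(window, cons_fwd, max_mismatches)
        if mm is not None:
            hits.append(MotifHit(start=start, strand="+", mismatches=mm))
        mm = _mismatches(window, cons_rev, max_mismatches)
        if mm is not None:
            hits.append(MotifHit(start=start, strand="-", mismatches=mm))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def find_tandem_arrays(hits: list[MotifHit], motif_length: int,
                       max_gap: int = DEFAULT_MAX_GAP) -> list[TandemArray]:
    """Chain same-strand hits into tandem arrays.

    Consecutive same-strand hits chain when their start-to-start distance is
    at most ``motif_length + max_gap`` (and at least ``motif_length``, i.e.
    units do not overlap). Chains of two or more hits are arrays; a single
    isolated hit is not.
    """
    if any(b.start < a.start for a, b in zip(hits, hits[1:])):
        raise InvalidInputError("hits must be sorted by start")
    arrays: list[TandemArray] = []
    for strand in "+-":
        strand_hits = [h for h in hits if h.strand == strand]
        chain: list[MotifHit] = []
        for hit in strand_hits:
            if chain and (motif_length <= hit.start - chain[-1].start
                          <= motif_length + max_gap):
                chain.append(hit)
            else:
                if len(chain) >= 2:
                    arrays.append(TandemArray(tuple(chain), motif_length))
                chain = [hit]
        if len(chain) >= 2:
            arrays.append(TandemArray(tuple(chain), motif_length))
    arrays.sort(key=lambda a: a.start)
    return arrays


def hits_table(seq_id: str, hits: list[MotifHit], motif_length: int) -> pd.DataFrame:
    """BED-like hit table with 1-based inclusive coordinates."""
    return pd.DataFrame([
        {"seq_id": seq_id, "start": h.start + 1, "end": h.end(motif_length),
         "strand": h.strand, "mismatches": h.mismatches}
        for h in hits])


def arrays_table(seq_id: str, arrays: list[TandemArray]) -> pd.DataFrame:
    return pd.DataFrame([
        {"seq_id": seq_id, "n_units": a.n_units, "span_bp": a.span_bp,
         "starts": ",".join(str(h.start + 1) for h in a.hits)}
        for a in arrays])
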
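"""Methylation quantification from MSRE-PCR electropherogram peak areas.

A methylation-sensitive restriction enzyme (MSRE) PCR triplex assay amplifies,
in one tube, (1) the query CpG island, (2) a fully unmethylated positive
control that the enzyme digests completely, and (3) a reference region with no
enzyme sites. Methylated (5mCpG) templates resist digestion and still amplify
from digested DNA; unmethylated templates do not. The fraction of
enzyme-resistant templates at the query island is therefore the ratio of query
to reference signal in the digested sample, normalised by the same ratio in
the undigested sample — the latter expressed through the correction factor
``f_AB`` which absorbs amplification-efficiency imbalance between the two
amplimers.

Peak areas are areas-under-peak (AUP) from capillary electrophoresis, in
arbitrary fluorescence units; only their ratios matter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

#: Methylation-state labels.
HYPO = "hypomethylated"
HEMI = "hemimethylated"
HYPER = "hypermethylated"

#: Default state boundaries (percent methylation, inclusive toward extremes).
HYPO_MAX = 20.0
HYPER_MIN = 80.0

#: Clamp slack (percentage points) beyond which a warning is logged.
CLAMP_SLACK = 10.0

#: Default residual-fraction threshold for digestion QC.
QC_RESIDUAL_MAX = 0.05


@dataclass(frozen=True)
class AmplimerQuartet:
    """The four peak areas feeding the methylation equation.

    Parameters
    ----------
    a : float
        AUP of the query CGI amplimer in UNDIGESTED DNA (> 0).
    b : float
        AUP of the digestion-refractory reference amplimer in UNDIGESTED
        DNA (> 0).
    c : float
        AUP of the query amplimer in DIGESTED DNA (>= 0).
    d : float
        AUP of the reference amplimer in DIGESTED DNA (> 0).
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name, val, strict in (("a", self.a, True), ("b", self.b, True),
                                  ("c", self.c, False), ("d", self.d, True)):
            if not math.isfinite(val):
                raise InvalidInputError(f"peak area {name}={val!r} is not finite")
            if val < 0 or (strict and val == 0):
                bound = "> 0" if strict else ">= 0"
                raise InvalidInputError(f"peak area {name}={val!r} must be {bound}")


@dataclass(frozen=True)
class MethylationResult:
    """Outcome of the methylation-ratio computation for one sample x target."""

    f_ab: float
    percent_meth: float
    clamped: bool
    state: str


@dataclass(frozen=True)
class DigestionQC:
    """Digestion-efficiency check on the fully susceptible control amplimer."""

    residual_fraction: float
    passed: bool


def correction_factor(a: float, b: float) -> float:
    """Amplification-imbalance correction factor ``f_AB``.

    ``f_AB = [(A*100/(A+B)) - 50] * 0.02``, i.e. ``2A/(A+B) - 1``: the signed
    imbalance between the query (A) and reference (B) amplimers measured on
    undigested DNA. Zero for a balanced assay, antisymmetric under swapping
    A and B, and strictly inside (-1, 1) for positive areas.
    """
    if not (math.isfinite(a) and math.isfinite(b)):
        raise InvalidInputError("peak areas must be finite")
    if a <= 0 or b <= 0:
        raise InvalidInputError("undigested peak areas must be > 0")
    # (A - B)/(A + B): same quantity as the percentage rendering, with one
    # rounding step instead of three
    return (a - b) / (a + b)


def classify_state(percent_meth: float, *, hypo_max: float = HYPO_MAX,
                   hyper_min: float = HYPER_MIN) -> str:
    """Map a percent-methylation value onto hypo/hemi/hypermethylated.

    Boundaries are inclusive toward the extreme states: ``<= hypo_max`` is
    hypomethylated, ``>= hyper_min`` is hypermethylated, anything between is
    hemimethylated (the state of an imprinted region where exactly one
    parental allele is methylated).
    """
    if not math.isfinite(percent_meth) or not 0.0 <= percent_meth <= 100.0:
        raise InvalidInputError(
            f"percent_meth={percent_meth!r} outside [0, 100]")
    if percent_meth <= hypo_max:
        return HYPO
    if percent_meth >= hyper_min:
        return HYPER
    return HEMI


def methylation_ratio(q: AmplimerQuartet, *, hypo_max: float = HYPO_MAX,
                      hyper_min: float = HYPER_MIN,
                      clamp_slack: float = CLAMP_SLACK) -> MethylationResult:
    """Percent of enzyme-resistant (methylated) templates at the query CGI.

    Computes ``%Meth = 100 * C(1 - f_AB) / (D(1 + f_AB))`` which, by the
    identity ``(1 - f_AB)/(1 + f_AB) = B/A``, equals the digested
    query:reference ratio normalised by the undigested one,
    ``100 * (C/D) * (B/A)``. Values pushed outside [0, 100] by peak-area noise
    are clamped and flagged; excursions beyond ``clamp_slack`` points log a
    warning since they suggest assay failure rather than noise.
    """
    f_ab = correction_factor(q.a, q.b)
    raw = 100.0 * (q.c * (1.0 - f_ab)) / (q.d * (1.0 + f_ab))
    clamped = not 0.0 <= raw <= 100.0
    percent = min(100.0, max(0.0, raw))
    if clamped and (raw < -clamp_slack or raw > 100.0 + clamp_slack):
        logger.warning(
            "raw methylation ratio %.2f%% clamped by more than %.1f points",
            raw, clamp_slack)
    state = classify_state(percent, hypo_max=hypo_max, hyper_min=hyper_min)
    return MethylationResult(f_ab=f_ab, percent_meth=percent,
                             clamped=clamped, state=state)


def digestion_qc(pos_undigested: float, neg_undigested: float,
                 pos_digested: float, neg_digested: float,
                 *, residual_max: float = QC_RESIDUAL_MAX) -> DigestionQC:
    """Check digestion completeness via the 100%-susceptible control amplimer.

    The residual fraction is the control:reference signal ratio after
    digestion, normalised by the same ratio before digestion; with complete
    digestion the control amplimer vanishes and the residual is 0.
    """
    for name, val in (("pos_undigested", pos_undigested),
                      ("neg_undigested", neg_undigested),
                      ("neg_digested", neg_digested)):
        if not math.isfinite(val) or val <= 0:
            raise InvalidInputError(f"{name}={val!r} must be a finite positive area")
    if not math.isfinite(pos_digested) or pos_digested < 0:
        raise InvalidInputError(f"pos_digested={pos_digested!r} must be >= 0")
    residual = (pos_digested / neg_digested) / (pos_undigested / neg_undigested)
    return DigestionQC(residual_fraction=residual, passed=residual <= residual_max)


def quantify_table(df: pd.DataFrame, *, hypo_max: float = HYPO_MAX,
                   hyper_min: float = HYPER_MIN,
                   clamp_slack: float = CLAMP_SLACK,
                   qc_residual_max: float = QC_RESIDUAL_MAX) -> pd.DataFrame:
    """Apply :func:`methylation_ratio` to a peak-area table.

    Expects columns ``sample_id, target, A, B, C, D`` (one row per
    sample x target CGI), optionally ``pos_undigested`` and ``pos_digested``
    for digestion QC against the B/D reference. Returns a table with columns
    ``sample_id, target, f_ab, percent_meth, clamped, state, qc_passed``
    (``qc_passed`` is NA when no control columns are present).
    """
    required = {"sample_id", "target", "A", "B", "C", "D"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"missing columns: {sorted(missing)}")
    rows = []
    has_qc = {"pos_undigested", "pos_digested"} <= set(df.columns)
    for rec in df.itertuples(index=False):
        q = AmplimerQuartet(a=float(rec.A), b=float(rec.B),
                            c=float(rec.C), d=float(rec.D))
        res = methylation_ratio(q, hypo_max=hypo_max, hyper_min=hyper_min,
                                clamp_slack=clamp_slack)
        qc_passed: object = pd.NA
        if has_qc:
            qc = digestion_qc(float(rec.pos_undigested), q.b,
                              float(rec.pos_digested), q.d,
                              residual_max=qc_residual_max)
            qc_passed = qc.passed
        rows.append({"sample_id": rec.sample_id, "target": rec.target,
                     "f_ab": res.f_ab, "percent_meth": res.percent_meth,
                     "clamped": res.clamped, "state": res.state,
                     "qc_passed": qc_passed})
    return pd.DataFrame(rows)


def read_peak_table(path) -> pd.DataFrame:
    """Read a tab-separated peak-area table (header required, UTF-8)."""
    return pd.read_csv(path, sep="\t", encoding="utf-8")


def write_result_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def quantify_samples(quartets: Iterable[AmplimerQuartet], **kw) -> list[MethylationResult]:
    """Convenience vector form of :func:`methylation_ratio`."""
    return [methylation_ratio(q, **kw) for q in quartets]


def oocyte_expectation_from_blastocyst(blastocyst_pct: float) -> float:
    """Expected oocyte methylation implied by a blastocyst measurement.

    At maternal germline DMRs the methylated (oocyte-derived) allele is
    diluted by the unmethylated paternal allele after fertilisation, so
    blastocyst methylation runs at about half the oocyte level; the oocyte
    expectation is therefore twice the blastocyst value (capped at 100).
    """
    if not 0.0 <= blastocyst_pct <= 100.0:
        raise InvalidInputError(
            f"blastocyst_pct={blastocyst_pct!r} outside [0, 100]")
    return min(100.0, 2.0 * blastocyst_pct)
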
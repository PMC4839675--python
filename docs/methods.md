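# Methods

This note records the models, rules and numerical choices behind each
module, what the synthetic-data generators do and do not emulate, and the
known limitations.

## MSRE-PCR methylation quantification (`msre`)

**Model.** The assay amplifies three amplimers from the same template pool:
the query CpG island, a fully HhaI-susceptible control, and a reference
with no HhaI sites. Methylated (5mCpG) query templates resist digestion.
With peak areas *A*, *B* (query, reference; undigested run) and *C*, *D*
(digested run), the methylated fraction is

    %Meth = 100 · C(1 − f_AB) / (D(1 + f_AB)),   f_AB = 2A/(A+B) − 1.

Since (1 − f_AB)/(1 + f_AB) = B/A, this equals 100·(C/D)·(B/A): the
digested query:reference ratio normalised by the undigested one. The
estimator assumes (i) peak area proportional to template amount, (ii) the
per-amplimer amplification efficiency identical across the two runs — any
per-amplimer multiplicative factor then cancels — and (iii) complete
digestion of unmethylated templates (checked by `digestion_qc`).
`f_AB` is computed as (A − B)/(A + B), the same quantity in one rounding
step; this keeps the B/A identity tight to ~1e−13 across three orders of
magnitude of imbalance. The identity and form-equivalence properties are
float-precision statements: evaluating (1 ± f_AB) loses about one part in
10^16 × (A/B), so the property tests sample areas over a realistic
electrophoresis dynamic range (ratios ≤ 10^3–10^5) rather than arbitrary
floats.

**Parameters.**

* State boundaries: hypomethylated ≤ 20%, hypermethylated ≥ 80%
  (inclusive), hemimethylated between. Chosen so the canonical exemplars
  classify as expected — an androgenetic mole near 0% is hypo, blood near
  47–51% hemi, embryonic stem cells at ~82% hyper. Configurable.
* Clamp slack 10 points: raw ratios slightly outside [0, 100] are expected
  from peak noise and clamped silently (flagged in the result); beyond the
  slack a warning is logged, since a 10-point excursion suggests assay
  failure rather than noise.
* Digestion-QC residual threshold 0.05: the control amplimer is fully
  susceptible, so more than 5% survival relative to the reference indicates
  incomplete digestion, which would inflate %Meth.

## STR trio parental-origin inference (`trio`)

**Model.** Nondisjunction is treated as the child receiving two
independent gametes from one parent and one from the other — no meiosis
I/II distinction and no recombination, which is exactly the resolution the
segregation evidence supports. Dosage is resolved from peak areas first
(area ∝ copy number), then every Mendelian-consistent split of the child's
three-allele multiset into a doubled parental pair plus a single gamete is
enumerated. A locus is informative only when all consistent splits name
the same parent; a family verdict (MT21/PT21) needs ≥ 3 informative loci
and unanimity. The enumeration is checked in the tests against a
brute-force oracle over all gamete triples on exhaustive 4-allele
configurations.

**Parameters.**

* 2:1 dosage window: larger/smaller peak ratio in [1.5, 3.0]. 1:1:1 window:
  max/min ≤ 1.6. The qualitative descriptions these formalise
  ("approximately 1:1:1", "consistent 2:1") carry no numbers; the windows
  are centred on the ideals, wide enough for ~5% peak CV, and narrow enough
  that a true 1:1 never passes as 2:1. Configurable.
* Unanimity rather than majority for verdicts: a single contradicting
  informative locus flags the family `inconsistent` instead of being
  outvoted, because a wrong-parent verdict is the costly error.
* Androgenetic verification requires ≥ 10 shared loci, homozygosity at all
  of them, every allele carried by the donor, and ≥ 3 donor-heterozygous
  loci where exactly one donor allele appears (each such locus excludes a
  biparental origin).

## Allele-specific methylation (`asm`)

HhaI cuts unmethylated DNA, McrBC cuts methylated DNA, so at a
heterozygous SNP inside a hemimethylated DMR the two digests reveal
complementary alleles; agreement of the two is the cross-enzyme
consistency check. An allele counts as detected in a digest genotype when
its signal reaches 10% of the major peak (instrument noise floor,
configurable). Parental assignment requires the methylated allele to be
transmissible by exactly one parent.

The trisomy classifier on %Meth alone uses thresholds 58.3 / 41.7 — the
midpoints between the disomic expectation (50) and the trisomic
expectations 200/3 and 100/3 — so the indeterminate band covers the
disomic value. The observed group separation (means near 68 vs 34) leaves
these midpoints > 1.3 noise-sd from either group mean at the ~6-point
between-sample sd used in simulation. Accuracy is reported among samples
reaching a verdict; with the deliberate indeterminate band, counting
indeterminates as errors would bound accuracy near Φ(1.39) ≈ 0.92 by
construction, while wrong-parent calls — the error that matters — stay
below 1%.

## Expression screen (`ase`)

A SNP is interrogated by a 29-character substring with a single biallelic
IUPAC code at the SNP position, expanded to two concrete 29-mers; a read
supports an allele when it contains that allele's 29-mer on either strand
(exact containment, no mismatches). Reads matching both expansions are
excluded as ambiguous. The per-read gate requires ≥ 90% of bases at Phred
≥ 25 (both boundaries inclusive); a separate per-base minimum at the SNP
position is not imposed by default. Classification needs depth ≥ 80;
the allele-a fraction (allele a = alphabetically first base of the code,
a fixed orientation convention) maps to: monoallelic strictly outside
(0.15, 0.85); biallelic inside [0.35, 0.65]; biallelic imbalance between —
the boundary fractions 0.15/0.85 fall in the imbalance band. The
chi-square statistic against 50/50 is (n_a − n_b)²/depth with 1 df, no
continuity correction.

The exact type-I level of the p < 0.05 rule at depth 100 is 0.0569
(discreteness makes it run above nominal). The calibration tests check
this exact level via the binomial pmf and a 10^5-replicate Monte-Carlo
estimate computed per distinct count; 10^5 keeps the estimator sd (~7e−4)
well below the 0.003 distance between the exact level and the 0.06 band
edge, so the check tests the method rather than sampling noise.

## Motif scanning (`motifs`)

Degenerate IUPAC matching on both strands with an optional mismatch
budget (default 0 — the degeneracy already lives in the consensus; N in
the sequence never matches). Same-strand hits chain into a tandem array
when consecutive start-to-start distances lie in [motif length,
motif length + max_gap]; max_gap defaults to 60 bp so seven units at the
observed ~62 bp spacing chain into a single array, and arrays need ≥ 2
units. Coordinates are 0-based half-open internally, 1-based inclusive in
report tables.

## Synthetic data (`simulate`)

What the generators emulate — and deliberately nothing more:

* **Trios**: parents draw alleles uniformly from an 8-allele pool at 5
  unlinked loci (defaults); trisomic children get two independent gametes
  from the origin parent. Peak areas are copy number × 1000 × lognormal
  noise (CV 5%). Not emulated: population allele-frequency skew, stutter
  peaks, null alleles, linkage, meiotic stage structure. Passing tests
  therefore show correctness of the segregation logic, not robustness to
  genotyping artefacts.
* **MSRE quartets**: A/B ratio equals the configured assay imbalance
  (default 1.0; recovery tests use 1.2 so the correction factor is doing
  real work); expected C = A × m/100, D = B; all four areas get
  independent lognormal noise at CV 3%, a plausible within-assay
  repeatability for capillary peak areas. Note the estimator then carries
  ~6% CV (four independent noises), so single-quartet absolute errors of
  2–4 points at mid-range methylation are intrinsic to these conditions;
  the estimator is unbiased and replicate means converge to the truth.
* **Reads**: allele chosen by a Bernoulli draw, embedded at a random
  offset in uniform random flanks, random strand, per-base substitution
  errors (default 10⁻³), qualities uniform in Q30–Q40. Not emulated:
  coverage bias, indels, quality-error correlation, splicing.
* **Motif sequences**: concrete units (degeneracy resolved uniformly) at
  constant spacing in random flanks. Not emulated: unit divergence or
  variable spacing.

All generators are driven by a single integer seed through
`numpy.random.default_rng`; identical configurations are bit-reproducible.

## Problem sizes

The test suite and `scripts/acceptance.py` use 500-family trio cohorts,
100 replicates per methylation level, 100+100 simulated trisomies,
10⁴–10⁵ chi-square replicates and 2-kb scan sequences — sizes at which
every Monte-Carlo check is stable across seeds while the whole suite runs
in seconds.

## Known limitations

* The MSRE estimator assumes run-to-run stability of per-amplimer
  efficiency; a systematic efficiency shift between the undigested and
  digested runs biases %Meth and is invisible to the QC.
* The epigenetic MT21/PT21 classifier presupposes an intact maternal
  imprint; loss of imprinting (as in embryonic stem cells, which run
  hypermethylated) or somatic mosaicism breaks the dosage arithmetic.
* The expression screen's exact 29-mer containment trades sensitivity for
  specificity: reads overlapping the SNP with fewer than 29 matching bases
  are not counted, so effective depth is lower than alignment-based
  counting would give.
* Single-hit "arrays" are never reported; a lone diverged unit next to an
  array is merged only if it still matches within the mismatch budget.
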
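# imprintkit

Tools for parent-of-origin analysis of trisomy 21 through DNA methylation,
built around a maternally imprinted differentially methylated region (DMR)
in the *WRB* gene on chromosome 21.

Most Down syndrome cases carry two maternal copies of chromosome 21 (MT21);
a small minority carry two paternal copies (PT21). Telling the two apart
normally requires genotyping the whole nuclear trio at polymorphic STRs —
impossible when parental DNA is unavailable. Because the *WRB* DMR carries a
maternal germline methylation imprint, the fraction of methylated templates
in the proband alone encodes the answer: a disomic sample runs near 50%
(one methylated maternal allele of two), an MT21 sample near 200/3 ≈ 66.7%
(two of three), and a PT21 sample near 100/3 ≈ 33.3% (one of three).

`imprintkit` implements the full analytical chain as a library with a thin
CLI (`imprintkit <subcommand>`):

| module | what it does |
|---|---|
| `imprintkit.msre` | percent methylation from MSRE-PCR electropherogram peak areas, with digestion QC and hypo/hemi/hyper classification |
| `imprintkit.trio` | parental origin of the extra chromosome from STR trio genotypes (allele segregation + peak-area dosage), and androgenetic-sample verification |
| `imprintkit.asm` | which parental allele is methylated, from HhaI/McrBC digest SNuPE genotypes; MT21/PT21 from percent methylation alone |
| `imprintkit.ase` | monoallelic vs biallelic expression from read sets via 29-mer SNP substring queries, with a chi-square test against 50/50 |
| `imprintkit.motifs` | degenerate IUPAC motif scanning and tandem-array detection (default consensus `AGGYGBYSYAGGACT`, the *WRB* DMR repeat unit) |
| `imprintkit.simulate` | synthetic trios, peak-area quartets, read sets and motif-bearing sequences with known truth, for testing every stage offline |

## The core quantity

A methylation-sensitive restriction enzyme (HhaI) digests unmethylated
templates only. A triplex PCR amplifies the query CpG island (peak areas
*A* undigested, *C* digested) alongside an enzyme-refractory reference
(*B* undigested, *D* digested). The methylated fraction is

```
%Meth = 100 · C(1 − f_AB) / (D(1 + f_AB)),   f_AB = 2A/(A+B) − 1
```

where `f_AB` corrects for amplification imbalance between the two
amplimers; algebraically `(1 − f_AB)/(1 + f_AB) = B/A`, so `%Meth` is the
digested query:reference ratio normalised by the undigested one. It is
invariant to each amplimer's amplification efficiency, and hits 0 and 100
exactly for fully digested and fully resistant templates.

## Worked example

```python
from imprintkit.msre import AmplimerQuartet, methylation_ratio
from imprintkit.asm import epigenetic_origin

res = methylation_ratio(AmplimerQuartet(a=14373, b=18163, c=9254, d=23352))
print(f"{res.percent_meth:.1f}% ({res.state}), f_AB = {res.f_ab:.3f}")
print(epigenetic_origin(res.percent_meth).verdict)
```

prints

```
50.1% (hemimethylated), f_AB = -0.116
indeterminate
```

— a typical disomic blood sample: half the templates methylated (the
maternal allele), so the parental-origin classifier correctly refuses both
trisomy verdicts. A trisomic sample measuring, say, 66% would print `MT21`.

The same analysis from a shell:

```sh
imprintkit meth peaks.tsv            # sample_id, target, A, B, C, D columns
imprintkit origin trio_genotypes.tsv # STR segregation analysis
imprintkit motif region.fasta --arrays-out arrays.tsv
imprintkit simulate --what trios --seed 1 --n-families 100
```

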
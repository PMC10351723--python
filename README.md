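# forenstr

A Python toolkit for sequencing-based forensic short tandem repeat (STR)
data. It is written for forensic genetics laboratories that receive
per-sample Excel "sample detail reports" from sequencing-based STR panels
and need, in one place, to:

* **parse** those reports — length-based genotypes, sequence-based alleles
  (with the "Typed Allele" rule), and identity-informative SNPs;
* **decompose** sequence-based alleles into bracketed repeat structures
  (e.g. `[TCTA]10 TCT`) against administrator-managed reference motif
  patterns, detecting insertions and deletions shorter than the motif;
* **compute** the standard forensic parameter set per locus;
* **rank** reference populations by the commonness of a multi-locus profile
  with a theta-corrected genotype-frequency model;
* **search** a stored cohort by genotype containment, with role-shaped
  output and tabular geographic aggregation;
* **simulate** complete seeded mock cohorts (including the genotype-swap
  anonymization used to build shareable showcase data), so every feature is
  testable with no access to real donor data.

## The statistics

For a locus with observed allele frequencies `p_i` over `N` genotyped
samples:

| quantity | definition |
| --- | --- |
| Hobs | observed heterozygote proportion |
| Hexp | unbiased expected heterozygosity, `(2N / (2N − 1)) (1 − Σ p_i²)` |
| PM | match probability: Σ of squared **observed** genotype-class (or haplotype-class) frequencies |
| PD | power of discrimination, `1 − PM` |
| PIC | polymorphic information content (Botstein), `1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²` |
| PE | power of exclusion (Fisher), `h² (1 − 2 h H²)` with `h = Hobs`, `H = 1 − Hobs` |

Haploid observations (Y loci, hemizygous X) get PM, PD and PIC only;
mixed-ploidy loci are evaluated on their haploid and diploid genotype
subsets separately, never pooled.

For profile search, a locus genotype's expected population frequency is

```
homozygote:   F(x) = p² + p (1 − p) θ
heterozygote: F(x) = 2 p q
```

with θ the population-subdivision correction (θ = 0 recovers Hardy–Weinberg
`p²`). A country's score is `Π 1/F(x)` over the queried loci; the lowest
score marks the population where the profile is most common.

## Worked example

Generate a 20-donor mock cohort, import it into a store, and compute the
per-locus statistics:

```
$ forenstr mock --n 20 --seed 7 --outdir mock
$ forenstr import mock/S*.xlsx --store store --metadata mock/personal_data.xlsx
$ forenstr stats --store store
Locus   Ploidy        N   Hobs     Hexp     PM       PIC      PD       PE
CSF1PO  diploid_only  20  0.65000  0.73974  0.12000  0.67306  0.88000  0.35522
D1S1656 diploid_only  20  0.80000  0.73974  0.13500  0.67760  0.86500  0.59904
D2S441  diploid_only  20  0.90000  0.83077  0.09000  0.78249  0.91000  0.79542
DXS10074 mixed        13                    0.28994  0.65796  0.71006
DXS10074 mixed         7  1.00000  0.82418  0.18367  0.72610  0.81633  1.00000
DYS391  haploid_only  13                    0.39645  0.53948  0.60355
TPOX    diploid_only  20  0.45000  0.50000  0.30500  0.46511  0.69500  0.14737
```

Each row is one statistic set: for example TPOX was typed diploid in all 20
donors, 45% of them heterozygous, and two random donors would share a TPOX
genotype with probability PM = 0.305. The X locus DXS10074 appears twice —
once for the 13 hemizygous (haploid) donors, once for the 7 diploid ones.

Decompose every typed sequence allele against the reference motif patterns
(CSF1PO's pattern is `[ATCT]n` on the forward strand with reverse
orientation, so its report sequences match `[AGAT]n`):

```
$ forenstr align --store store --motifs mock/motif_specs.xlsx
Locus   Allele  Sample ID  Year  Reads  Repeat Structure  Sequence
CSF1PO  9       S0006      2021  465    [AGAT]9           AGATAGATAGAT...
CSF1PO  10      S0001      2021  762    [AGAT]10          AGATAGATAGAT...
...
```

and search the store (laboratory role also returns IDs and geography):

```
$ forenstr search --store store --geno TPOX=8,8 --role laboratory
matches  10
sample IDs  S0001, S0002, S0006, ...
country   Thailand   10
province  Bangkok    2
...
```

`forenstr profile-search`, `forenstr export`, and `forenstr isnp-summary`
cover population ranking, the five-column alignment export workbook, and
SNP genotype-class proportions; see `forenstr COMMAND --help`.

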
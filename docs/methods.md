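# Methods

## Scope and data model

The toolkit operates on per-donor *sample detail reports*: Excel workbooks
with per-chromosome STR sheets (`Autosomal STRs`, `Y STRs`, `X STRs`) and an
optional `iSNPs` sheet. Each STR sheet carries a length-based genotype table
and a sequence-based allele table; a genotype is, by construction, the
multiset of allele labels over the sequence rows whose "Typed Allele" cell
is "Yes" (the *typed-allele law*). The reader enforces this law and refuses
reports that violate it, naming the offending locus. Chart ("Figure") sheets
and the run settings sheet are ignored.

Because the concrete cell layout of these reports varies across software
versions and is not machine-readable from any published schema, the reader
locates each table by scanning for its header row (`Locus` plus allele
columns; `Typed Allele` plus `Reads`) instead of fixed addresses, and the
genotype-column labels are a parameter. Diploid genotypes are accepted both
as two allele columns and as a single comma-joined cell, and are normalized
to numeric non-decreasing order so unordered comparisons are plain equality.
A single allele on an X or Y locus is haploid; a repeated label is a diploid
homozygote. Sequences are uppercased and restricted to A/C/G/T — reports
contain called sequences, not IUPAC ambiguity codes.

## Repeat decomposition

Reference repeat patterns use bracketed nomenclature: `[MOTIF]n` for a
variable block, `[MOTIF]k` for a fixed count, bare runs for literal flanks.
Patterns are authored on the forward strand; a per-locus orientation flag
says the report sequences are reversed, in which case the effective pattern
is the blockwise reverse complement in reverse order. A pattern may be
scoped to a single allele label (microvariants such as D2S441 10.3 often
need their own structure); exact allele scope wins over the locus default,
and loci with no pattern are skipped, not failed.

Decomposition is a dynamic program over (sequence position, block index,
phase within block). Admissible segments are: exact motif copies;
*insertions* of 1..L−1 bases between adjacent copies (L = motif length);
*deletions*, i.e. an interrupted copy missing a contiguous chunk of 1..L−1
motif bases; a trailing partial copy (proper motif prefix) closing a block —
the source of fractional microvariant alleles; and literal flanks of up to a
configurable budget (default 20 bases) at the sequence ends, since some
loci (D1S1656, D5S818) report flanking bases. The objective is
lexicographic: maximize bases in exact copies, then minimize unexplained
bases, then indel bases, then literal bases; remaining ties resolve by a
fixed transition order that prefers the leftmost assignment, so renders are
deterministic. Indels of length ≥ L are never reported: sequence that would
need one is classed as unexplained, and any unexplained bases mark the
alignment as failed while still returning the best partial explanation.

At most one indel event sits at each copy boundary; independent indels at
different boundaries are unlimited. This keeps the DP quadratic and matches
how repeat nomenclature annotates interruptions. Renders are
space-separated tokens: `[MOTIF]count`, literal bases verbatim, `+BASES`
for insertions, `-BASES` for deletions; indel positions are recorded as
offsets into the input sequence. A decomposition can be viewed on the
opposite strand (segment order reversed, every motif and base
reverse-complemented, positions re-mapped), which is an involution and
backs the forward-strand display toggle of cohort alignments.

The test suite checks the DP against an independently written brute-force
segmentation oracle that enumerates every admissible segmentation cost.
Exhaustive agreement is verified for all sequences up to length 10 over a
two-letter alphabet against two single-block specs, with seeded random
sequences covering lengths 11–20 and 200 seeded motif expansions with
injected 1–3-base indels at full allele size; these problem sizes keep the
exhaustive enumeration tractable while exercising every segment type.

## Forensic statistics

Per locus and ploidy subset (haploid and diploid subsets of a mixed locus
are never pooled):

* allele frequencies are observed counts over total observed alleles
  (2 per diploid, 1 per haploid genotype);
* `Hobs` = heterozygote proportion; `Hexp = (2N/(2N−1))(1 − Σp²)`
  (unbiased estimator);
* `PM` = Σ of squared *observed* genotype-class (haploid: haplotype-class)
  frequencies — a match probability, deliberately not derived from expected
  Hardy–Weinberg proportions; `PD = 1 − PM` holds exactly by construction;
* `PIC` = Botstein's `1 − Σp² − Σ_{i<j} 2 p_i² p_j²`;
* `PE` = Fisher's `h²(1 − 2hH²)`, `h = Hobs`, `H = 1 − Hobs`.

Gene diversity is intentionally not reported: published formulations
disagree and the toolkit only ships statistics it can pin to one
definition. Fewer than two diploid genotypes is an insufficient-data
outcome (Hexp undefined), not an error. Internal sums iterate in sorted key
order, so equal multisets of genotypes give bit-identical results under any
sample permutation. Values are stored at full precision; display rounding is
five decimal places, and tests compare at absolute tolerance 1e−5.

## Profile search

`F(x) = p² + p(1−p)θ` for homozygotes, `F(x) = 2pq` for heterozygotes;
θ ∈ [0, 1) defaults to 0 and applies only to homozygotes. A country's score
is the product of reciprocal F(x) over the queried loci, ranked ascending
with lexicographic tie-breaks on country name. Query alleles missing from a
country's table are substituted with a floor frequency (default 0.001) and
flagged per locus — silent exclusion would bias rankings invisibly — while
a strict mode excludes such countries and reports them. Profile queries
cover autosomal diploid genotypes only; a haploid locus in a query is an
input error. Core-loci panels gate queries: a panel displays the default
loci unioned with its own, requires only its own, and validation names any
missing required locus.

## Cohort search, geography, iSNPs

Overview search is exact containment on normalized unordered genotypes: a
sample matches when every queried locus genotype equals its stored one;
lacking a locus fails the match without error. Match counts are therefore
monotone non-increasing in the criteria. Role shapes output only — public
callers get the count, laboratory/administrator callers also get IDs and
per-country/per-province groupings; there is no account system. A kit
restriction constrains which loci may be queried, nothing else. Geographic
aggregation counts a locus's alleles per province and samples per region
over donors that have both metadata and the locus, tallying the rest as
unlocated so totals conserve. iSNP summaries are genotype-class proportions
over non-missing calls.

## Synthetic cohorts

The generator defines the study conditions. Defaults: 125 donors (the
showcase scale the toolkit's validation protocol is written for) over six
loci spanning the three ploidy cases — four autosomal (TPOX, CSF1PO with
reverse orientation, D2S441 with microvariant alleles, D1S1656 with
flanking bases), one Y (DYS391), one X (DXS10074) — plus three iSNPs and a
four-province Thai geographic vocabulary. Allele-frequency vectors are
fixed, realistic single-mode ladders; diploid genotypes pair alleles
independently (Hardy–Weinberg), with an optional inbreeding coefficient to
inflate homozygosity in power tests. Sex is drawn 50/50: males carry
haploid X and Y calls, females diploid X and none, which is what makes X
loci mixed-ploidy at cohort level. Sequences are pure motif expansions
(microvariants append the fractional number of leading motif bases) inside
the locus flanks; an injection option adds sub-motif-length insertions to
exercise the decomposer. Typed rows are emitted one per genotype allele
(homozygotes get two identical rows, keeping the typed-allele law a
multiset identity), and occasional low-read untyped rows exercise the
"Typed Allele" filter. All randomness flows from one integer seed.

What the generator does **not** emulate: sequencing error, stutter
artifacts, coverage imbalance, isoalleles (same length, different
sequence), null alleles, or linkage between loci. Passing tests therefore
demonstrate correctness of the computations on clean, well-formed inputs —
not robustness to raw instrument noise, which the upstream typing software
is assumed to have resolved.

`swap_anonymize` rebuilds a cohort by permuting genotypes within each locus
across the samples carrying that locus, moving each genotype's
sequence-based rows with it. Per-locus genotype and allele multisets are
invariant, hence every per-locus statistic is exactly conserved, while no
output record corresponds to a real donor.

## Storage and interfaces

The sample store is a directory of JSON records plus an index file with
atomic replacement — deliberately desk-scale; no database server and no
concurrent-writer guarantees beyond single-process atomic replace. All
workbooks are XLSX via openpyxl (legacy .xls is out of scope). The
alignment export writes exactly the five columns Sample ID | Sample Year |
Allele | Repeat Structure | Sequence; the report format does not guarantee
a year, so the record's year is optional and exports an empty cell when
absent. The core-loci workbook marks the default panel with the country
value `Default`. The `forenstr` CLI is a thin layer over these functions;
every command is deterministic given its inputs and seed.

## Known limitations

* The bracket-notation grammar is the minimal closure of patterns seen in
  practice (variable/fixed/bare blocks); lowercase flank conventions and
  SNP annotations inside motifs are not parsed.
* Fixed-count blocks must match exactly; indel detection applies to
  variable blocks.
* Decomposition cost grows with sequence length × pattern size; it is
  intended for STR amplicons (tens to a few hundred bases), not reads.
* Profile search implements reciprocal-product ranking only; it is not a
  likelihood-ratio kinship framework and applies no sampling correction
  beyond θ.
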
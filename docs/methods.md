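# Methods

## The statistical model

### Exact conditional Poisson test for two unreplicated libraries

Each library is modeled as a Poisson sampling of transcripts: the count of a
transcript in library *s* is Poisson with mean proportional to its underlying
expression and to the library's total clean reads *N_s*. Under the null of
equal expression, conditioning on the observed count *x* in library 1 yields
the law of the count *Y* in library 2:

    P(y | x) = r^y (x+y)! / ( x! y! (1+r)^(x+y+1) ),   r = N2/N1,

which is negative binomial with *x*+1 successes and success probability
1/(1+*r*). We evaluate the pmf with log-gamma arithmetic and the cumulative
tails in closed form via the regularized incomplete beta function:
`Pr(Y ≤ y | x) = I_p(x+1, y+1)` with `p = N1/(N1+N2)`, and
`Pr(Y ≥ y | x) = I_{1-p}(y, x+1)` for y ≥ 1. This is the same log-gamma-stable
computation an explicit shorter-tail summation would perform, without the
loop, and it remains accurate for counts up to the millions (verified against
an exact rational-arithmetic oracle to ~1e-13 relative error in the tests).

**Two-sidedness and symmetry.** The two-sided p doubles the smaller of the
two tails and is capped at 1. Because the conditional law depends on which
library is conditioned on, the naive doubled-tail rule is not invariant under
relabeling the two libraries (e.g. x=0, y=1 at equal totals gives 1.0 one way
and 0.5 the other). We therefore canonicalize the orientation: the library
whose (count, total) pair is lexicographically smaller is always the
conditioning one. This preserves the conditional-tail form of the test and
makes `p(x, y, N1, N2) = p(y, x, N2, N1)` hold exactly.

**Zero-count pairs.** Transcripts absent from both libraries are retained
with p = 1 and log2 fold change 0 rather than filtered; they carry no
evidence in either direction and retention keeps output rows aligned with
input rows.

**Effect size.** FPKM = count / ((length/1000)·(total/10^6)); single-end
reads are counted as fragments. The fold change is log2(FPKM_b/FPKM_a) with
0.01 substituted for zero FPKM, so fold changes are finite and antisymmetric.
The DE call combines Benjamini–Hochberg q ≤ 0.001 with |log2FC| ≥ 1; both
thresholds are parameters. BH (an FDR-controlling step-up) is used for the
q-values because the thresholds are phrased as an FDR bound; underflowing
p-values are clamped at the smallest positive normal double before the
step-up so ranks are preserved.

### Over-representation and dual-context selection

Enrichment of a term with *M* annotated genes among *n* DEGs in a universe of
*N* annotated genes is the hypergeometric upper tail Pr(X ≥ m), evaluated
with `scipy.stats.hypergeom`. Three choices deserve note:

- **Unit of analysis is the gene (isoform group), not the transcript.** A
  gene is a DEG for a contrast if at least one of its transcripts is DE.
  Counting transcripts would let genes with many assembled isoforms dominate
  the test.
- **Universe per ontology** is the set of genes carrying at least one
  annotation in that ontology, not all assembled genes; genes without
  annotation carry no information for the test.
- **Correction policy.** Every term is reported with raw p, Bonferroni-
  corrected p and BH q, so both a family-wise and an FDR reading are
  available for either ontology.

Dual-context selection keeps a term iff its p-value is ≤ α (default 0.05) in
both the grazing-response contrast and the differential-tolerance contrast.
By default the Bonferroni-corrected p is thresholded (`use_corrected=False`
switches to raw p, since published tables do not always state which scale
they print). Terms present in only one context are retained with the missing
p set to 1 (never selected) plus a warning; output is ordered by ascending
tolerance p with term-id tie-breaks for determinism.

### Candidate patterns

The contrasts are oriented as TG-vs-TU (response; ungrazed tolerant baseline)
and IG-vs-TG (tolerance; grazed tolerant baseline). A transcript is

- *suppressed with tolerant advantage* iff DE down in the response contrast
  and DE with negative fold change in the tolerance contrast (intolerant
  below tolerant);
- *upregulated with tolerant advantage* iff DE up in response and DE with
  negative tolerance fold change;
- *other* in all remaining cases, so the three patterns partition
  transcripts.

"Abundance" is FPKM (the quantity the profiles are drawn in), and the
tolerance requirement uses the DE call of the IG-vs-TG contrast, not a raw
FPKM comparison. A gene inherits a pattern iff at least one isoform carries
it and no isoform carries the opposite pattern; non-candidate isoforms do not
veto a call (isoform detection is partial in de novo assemblies), directional
conflict does. Candidates are patterned genes annotated to at least one
dual-context-selected term.

### SNP consistency filter

Per sample, an IUPAC consensus is called from the base composition at a
position: alleles need coverage ≥ 4 reads overall, ≥ 2 supporting reads and
≥ 20% frequency (all configurable; these thresholds are this package's
declared defaults — no published caller is being matched). One allele yields
that base, two the corresponding ambiguity code; with more than two
candidate alleles, the lowest-frequency ones are dropped, and an unresolvable
tie rejects the position.

A site is reported iff the grazed and ungrazed tolerant libraries carry the
same single base and the intolerant library differs — a different single base
or any two-base ambiguity code. This is the literal monomorphic/polymorphic
rule; sites heterozygous in all three libraries (a configuration that does
appear in published variant tables) are deliberately rejected, and the
simulator plants exactly such sites as decoys. Variant alleles are reported
as `ref:alt` (ref = the shared tolerant base).

Positions are 1-based from the transcript 5' end; transcripts are treated as
sense-strand assembled mRNA. With a CDS interval, positions before it are
5'UTR, after it 3'UTR; inside, the affected codon is translated with each
alternative allele (standard genetic code; stops rendered as `X`), giving
`synonymous` or per-allele `From->To (allele)` strings (ASCII arrow). A
transcript without CDS is annotated `noncoding`. The test suite checks the
codon-level annotation against an independent oracle that translates the
whole CDS before and after the substitution.

### Welch tests

t = (m1−m2)/√(s1²/n1+s2²/n2) with Welch–Satterthwaite degrees of freedom and
a two-sided p from the t distribution (delegated to
`scipy.stats.ttest_ind_from_stats`). Reported SDs are assumed to be sample
SDs (n−1 divisor); this convention reproduces the published trait p-values to
their printed precision. The raw-value form computes the same summaries first
so the two entry points agree to machine precision.

## The synthetic generator

`simulate_experiment` emulates the study design: ~2,000 genes with 1–4
isoforms each (≈5,000 transcripts), lengths 300–3,000 bp, three libraries of
2×10^6 clean reads, and baseline FPKM drawn log-normal(μ=2, σ=1) — a median
around 7 FPKM with a realistic heavy right tail. Counts are Poisson with mean
FPKM·kb·(N/10^6), matching the DE test's own null; there are no replicates
to estimate over-dispersion from, which is precisely the regime the exact
test addresses.

Planted structure:

- 10 suppressed-advantage and 10 upregulated-advantage genes with ±2 log2
  effects per contrast (margin 2× the calling threshold). Their baselines
  are floored so the weakest library still expects ≥ 40 reads per transcript:
  candidate genes in this kind of screen are by construction well-measured,
  and without the floor a low-expression "planted" gene would be planted in
  name only.
- Additional DE genes (8% response-only, 5% tolerance-only, 3% both) whose
  tolerance effects are positive (intolerant higher), so they are DEG-set
  members and enrichment fodder but can never form a tolerant-advantage
  pattern; they double as wrong-direction bait for the classifier.
- Two ontologies (GO-like, 50 terms; KEGG-like, 30 terms) with five planted
  terms each containing every pattern gene plus both-contrast DE genes —
  over-represented in both DEG sets — against random background terms.
- 10 consistent SNP sites plus decoy sites covering every violation class of
  the filter (tolerant-discordant, all-identical heterozygous, all-identical
  monomorphic, intolerant-uncovered), with multinomial base counts at 30–80×
  coverage and a 1% per-read error rate.
- Phenotype traits drawn normal with the published group means/SDs at n=10
  per group.

What the generator does **not** emulate: over-dispersion beyond Poisson,
assembly artifacts (chimeras, fragmented transcripts, mis-grouped isoforms),
positionally correlated sequencing error, allele dosage in a polyploid, or
GO-graph structure (terms are flat, independent sets). Passing the planted-
recovery tests therefore demonstrates correctness of the pipeline's logic
under its own model assumptions, not robustness to real-data violations of
them.

## Numerical choices and edge cases

- All test probabilities are computed in log space (log-gamma / incomplete
  beta); no factorials are formed.
- p-values are clamped to (tiny, 1] before multiple-testing correction.
- Output orderings are fully deterministic (tolerance-p then term-id for
  selections; gene-id for candidates; transcript-id, position for SNPs).
- Degenerate inputs fail loudly: zero lengths/totals, p-values outside
  (0, 1], conflicting isoform groupings, CDS out of frame or out of bounds,
  reference-base mismatches between a SNP report and its sequence.
- The acceptance script scales its checks to desk size (oracle grid x+y ≤ 60,
  10,000 null transcripts, five simulation seeds), chosen so the entire
  recomputation completes in seconds while keeping every estimate's Monte
  Carlo error far below the decision margins.

## Known limitations

- The exact test's p-values are conservative near the cap and discrete at
  small counts; q-values inherit that discreteness.
- Gene-level DEG status ("any isoform DE") is a deliberate, simple rule; it
  can flag a gene on a single minor isoform.
- The SNP caller is a threshold consensus on base compositions, not a
  genotype-likelihood model, and makes no attempt at allele dosage in
  autotetraploids.
- With a single library per condition, "differential expression" conflates
  biological and library effects; nothing in the statistics can separate
  them. The package implements the design faithfully rather than fixing it.
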
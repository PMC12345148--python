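# Methods

## Edit-calling model

An A-to-I edit manifests in RNA sequencing as an A→G substitution on the
transcribed plus strand or T→C on the minus strand. The caller therefore
considers only reference-A/T pileup positions and, per position, one
candidate change determined by the reference base. Filters, all exposed in
`CallThresholds`:

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 10 reads | minimum RNA depth |
| `min_variant_reads` | 3 reads | minimum edited-read support |
| `min_fraction`, `max_fraction` | 0.05, 0.95 | editing-fraction window; the upper bound removes residual homozygous variants |
| `complex_fraction` | 0.05 | a position where either remaining base reaches this fraction is excluded as a likely unmasked variant/artifact |
| `drop_unassessable` | true | exclude positions lacking ≥ `min_depth` DNA evidence |

Strand handling: inside an annotated gene only the strand-consistent change
is eligible and the call credits every containing gene on that strand (a
site inside two overlapping same-strand genes credits both); intergenic
positions are accepted in either orientation and reported unstranded, since
transcript strand is unknowable without annotation. Germline masking is a
hard exclusion: a position is masked when pooled exome depth ≥ 10 and any
non-reference base reaches 10% of it, or when it appears on a supplied
known-variant list.

## Consensus rules

Site identity is `(contig, position, change)`, so opposite-orientation
events at one coordinate are distinct sites (they imply different edited
transcripts). The default consensus is *all* animals of a genotype, for
sites (identical key everywhere) and for genes (≥ 1 passing call anywhere
in the gene's full span, introns included, per animal). A k-of-n
generalization exists for sensitivity analyses but is not the default.
Because per-animal sites need not coincide for the gene rule, the genes of
the consensus-site set are a subset of — typically smaller than — the
consensus gene set; this containment is enforced by tests.

Feature precedence for annotation is 3′UTR > 5′UTR > CDS > intron, i.e. a
base annotated as UTR is reported as UTR rather than generic exon; this is
a documented convention, chosen because 3′UTR editing is the biologically
salient class for ADAR substrates. Repeat-class assignment is orthogonal
(a site can be intron + SINE); overlap ties break by smallest interval,
then alphabetical class.

## Synthetic study and its oracle

The generator emulates the study design the package targets: four genotypes
× four animals; a wild-type-like common pool of edited sites shared by
`WT`, `Adar_het` and `RdRp_tg` (360 sites by default, plus 25 private sites
each); and a `DoubleHet` genotype carrying the common pool plus a large
private pool (240 sites), sized so its consensus editome exceeds the others
by ~56% — inside the 50–65% excess regime the comparison stage is meant to
resolve. Placement weights (intergenic 0.50, 3′UTR 0.30, CDS 0.08, intron
0.08, 5′UTR 0.04) concentrate sites where ADAR substrates live; per-site
editing fractions are Uniform(0.2, 0.7); 150 colony-shared SNPs (half
heterozygous) appear in both DNA and RNA evidence, which is what makes the
masking stage non-trivial. The toy genome is 2 × 60 kb with 120 tiled
5′UTR–CDS/intron–3′UTR genes on random strands and uniformly placed repeat
elements that may overlap genes. Defaults for depth are Poisson(50) RNA and
Poisson(40) pooled exome, both zero-truncated, with symmetric sequencing
error 0.005 (e/3 to each non-reference base). These sizes were chosen once
as a desk-scale instance that preserves the study's structure; the unit
suite uses a further-scaled 40 kb version of the same regime.

The truth object carries an analytic detection oracle: for a site with
editing fraction f, the per-animal probability of a passing call integrates
the zero-truncated Poisson depth against the Binomial(d, p) variant count
with p = f(1−e) + (1−f)e/3, the variant-read and fraction windows, and the
complex-position exclusion (each off-target base count Binomial(d, e/3),
treated as independent — accurate to well below the Monte-Carlo noise at
realistic error rates). Consensus probability is this raised to the number
of animals; summing over planted sites gives the expected consensus-site
count per genotype. Expected consensus *gene* counts are not claimed
analytically (they are a union over per-gene site sets without a clean
closed form); gene-level behaviour is checked structurally instead.

What the generator does **not** model: read-level artifacts (alignment,
duplicates, base-quality structure), splicing-aware coverage,
hyper-editing clusters, strand-specific library biases, and overdispersed
coverage. Passing recovery tests therefore demonstrates correctness of the
statistical pipeline under its stated model, not robustness to alignment
pathology in real data.

Expression counts for the DEG plumbing are Poisson–log-normal (gene means
log-normal around 8 with σ=1.2, sample jitter σ=0.2), with ISG genes (30%
of genes) scaled per genotype by 1 / 1.5 / 4 / 16 — the double heterozygote
four-fold above the RdRp transgenic, matching the three-to-five-fold regime
the comparison is designed around.

## Statistical choices

- **ISG enrichment** uses a two-sided Fisher exact test (hypergeometric) on
  (ISG vs not) × (unique vs shared) over genic consensus sites; the sample
  odds ratio is reported with the ±inf convention on zero margins alongside
  a Haldane-corrected (+0.5) estimate.
- **BH adjustment** is the standard step-up procedure (via statsmodels),
  cross-checked in tests against an explicit backward-minimum loop.
- **The built-in DEG caller** is plumbing only: log2 fold change of group
  means with one pseudocount and an exact Mann–Whitney p per gene. With
  four animals per group the exact two-sided p cannot fall below
  2/70 ≈ 0.0286, so a BH-adjusted 0.05 cutoff is unattainable unless most
  genes are differential; the pipeline's summary of this caller therefore
  uses adjusted p < 0.1 (a granularity-matched choice, documented here),
  while `deg_isg_summary`'s own default stays at 0.05 for externally
  supplied DEG tables from real DE packages.
- **Expression heatmap transform** is elementwise log(x + 1) (natural log by
  default, base selectable), exact-inverse tested.

## Numerical and engineering notes

- All interchange coordinates are 1-based inclusive; BED is converted
  exactly once at parse/write time (0-based half-open), and the conversion
  is round-trip tested.
- All randomness flows from a single seed through fixed
  `SeedSequence` spawn keys (genome, truth, expression, one stream per
  animal), so adding samples never perturbs existing ones and identical
  configs give byte-identical outputs, including the pipeline's
  `report.json`.
- Degenerate inputs: empty genotypes produce zero-count summaries rather
  than errors; a zero baseline makes percent change an explicit error; an
  empty genic-site universe makes the ISG proportion an explicit error;
  consensus with `n_required` above the animal count is a parameter error.
- Venn cells are materialized for all 2⁴−1 label subsets, so empty cells
  are reported as zeros rather than omitted.

## Known limitations

- The caller consumes base-count pileups; producing them (alignment,
  dedup, counting) is upstream and out of scope, as are editing-index
  summaries and hyper-editing rescue.
- Multi-allelic and strand-ambiguous positions are excluded rather than
  modeled; the complex-position rule is a heuristic, not a genotyper.
- ISG membership must be supplied; the package never infers it.
- The Fisher test treats sites as independent observations; clustered
  editing within one repeat element violates this mildly, as it does in
  the analyses the package reproduces.
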
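# Methods

This note documents the models, defaults and numerical choices behind
`p1bslink`, and what the synthetic-study tests do and do not demonstrate
about real data.

## The analysis model

The pipeline studies a transcription factor (TF) that activates a stress
response through a degenerate promoter element.  Its working model, in the
Pi-starvation idiom used throughout the package:

- **Direct targets** carry one or more copies of the element (P1BS,
  `GNATATNC`) in the proximal promoter; their induction is element-driven
  and survives translation inhibition (the GR-fusion + DEX + CHX design).
- **Indirect targets** are induced (or repressed) downstream of the TF
  without binding sites; their response collapses in the TF mutants but not
  in the CHX experiment.
- A fraction of the response is TF-independent (driven by other
  regulators), so mutant attenuation is partial at the population level.
- A second element (motif B, `GAWGATNC`) contributes only in *cis*
  proximity to P1BS, which motivates the distance-capped co-occurrence
  statistic.

## Region partition

Each gene's neighbourhood is split into eight parts: distal promoter
(−3000..−1000 from the TSS), proximal promoter (−1000..0), 5′UTR, CDS,
intron, 3′UTR, proximal downstream (0..+1000 past the TES) and distal
downstream (+1000..+3000).  Intervals are 0-based half-open internally
(GFF3 I/O converts to/from 1-based inclusive); partitions are strand-aware
and clipped at chromosome edges; degenerate parts (intronless genes,
non-coding genes) are empty lists, with a non-coding transcript assigned
wholly to the 5′UTR.  The promoter anchor is the annotated TSS by default;
because promoter fragments are often cloned up to the start codon, an
`anchor="atg"` switch re-anchors the two promoter windows at the
translation start.  For multi-transcript genes the canonical transcript is
the one with the longest CDS (ties: longest transcript, then smallest id).
Neighbouring genes' windows may overlap — counts are per gene, not per
genomic base.

## Motif scanning and counting

Scanning is exhaustive over all windows, with overlapping matches all
reported: enrichment arithmetic assumes no greedy consumption.  Both-strand
scanning is the default; a window matching the reverse complement of the
pattern is reported once on `-`, and a window matching both ways at one
start is reported once on `+`.  For P1BS both-strand scanning is a no-op
(the pattern equals its own reverse complement); for motif B it roughly
doubles sensitivity.  An `N` in the reference matches only an `N` pattern
position.  Hits are assigned to the region containing their start
coordinate (half-open intervals make boundary assignment unambiguous), and
per-gene counts are per distinct start position.  The `any` column is the
row sum over the eight mutually disjoint regions, i.e. the −3 kb..+3 kb
count behind the "fraction of genes lacking the element" statistic.

## Differential expression

`contrast()` computes log2FC as the difference of group means of log2
expression and a two-sample t statistic.  With three replicates per group a
per-gene test has only ~4 residual degrees of freedom, and the heavy t
tails then dominate power at FDR-adjusted thresholds.  Because the
package's synthetic data (and microarray data generally) have comparable
variances across genes, the default test shrinks the pooled per-gene
variance toward the across-gene mean with a fixed prior weight of 20
pseudo-df (the classic Cyber-T-style stabilisation; Baldi & Long 2001,
Bioinformatics 17:509) and uses a t reference with the augmented df.  This
is deliberately *not* an empirical-Bayes estimator — no hyperparameter is
fit — and `moderate_var=None` restores the plain Welch test.  Externally
computed contrast tables (gene_id, log2fc, p, fdr) can be substituted
anywhere a contrast is consumed, so moderated statistics from a dedicated
DE package drop in directly.  BH adjustment is applied within each
contrast over all genes in the matrix.  Degenerate zero-variance groups
resolve exactly (equal → p=1, unequal → p=0).

Tiered responsiveness calls use fold + FDR cut-offs (up iff
log2fc ≥ log2(fold) and FDR < q); tier sets nest by construction.  The
mutant-effect table reports, per wild-type tier × direction, the percentage
of those genes called down ("reduced") or up ("increased") in each
mutant-vs-wt contrast under starvation, at both the strict (2×, FDR<0.05)
and relaxed (1.5×, FDR<0.1) cut-offs; empty cells are undefined (NaN), not
zero.  Mutant comparisons are mutant-vs-wt under starvation; the
within-genotype starved/replete ratio is available by changing the group
specs.  Tissues are analysed as independent contrast families.

## Enrichment, dosage and specificity

Relative element content per region is the ratio of per-gene mean hit
counts, focal set over universe (universe ≡ 1).  "Content per gene" is an
arithmetic mean, not a length-normalised density, matching how per-region
content is conventionally plotted; a `per_kb` option reports densities as
well.  Significance is a 1-df χ² of the focal set's total hits against the
universe-rate expectation (two cells: in/out of the focal set); an exact
two-sided binomial is available for small counts and agrees with the χ²
within ~10 % once expected counts reach ~20.

The dose curve sorts induced genes by log2FC (descending, gene-id
tie-break, since rank ties must resolve deterministically), slides a
30-gene window at one-gene steps and emits (mean count, mean log2FC) per
window; Spearman ρ across windows summarises the trend.  Specificity
scores count the other conditions (default 28, supplied as opaque binary
columns) in which an induced gene is also induced; genes are binned by
promoter count class {0, 1, >1} and compared by an r×c χ² on score bins
{0, 1, 2, ≥3} — a binned contingency is the most direct χ² construction
for comparing score distributions across classes.  Degenerate tables
(e.g. all scores zero) report p = 1.

## Co-occurrence nulls

Two motifs are "linked" in a gene when some hit pair sits within a 25 bp
edge-to-edge gap (overlapping hits have gap 0; a start-to-start option
covers the alternative reading of "distance between the two motifs").  The
counting unit is genes with ≥1 linked pair.  The default null redraws the
B-hit offsets uniformly within each gene's region, preserving per-gene
counts (seeded, default 1999 permutations); the expected count is the
permutation mean.  The p-value is the randomized rank of the observed count
among the permuted counts: because the statistic is a small integer, the
deterministic `#{perm ≥ obs}` rule is conservative under heavy ties,
whereas the randomized rank is exactly discrete-uniform on
{1/(n+1), …, 1} under the null — this is what makes the null-calibration
test (KS against Uniform(0,1) over replicate genomes) meaningful.  The
analytic null sums per-gene linkage probabilities under independent uniform
placement — exact by enumeration for the one-A-one-B case, seeded
Monte-Carlo (2000 draws/gene) otherwise — and reports the one-cell
χ² = (O−E)²/E (1 df, upper tail), the statistic used in the worked example
(O=26, E=12.4 → χ²=14.92, p≈1.1×10⁻⁴).

## Set overlaps

Overlap significance is the exact hypergeometric upper tail
P(X ≥ |A∩B|) with the expression matrix as the default universe;
enrichment is the directional claim of interest, hence one-sided.  Flag
representation (e.g. TF genes in a shared set) is the ratio of flagged
fractions with a two-sided Fisher test.  Overlap matrices report raw p
plus a BH column as convenience.  The GSR cross-tabulation reports, per
catalogue, the starvation-induced subset (2×, FDR<0.05) and the percentage
of it down in the double mutant (1.5×, FDR<0.1).

## The synthetic study

The generator emulates the replicated two-condition, multi-genotype,
two-tissue design the downstream statistics assume.  Defaults (the
conditions every recovery test runs at): 2000 genes; GC 0.36
(Arabidopsis-like); 15 % direct targets with Poisson(1.5) planted proximal
P1BS copies clipped to ≥1 and effect 1.5 + 0.5·copies log2; 15 % indirect
induced genes (effects U(1.5, 3), half TF-dependent so that exactly 75 %
of induced genes are TF-controlled); 10 % repressed genes (effects
−U(1, 2.5), all indirectly TF-dependent); genotype attenuation wt 1.0,
single mutant 0.3, double mutant 0.05; replicate noise sd 0.25 log2 with 3
replicates; half the direct targets get a linked motif B at a planted edge
gap of 1–25 bp.  Class, dependency, tissue-profile and flag fractions are
allocated as exact rounded counts, not per-gene coin flips, so planted
fractions are exact.  Genes sit in non-overlapping ±3 kb slots with a
fixed exon/intron layout; a flag places every other gene on the minus
strand to exercise strand logic; planted sites never overlap (rejection
sampling), keeping truth counts unambiguous.  Expression is generated
directly on the log2 scale — the downstream statistics consume log-ratios,
and probe/intensity modelling is out of scope.  The DEX+CHX pseudo-
genotype contrast expresses only the element-driven component (multiplier
1.0 in the overexpressor vs 0.3 in the mutant background), mimicking
translation-blocked TF activation.  Per-gene activity in {both, shoot,
root} (0.7/0.15/0.15) gives the two tissue contrast families distinct
responsive sets.  Direct targets draw Poisson(2) other-condition
inductions vs Poisson(5) for all other genes, encoding the greater
starvation-specificity of element-carrying targets.

What the generator does **not** model — and therefore what passing
recovery tests do not show about real data: probe-level microarray noise
and normalisation artefacts, gene-length and GC heterogeneity, clustered
or dinucleotide-structured background sequence, position or orientation
preferences of real binding sites, correlated replicate effects, and any
genome-scale linkage between neighbouring genes.  Real-genome, real-array
counts cannot be reproduced at this scale; the worked-example statistics
(26 vs 12.4; the pooled GSR fraction) are recomputed from their catalogue
counts as fixed inputs.

## Problem sizes and determinism

Recovery tests run at 2000 genes (≈16 Mb of sequence), chosen so that
sampling error on the recovered quantities (Spearman ρ of ≈480 sliding
windows, precision/recall over 300 planted targets, a percentage over
≈510 genes) is small against the tested margins while the whole suite
stays fast.  Null calibration uses 50 replicate 300-gene genomes with 199
permutations each.  Every random draw flows from one integer seed through
`numpy.random.SeedSequence` spawning; equal seeds give byte-identical
FASTA/GFF3/TSV artifacts and identical pipeline reports.  The sliding-
window ρ for a region with no planted dosage effect is itself a stochastic
quantity with standard deviation ≈0.24 under the null (windows of 30 over
≈500 genes are heavily autocorrelated), so its small-magnitude check is a
single-seed statistical statement, not a deterministic bound.

## Known limitations

- The analytic co-occurrence null is exact only for one-A-one-B genes;
  higher counts use within-gene Monte-Carlo, and joint placement
  inclusion–exclusion over pairs sharing a hit is not implemented.
- The moderated test assumes roughly exchangeable per-gene variances; with
  strongly variance-heterogeneous data, supply external contrast tables or
  set `moderate_var=None`.
- Region partitioning uses one canonical transcript per gene; splice-aware
  region sets are out of scope.
- The 28 other-condition calls are opaque binary inputs; no attempt is
  made to model which conditions they are or their thresholds.
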
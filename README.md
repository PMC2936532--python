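# p1bslink

Regulatory-genomics toolkit for linking a promoter *cis*-element to the
transcriptional response it drives, modelled on the phosphate (Pi)
starvation response in *Arabidopsis*: the MYB-CC transcription factors
PHR1/PHL1 bind the degenerate element **P1BS** (`GNATATNC`, an imperfect
palindrome equal to its own reverse complement) and activate Pi
starvation-induced genes, assisted by a second promoter element, **motif B**
(`GAWGATNC`), that acts only in concert with P1BS.

The package implements the computational arc of that analysis as a tested
pipeline, for anyone asking the same questions of a TF/element pair:

- **IUPAC motif scanning** — exhaustive, both-strand, overlap-aware hit
  detection for degenerate consensus motifs.
- **Region-resolved element content** — each gene's ±3 kb neighbourhood is
  partitioned into eight parts (distal/proximal promoter, 5′UTR, CDS,
  intron, 3′UTR, proximal/distal downstream) and per-gene hit counts are
  normalised to the genome average (universe ≡ 1), with χ² significance and
  the fraction of genes lacking the element anywhere in −3 kb..+3 kb.
- **Differential expression & set algebra** — two-sample contrasts with
  variance moderation and Benjamini–Hochberg FDR; tiered responsive sets
  (4×/2× at FDR<0.05, 1.5× at FDR<0.1); mutant-effect cross-tabulations;
  direct-target calling from a DEX+CHX posttranslational-activation design.
- **Motif dosage vs inducibility** — genes ranked by log₂ fold induction,
  sliding windows of 30 genes at one-gene steps, mean element count per
  window against mean induction (Spearman ρ summarises the trend).
- **Cross-stress specificity** — number of other stress conditions (of 28)
  in which an induced gene is also induced, binned by promoter element
  count {0, 1, >1}.
- **Distance-constrained co-occurrence** — genes with a motif-B hit within
  a ≤25 bp edge-to-edge gap of a P1BS hit, tested against a within-gene
  permutation null (seeded) or an analytic uniform-placement null, with the
  one-cell χ² = (O−E)²/E worked-example statistic.
- **Gene-set overlap statistics** — exact hypergeometric enrichment between
  responsive sets, Fisher tests of flag (e.g. TF) representation in shared
  sets, and the general-stress-response (GSR) cross-tabulation.
- **Synthetic study generator** — a toy genome + replicated
  two-condition (+Pi/−Pi), multi-genotype (wt, *phr1*, *phr1 phl1*,
  GR-fusion overexpressor), two-tissue expression design with
  motif-dosage-dependent induction planted in promoter sequences and a
  full ground-truth table, used for parameter-recovery testing.

## Worked example

Run the full pipeline on a synthetic study from one YAML config:

```bash
cat > config.yaml <<EOF
outdir: demo_out
seed: 1
cooccur_n_perm: 1999
synthetic:
  seed: 1
  n_genes: 2000
EOF
p1bslink run --config config.yaml
```

This generates the genome, scans both motifs, computes all contrasts and
writes `demo_out/report.json`. With seed 1 the report contains (among other
sections):

```
"dose":    {"spearman_rho": {"prox_prom": 0.859, "downs2": 0.010, ...}}
"cooccur": {"observed": 134, "expected": 25.99, "p": 0.0005, ...}
"de":      {"shoot": {"n_up": 510, ...},
            "direct_targets": {"n_ox_up": 298, ...}}
```

Reading: induction strength tracks planted promoter element dosage
(ρ ≈ 0.86 in the proximal promoter, no correlation downstream); linked
P1BS–motif-B pairs are five-fold enriched over the permutation null
(134 observed vs 26 expected, permutation p = 5×10⁻⁴); and the DEX+CHX
contrast recovers 298 candidate direct targets out of the 300 planted.
Each stage is also available as a subcommand (`generate`, `scan`, `de`,
`enrich`, `dose`, `specificity`, `cooccur`, `overlap`) that resumes from
the files earlier stages left in the output directory.

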
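# rankmeth

Window-based differential DNA-methylation analysis for methylation-capture
(MBD-Seq) count data, built for studies that ask whether a two-level trait
— here, social rank class in a wild mammal cohort of cubs and adults —
leaves a genome-wide methylation signature. In MBD-Seq the read depth over
a region tracks its methylation level, so the question becomes one of
differential count abundance.

The pipeline, end to end:

1. **Counting & normalization** — tile the genome into 300-bp windows,
   drop low-information windows (< 10 reads total or positive in < 10
   samples), and compute TMM (trimmed mean of M-values) factors so that
   composition bias does not masquerade as methylation change.
2. **Window-level testing** — for each window w and sample i, a
   negative-binomial GLM with log link:

       log mu_wi = beta_0w + beta_aw·[age_i = cub] + beta_rw·[rank_i = low] + log(L_i f_i),
       Var(Y) = mu + phi·mu²

   with empirical-Bayes dispersion estimation (Cox-Reid adjusted profile
   likelihood, tagwise shrunk toward the common value), a 1-df
   likelihood-ratio test of the rank effect, and genome-wide
   Benjamini-Hochberg adjustment. logFC = beta_rw / ln 2 > 0 means
   hypermethylated in the low-ranking class.
3. **DMR calling** — maximal runs of adjacent significant (FDR ≤ 0.05)
   windows sharing one effect direction merge into differentially
   methylated regions (DMRs).
4. **Annotation** — TSS (first position of the first exon, strand-aware),
   2-kb promoters, introns (gene minus exon) derived from a GFF3 gene
   model; DMRs classified intragenic/intergenic with per-feature counts.
5. **Robustness** — the cohort is split into 6 constrained groups; each
   leave-one-group-out subset of 35 samples reruns the whole analysis, and
   a DMR is kept ("selected") only if every member window is significant
   (p ≤ 0.05) with a coherent direction in every subset.
6. **Discriminative power** — random forests classify rank class from
   per-DMR CPM (plus age); out-of-bag error over repetitions, against
   matched-size random-location controls and a chance band.
7. **Concordance & mitochondria** — rank effects refitted separately per
   age class and correlated (empirical p from random window draws);
   mitochondrial vs. nuclear mean CPM compared per individual with exact
   Wilcoxon signed-rank tests, rank classes with rank-sum tests.

A first-class synthetic-data generator (`rankmeth.simulate`) produces
cohorts, genomes, methylation and expression count matrices with planted
DMRs and a machine-readable truth ledger, so every stage is exercised
against known ground truth. See `docs/methods.md` for the model details
and design choices.

## Worked example

The `analysis/` scripts run the whole study on synthetic data with planted
truth (60 DMRs of 1–5 windows at |log2 fold-change| 2, both directions, on
a 1.5-Mb nuclear contig plus a 17-kb mitochondrial contig at 8× abundance):

```bash
python analysis/01_simulate.py
python analysis/02_differential_methylation.py
python analysis/03_annotate_dmrs.py
python analysis/04_coherence_robustness.py
python analysis/05_discriminative_power.py
python analysis/06_concordance_mito.py
```

which prints (abridged):

```
cohort: 42 samples (18 high / 24 low)
windows: 5057 of 300 bp; planted DMRs: 60 covering 130 windows

windows tested: 5057 (of 5057 raw); common dispersion 0.200
significant windows at FDR <= 0.05: 138; merged into 68 DMRs
DMR lengths: 300-1500 bp; 38 hypermethylated in low-ranking, 30 hypomethylated

68 DMRs: 40 intragenic, 28 intergenic

6 groups of [7, 7, 7, 7, 7, 7] samples; subsets of [35, 35, 35, 35, 35, 35]
candidates: 68; selected: 68; excluded: 0

chance band (proportional guessing +/- 3 SE): [0.258, 0.721]
            selected: oob 0.0-0.0% (mean 0.0%) — below chance
    mean_methylation: oob 50.0-54.8% (mean 52.3%) — at chance
           control_1: oob 52.4-52.4% (mean 52.4%) — at chance

age-class concordance at 138 DMR windows: r = 0.96, empirical p = 0.000999
   dna_mito_vs_nuclear (signed_rank_paired): stat=171.0 Z=3.70 p=7.629e-06
   rna_mito_vs_nuclear (signed_rank_paired): stat=171.0 Z=3.70 p=7.629e-06
```

Reading this: the window test recovers essentially all 130 planted windows
at FDR ≤ 0.05 with a handful of false merges (68 called vs. 60 planted
DMRs); with effects this strong, every called DMR survives the six-subset
coherence filter; DMR features drive the classifier's oob error to ~0
while the mean-methylation covariate and random single windows sit at
chance; the planted effect is shared by cubs and adults (r = 0.96, at the
empirical-p floor for 1000 draws); and the 8× mitochondrial abundance is
detected in both the methylation and the expression data (all 18 paired
differences positive).

Each stage writes its tables (TSV/JSON/BED/GFF3) under `results/`.

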
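#!/usr/bin/env python
"""Stage 1 — generate the synthetic study dataset.

Builds a cohort shaped like the field study (42 females: 18 high-ranking,
24 low-ranking, split into cubs and adults), a small genome (one 1.5-Mb
nuclear contig plus a 17-kb mitochondrial contig with elevated capture
abundance), methylation-capture counts over 300-bp windows with 60 planted
rank-associated DMRs of 1-5 windows at |log2 fold-change| 2 in both
directions, and a matched expression matrix. Writes everything, plus the
truth ledger, under results/data/.
"""

import argparse
import os

import rankmeth as rm
from rankmeth.genome import write_gff3
from rankmeth.simulate import plant_random_dmrs

CONTIGS = [("chr1", 1_500_000, False), ("chrM", 17_000, True)]


def build_config(seed: int) -> rm.SimConfig:
    planted = plant_random_dmrs(CONTIGS, 300, 60, [1, 2, 1, 3, 1, 5],
                                log2_effect=2.0, seed=seed)
    return rm.SimConfig(seed=seed, contigs=CONTIGS, planted_dmrs=planted)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20240328)
    ap.add_argument("--out", default="results/data")
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    cfg = build_config(args.seed)
    samples = rm.simulate_cohort(cfg)
    genome = rm.simulate_gene_model(cfg, genes_per_contig=8)
    meth, truth = rm.simulate_methylation_counts(cfg, genome, samples)
    expr = rm.simulate_expression_counts(cfg, genome, samples)

    samples.to_csv(f"{args.out}/samples.tsv", sep="\t")
    meth.write_tsv(f"{args.out}/methylation_counts.tsv")
    expr.write_tsv(f"{args.out}/expression_counts.tsv")
    write_gff3(genome, f"{args.out}/genes.gff3")
    cfg.window_grid().to_bed(f"{args.out}/windows.bed")
    truth.write(f"{args.out}/truth.bed", f"{args.out}/truth.json")

    n_planted = (truth.window_effects != 0).sum()
    print(f"cohort: {len(samples)} samples "
          f"({(samples['rank_class'] == 'high').sum()} high / "
          f"{(samples['rank_class'] == 'low').sum()} low)")
    print(f"windows: {len(cfg.window_grid())} of {cfg.window_width} bp; "
          f"planted DMRs: {len(cfg.planted_dmrs)} covering {n_planted} windows")
    print(f"wrote {args.out}/")


if __name__ == "__main__":
    main()
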
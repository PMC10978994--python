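#!/usr/bin/env python
"""Stage 6 — age-class concordance and mitochondrial/nuclear contrasts.

Refits the rank effect separately in cubs and adults at the DMR windows,
correlates the two logFC vectors (empirical p from 1000 random equal-size
window draws), then compares mitochondrial against nuclear mean CPM per
individual for both the methylation and the expression data (paired
signed-rank) and high- against low-ranking overall abundance (rank-sum).
"""

import argparse
import importlib.util
import json
import os

import pandas as pd

import rankmeth as rm
from rankmeth.concordance import (ageclass_effects, effect_correlation_test,
                                  mito_nuclear_compare)
from rankmeth.genome import read_gff3

_spec = importlib.util.spec_from_file_location(
    "stage3", os.path.join(os.path.dirname(__file__), "03_annotate_dmrs.py"))
_stage3 = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_stage3)
load_dmrs = _stage3.load_dmrs


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--diffmeth", default="results/diffmeth")
    ap.add_argument("--out", default="results/concordance")
    ap.add_argument("--draws", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=5)
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    counts = rm.CountMatrix.read_tsv(f"{args.data}/methylation_counts.tsv")
    expr = rm.CountMatrix.read_tsv(f"{args.data}/expression_counts.tsv")
    samples = pd.read_csv(f"{args.data}/samples.tsv", sep="\t", index_col=0)
    genome = read_gff3(f"{args.data}/genes.gff3", mito_contigs={"chrM"})
    filtered = rm.filter_windows(counts)
    dmrs = load_dmrs(f"{args.diffmeth}/dmrs.tsv")
    candidate = sorted({w for d in dmrs for w in d.window_ids})

    effects = ageclass_effects(filtered, samples, list(filtered.window_ids))
    corr = effect_correlation_test(effects, candidate, n_draws=args.draws,
                                   seed=args.seed)
    effects.effects.loc[candidate].to_csv(
        f"{args.out}/ageclass_effects_dmr_windows.tsv", sep="\t")

    adults = samples[samples["age_class"] == "adult"]
    tests, table = mito_nuclear_compare(
        filtered.subset_samples(list(adults.index)),
        expr.subset_samples(list(adults.index)), genome, adults)
    table.to_csv(f"{args.out}/paired_abundance.tsv", sep="\t")
    with open(f"{args.out}/tests.json", "w") as fh:
        json.dump({"age_concordance": {
                       "pearson_r": corr.r, "n_windows": corr.n_windows,
                       "n_draws": corr.n_draws,
                       "empirical_p": corr.empirical_p},
                   "wilcoxon": [t.to_dict() for t in tests]}, fh, indent=2)

    print(f"age-class concordance at {corr.n_windows} DMR windows: "
          f"r = {corr.r:.2f}, empirical p = {corr.empirical_p:.4g} "
          f"({corr.n_draws} draws)")
    for t in tests:
        print(f"  {t.label:>20} ({t.test}): stat={t.statistic:.1f} "
              f"Z={t.z:.2f} p={t.p:.4g}")
    print(f"wrote {args.out}/")


if __name__ == "__main__":
    main()
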
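#!/usr/bin/env python
"""Stage 4 — subsample-coherence selection.

Partitions the cohort into 6 constrained groups, reruns the full window
analysis on each leave-one-group-out subset of 35 samples, and keeps only
DMRs whose member windows are significant (p <= 0.05) with one coherent
effect direction in every subset.
"""

import argparse
import importlib.util
import json
import os

import pandas as pd

import rankmeth as rm
from rankmeth.robustness import (coherence_select, make_subset_scheme,
                                 refit_subsets)

_spec = importlib.util.spec_from_file_location(
    "stage3", os.path.join(os.path.dirname(__file__), "03_annotate_dmrs.py"))
_stage3 = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_stage3)
load_dmrs = _stage3.load_dmrs


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--diffmeth", default="results/diffmeth")
    ap.add_argument("--out", default="results/robustness")
    ap.add_argument("--k", type=int, default=6)
    ap.add_argument("--seed", type=int, default=17)
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    counts = rm.CountMatrix.read_tsv(f"{args.data}/methylation_counts.tsv")
    samples = pd.read_csv(f"{args.data}/samples.tsv", sep="\t", index_col=0)
    filtered = rm.filter_windows(counts)
    tests = pd.read_csv(f"{args.diffmeth}/window_tests.tsv", sep="\t",
                        index_col=0)
    dmrs = load_dmrs(f"{args.diffmeth}/dmrs.tsv")

    scheme = make_subset_scheme(samples, k=args.k, seed=args.seed)
    cand_windows = sorted({w for d in dmrs for w in d.window_ids})
    stats = refit_subsets(filtered, samples, scheme, cand_windows)
    report = coherence_select(tests, stats, dmrs, seed=args.seed)

    scheme.to_frame().to_csv(f"{args.out}/subset_scheme.tsv", sep="\t")
    stats.table.to_csv(f"{args.out}/subset_stats.tsv", sep="\t", index=False)
    report.table.to_csv(f"{args.out}/coherence_report.tsv", sep="\t")
    with open(f"{args.out}/coherence_report.json", "w") as fh:
        json.dump({"alpha": report.alpha, "seed": args.seed,
                   "selected": report.selected,
                   "excluded": report.excluded}, fh, indent=2)

    print(f"{args.k} groups of "
          f"{sorted(len(g) for g in scheme.groups)} samples; subsets of "
          f"{sorted(len(s) for s in scheme.subsets)}")
    print(f"candidates: {len(dmrs)}; selected: {len(report.selected)}; "
          f"excluded: {len(report.excluded)}")
    for name in report.excluded:
        print(f"  excluded {name}: {report.table.loc[name, 'reasons']}")
    print(f"wrote {args.out}/")


if __name__ == "__main__":
    main()
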
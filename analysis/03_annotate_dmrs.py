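#!/usr/bin/env python
"""Stage 3 — functional annotation of the DMRs.

Derives TSS (first position of the first exon, strand-aware), 2-kb
promoters, and introns (gene minus exon) from the gene model, classifies
each DMR by the features it overlaps, and tabulates per-feature DMR counts
plus the intragenic/intergenic split.
"""

import argparse
import json
import os

import pandas as pd

from rankmeth.annotate import (annotate_dmrs, annotated_to_frame,
                               derive_features, summarize_overlaps)
from rankmeth.diffmeth import DMR
from rankmeth.genome import read_gff3


def load_dmrs(path: str) -> list[DMR]:
    df = pd.read_csv(path, sep="\t")
    return [DMR(r.contig, int(r.start), int(r.end),
                r.window_ids.split(","), r.direction,
                float(r.mean_logFC), float(r.min_q))
            for r in df.itertuples()]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--diffmeth", default="results/diffmeth")
    ap.add_argument("--out", default="results/annotation")
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    genome = read_gff3(f"{args.data}/genes.gff3", mito_contigs={"chrM"})
    dmrs = load_dmrs(f"{args.diffmeth}/dmrs.tsv")
    features = derive_features(genome)
    annotated = annotate_dmrs(dmrs, features)
    summary = summarize_overlaps(annotated)

    features.write_gff3(genome, f"{args.out}/features.gff3")
    annotated_to_frame(annotated).to_csv(f"{args.out}/annotated_dmrs.tsv",
                                         sep="\t", index=False)
    with open(f"{args.out}/overlap_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    n_intra = sum(a.locality == "intragenic" for a in annotated)
    print(f"{len(dmrs)} DMRs: {n_intra} intragenic, "
          f"{summary['intergenic']} intergenic")
    print("per-feature DMR counts:",
          {k: v for k, v in summary.items() if k != "intergenic"})
    print(f"wrote {args.out}/")


if __name__ == "__main__":
    main()
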
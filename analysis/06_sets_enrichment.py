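#!/usr/bin/env python
"""Cross-contrast overlap, consistent TNBC-specific sets, genomic-category
distribution, and host-gene over-representation.

Builds the probe x contrast membership table from the three subtype
contrasts, computes the Venn partition of hyper- and hypomethylated sets,
extracts probes consistently altered in TNBC against every luminal
comparison, tallies the genomic categories of significant probes, and runs
the hypergeometric over-representation test of significant host genes
against per-chromosome gene sets (stand-ins for pathway annotations).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from epicirc.differential import contrast
from epicirc.io import annotation_frame, read_annotation, read_channel_matrix, read_sample_sheet, write_result_table
from epicirc.quantify import quantify
from epicirc.sets import (
    category_distribution, consistent_specific_set, host_gene_query,
    hypergeometric_ora, membership_table, venn_counts, venn_table,
)

parser = argparse.ArgumentParser()
parser.add_argument("--indir", type=Path, default=Path("results/synthetic"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

ip = read_channel_matrix(args.indir / "raw_ip.tsv", "IP_Cy5")
sup = read_channel_matrix(args.indir / "raw_sup.tsv", "Sup_Cy3")
annotation = read_annotation(args.indir / "annotation.tsv")
samples = read_sample_sheet(args.indir / "samples.tsv")
spikes = [a.probe_id for a in annotation if a.is_spike_in]
quant = quantify(ip, sup, spikes)

pooled = samples.copy()
pooled["group"] = np.where(pooled["group"] == "TNBC", "TNBC", "Luminal")
contrasts = {
    "TNBC_vs_LuminalA": contrast(quant, samples, "TNBC", "LuminalA"),
    "TNBC_vs_LuminalB": contrast(quant, samples, "TNBC", "LuminalB"),
    "TNBC_vs_Luminal": contrast(quant, pooled, "TNBC", "Luminal"),
}
members = membership_table(contrasts)
names = list(contrasts)

venn_frames = []
for direction in ("hyper", "hypo"):
    counts = venn_counts(members, names, direction)
    venn_frames.append(venn_table(counts, direction))
    union = sum(counts.values())
    shared = counts[frozenset(names)]
    print(f"{direction}: union of {union} probes across 3 contrasts, "
          f"{shared} shared by all")
write_result_table(pd.concat(venn_frames, ignore_index=True),
                   args.outdir / "venn_regions.tsv", "sets")

ann = annotation_frame(annotation)
for direction in ("hyper", "hypo"):
    consistent = consistent_specific_set(members, names, direction)
    print(f"TNBC-specific consistently {direction}methylated: {len(consistent)} probes")
    (args.outdir / f"consistent_{direction}.txt").write_text(
        "\n".join(consistent) + ("\n" if consistent else "")
    )

cats = category_distribution(members, ann)
cats.to_csv(args.outdir / "category_distribution.tsv", sep="\t")
totals = cats.sum()
print("genomic categories of significant probes:",
      {k: int(v) for k, v in totals.items()})

retained = quant.retained[quant.retained].index
universe = host_gene_query(retained, ann)
gene_sets = {
    f"chrom:{c}": (f"host genes on {c}", set(sub["host_gene"]))
    for c, sub in ann[~ann["is_spike_in"]].groupby("chromosome")
}
sig = members.index[members.isin(["hyper", "hypo"]).any(axis=1)]
query = host_gene_query(sig, ann)
ora = hypergeometric_ora(query, gene_sets, universe)
write_result_table(ora, args.outdir / "enrichment.tsv", "enrichment")
print(f"over-representation: {len(query)} significant host genes against "
      f"{len(gene_sets)} gene sets; {int(ora['significant'].sum())} terms at q<0.05")
print(f"tables written to {args.outdir}/")
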
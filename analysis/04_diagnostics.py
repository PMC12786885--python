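#!/usr/bin/env python
"""Study-level inference diagnostics for the TNBC vs pooled-luminal contrast.

Permutation test on the significant-feature count (1000 label shuffles),
KS uniformity of the raw p-value distribution, and the post hoc power
translation: the minimum detectable Cohen's d at 80% power converted to a
log2 fold change through the median per-probe pooled SD.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from epicirc.diagnostics import diagnose
from epicirc.differential import contrast
from epicirc.io import read_annotation, read_channel_matrix, read_sample_sheet
from epicirc.quantify import quantify

parser = argparse.ArgumentParser()
parser.add_argument("--indir", type=Path, default=Path("results/synthetic"))
parser.add_argument("--out", type=Path, default=Path("results/diagnostics.json"))
parser.add_argument("--B", type=int, default=1000)
parser.add_argument("--seed", type=int, default=17)
args = parser.parse_args()

ip = read_channel_matrix(args.indir / "raw_ip.tsv", "IP_Cy5")
sup = read_channel_matrix(args.indir / "raw_sup.tsv", "Sup_Cy3")
annotation = read_annotation(args.indir / "annotation.tsv")
samples = read_sample_sheet(args.indir / "samples.tsv")
spikes = [a.probe_id for a in annotation if a.is_spike_in]
quant = quantify(ip, sup, spikes)

pooled = samples.copy()
pooled["group"] = np.where(pooled["group"] == "TNBC", "TNBC", "Luminal")
res = contrast(quant, pooled, "TNBC", "Luminal")

report, perm = diagnose(
    quant, pooled, "TNBC", "Luminal", res["p"].values,
    B=args.B, seed=args.seed,
)
payload = report.as_dict()
payload["null_count_histogram"] = {
    str(k): int(v) for k, v in
    zip(*np.unique(perm.null_counts, return_counts=True))
}
args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(json.dumps(payload, indent=2) + "\n")

print(f"observed significant features: {report.observed_sig_count}; "
      f"permutation p = {report.empirical_p:.3f} (B={report.permutation_iterations})")
print(f"p-value uniformity: KS D = {report.ks_D:.3f}, p = {report.ks_p:.2e} "
      "(left-tail enrichment indicates true signal)")
print(f"minimum detectable effect at 80% power: d = {report.cohens_d:.2f}, "
      f"log2FC = {report.mde_log2fc:.2f} (pooled SD {report.sd_pooled:.2f})")
print(f"report written to {args.out}")
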
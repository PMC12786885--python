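# epicirc

Analysis pipeline for **MeRIP epitranscriptomic microarrays** profiling
N6-methyladenosine (m⁶A) on circular RNAs across breast-cancer subtypes
(TNBC vs Luminal A/B). It takes raw two-channel probe intensities — the
immunoprecipitated (IP, Cy5) and supernatant (Sup, Cy3) fractions of each
sample — through:

1. **Spike-in normalization & quantification** — per array and channel,
   `norm = log2(raw) − mean(log2 spike-in raw)`; the *m⁶A quantity* of a
   probe is its normalized IP intensity, and the modification
   stoichiometry is `%Modified = IP/(IP+Sup)`. Probes need Present/Marginal
   QC flags in ≥ 4 samples to be retained.
2. **Differential methylation** — per-probe unpaired t-tests on the m⁶A
   quantity, `log2FC = mean_A − mean_B`, `FC = 2^log2FC`, BH q-values, and
   hyper/hypo calls under the joint rule |FC| ≥ 2 and raw p < 0.05.
3. **Inference diagnostics** — a label-permutation test on the count of
   significant probes (empirical p = #{perm count ≥ observed}/B),
   Kolmogorov–Smirnov uniformity of the p-value distribution, and the post
   hoc power translation: the smallest Cohen's *d* with 80% power under the
   noncentral-t power function, converted to a minimum detectable log2FC
   via the pooled SD (MDE = d·s_p).
4. **ROC biomarker ranking** — per-probe Mann–Whitney AUC (ties count ½)
   with full threshold curves for the top-20 hyper/hypo probes.
5. **Set logic & enrichment** — Venn partitions of significant sets across
   contrasts, "TNBC-specific consistent" sets (same call in every
   comparison), genomic-category tallies (exonic/intronic/sense-overlapping/
   antisense/intergenic), and hypergeometric over-representation of host
   genes against GMT gene sets.
6. **Survival** — median-split of a marker, Kaplan–Meier curves, log-rank
   test, and univariate Cox HR (Efron ties) with a Wald 95% CI.

Because the patient cohort behind such studies is typically private, the
package ships a first-class **synthetic-data generator**
(`epicirc.simulate`) reproducing the assumed statistical structure: 27
arrays in 3 groups of 9, log-normal intensities, a shared spike-in block,
per-array scale effects, a configurable fraction of truly modified probes
(log2 effects ≈ 1.77, noise SD 1 on the log2 scale), and QC flags. Every
stage is tested against it and against independent small-n oracles.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data and write tables under `results/`:

```sh
python analysis/01_simulate_study.py --seed 17
python analysis/02_quantify.py
python analysis/03_differential.py
python analysis/04_diagnostics.py
python analysis/05_roc.py
python analysis/06_sets_enrichment.py
python analysis/07_survival.py
```

Output from that exact run:

```text
simulated 2020 probes (20 spike-ins) x 27 samples in groups {'TNBC': 9, 'LuminalA': 9, 'LuminalB': 9}
100 probes carry a true TNBC effect (median |log2FC| 1.72)
...
TNBC_vs_Luminal: 56 hyper, 67 hypo of 2000 tested (q<0.05: 83); strongest FC 7.69
...
observed significant features: 123; permutation p = 0.000 (B=1000)
p-value uniformity: KS D = 0.049, p = 1.52e-04 (left-tail enrichment indicates true signal)
minimum detectable effect at 80% power: d = 1.19, log2FC = 1.17 (pooled SD 0.99)
...
best discriminator: circ_00807 (AUC = 1.000, b_high)
AUC > 0.8 for 40/40 probes; median AUC 0.966
...
TNBC-specific consistently hypermethylated: 43 probes
genomic categories of significant probes: {'exonic': 245, 'intronic': 89, ...}
...
log-rank chi2 = 52.46, p = 4.39e-13
Cox HR (high vs low) = 2.65 (95% CI 2.02-3.48, p = 2.48e-12)
```

Reading: of 2000 probes, 123 clear the joint |FC|/p gate in the pooled
contrast — far more than any of 1000 label permutations produce (empirical
p < 0.001), and the p-value histogram's left tail departs from uniformity
(KS). The 9-vs-18 design can detect a standardized effect d ≈ 1.2 at 80%
power, i.e. a log2FC ≈ 1.2 at the observed pooled SD — only large effects
are reliably detectable, matching the generator's effect regime. The top
fold-change probes are near-perfect subtype discriminators (AUC up to
1.0), and the simulated prognostic marker (true HR 2.4) is recovered with
a CI covering the truth.

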
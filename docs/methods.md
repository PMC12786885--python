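# Methods

## Measurement model

Each sample contributes two arrays' worth of probe intensities: the
m⁶A-immunoprecipitated RNA fraction (IP, Cy5-labeled) and the unbound
supernatant (Sup, Cy3-labeled). Raw fluorescence is assumed log-normal;
all analysis happens on the log2 scale. Exogenous spike-in RNAs of fixed
input amount anchor each array: for channel c and sample s,

    norm_c[p, s] = log2(raw_c[p, s]) − mean over spike-ins i of log2(raw_c[i, s])

The spike-in average is the arithmetic mean of log2 values (equivalently
the log2 geometric mean), computed **per array and per channel** — the only
reading that makes the subtraction well defined sample by sample.
Normalization is a pure location shift per array: probe-to-probe
differences within an array are untouched, and rescaling an entire array
(spike-ins included) cancels exactly.

The **m⁶A quantity** of a probe is its normalized IP intensity. The
stoichiometry **%Modified = IP/(IP+Sup)** is computed directly on the
normalized log2 intensities — the form the quantification defines — with a
`percent_modified_scale: linear` switch for the plausible alternative
2^ip/(2^ip+2^sup). Because normalized log2 values can be negative (probe
dimmer than the spike-in geometric mean), the default ratio can leave
[0, 1]; such cells are clamped and carry an `out_of_range` flag rather than
being silently altered or dropped. A zero denominator yields NA. On
synthetic data at default settings roughly a quarter of cells are flagged;
this is a property of the printed formula, not of the implementation, and
the linear variant never flags.

**QC retention**: a probe is kept when it has a Present or Marginal flag in
at least `min_pm = 4` samples, counted over *all* samples (one global rule,
not per group), applied after normalization and before any contrast.
Non-positive raw intensities are an error by default (they indicate a
corrupt export); `floor_epsilon` opts into clamping.

## Differential methylation

For groups A and B, per retained probe: `log2FC = mean_A − mean_B` of the
m⁶A quantity, `FC = 2^log2FC`, and a two-sided unpaired t-test. The default
is the classical pooled-variance Student's t (what array pipelines mean by
"unpaired t-test"); Welch is a switch. Benjamini–Hochberg q-values are
computed across all tested probes of the contrast, with NA p-values
excluded from m and propagated.

Significance is the joint rule **|FC| ≥ 2 and raw p < 0.05**, symmetric on
the linear scale (fc ≥ 2 or fc ≤ ½). Raw p is the default gate because
small designs rarely clear FDR < 0.05 — the q column is always emitted and
`use_q` switches the gate. Degenerate probes: zero variance in both groups
with equal means gives p = 1; zero variance with unequal means gives NA
with a `zero_variance` flag (an infinite t statistic is not evidence, it is
noiseless data). Top-k ranking is by fold change (largest FC among hyper,
smallest among hypo), ties broken by ascending p then probe id, making
every ordering deterministic.

## Inference diagnostics

*Permutation test.* The study-level statistic is the **count** of probes
passing the joint gate. Group labels are permuted preserving group sizes
(uniform over assignments, sampled with replacement; small designs can
enumerate all distinct assignments exhaustively), the entire
contrast-and-classify pipeline is rerun per permutation, and the empirical
p is the plain proportion of permutations whose count reaches the observed
one. The (1+#)/(1+B) estimator is available via `plus_one`; the plain
proportion is the default because it is the conventional report at
B = 1000.

*KS uniformity.* One-sample two-sided Kolmogorov–Smirnov test of the raw
p-values against Uniform(0,1) (scipy's exact/asymptotic selection).
Left-tail enrichment — D large with small KS p — is the signature of true
signal mixed into the null.

*Power translation.* The power of the two-sided two-sample t-test at
standardized effect d uses the noncentral-t distribution with
ncp = d·√(n₁n₂/(n₁+n₂)). The minimum detectable effect solves power(d) =
0.80 at α = 0.05 by bisection to |Δpower| < 10⁻⁶, and the identity
MDE_log2FC = d·s_p converts it through the pooled SD. The study-level s_p
is the **median across retained probes of the per-probe pooled SD** —
robust, and one concrete choice among the unspecified aggregations. At the
9-vs-9 design point with s_p ≈ 1 this gives d ≈ 1.41 and MDE ≈ 1.4–1.5
log2 units: the design detects only large effects, which is exactly the
regime the |FC| ≥ 2 gate targets.

## ROC

AUC is the normalized Mann–Whitney U computed from midranks (ties
contribute ½); the curve enumerates all thresholds and its trapezoidal
area equals the U-statistic AUC identically. The default score is the m⁶A
quantity (the variable the contrasts test); %Modified is selectable. The
default `auto` direction policy reports the orientation with AUC ≥ 0.5
together with which group scores higher; `fixed` keeps group A positive so
that AUC(scores) + AUC(−scores) = 1. No confidence intervals are computed.

## Set logic and enrichment

Membership tables map every probe to its call per contrast (`untested`
where absent). Venn regions are the full inclusion–exclusion partition
(2–4 contrasts); regions sum to the union by construction and by test. A
"consistent subtype-specific set" is the intersection of same-direction
calls across the listed contrasts. Category tallies count the five genomic
classes per contrast and direction over significant probes only.

Enrichment is the standard hypergeometric over-representation test:
p = P(X ≥ k) for X ~ Hypergeom(N, K, n), with each gene set intersected
with the universe first, k = 0 giving p = 1, and BH across terms at
q < 0.05. Gene sets come from GMT files; pathway databases are deliberately
not bundled — exported term lists are supplied by the user. A circRNA
contributes its host gene once (deduplicated); the default universe is the
deduplicated host genes of all retained probes. miRNA-interaction
annotations, when present, are a passive join, never computed.

## Survival

Subjects split at the marker median; values strictly above go `high`, ties
at the median go `low` (deterministic and documented). Kaplan–Meier is the
product-limit estimator; the log-rank test is the standard (O−E)²/V
chi-square with 1 df; the univariate Cox fit on the high/low indicator
uses Efron tie handling with convergence precision 10⁻⁹ on the
coefficient, HR = exp(β) for high vs low, and Wald 95% CI. Monotone
partial likelihood (all events on one side) is flagged `separation` with
an unbounded CI instead of a spurious finite interval. Estimation is
delegated to lifelines; the conventions and the oracle tests (closed-form
toy tables, brute-force partial-likelihood maximization) are this
package's.

## Synthetic data generator

The generator defines the study conditions every test runs under:

| parameter | default | meaning |
|---|---|---|
| `group_sizes` | 9/9/9 (TNBC, Luminal A, Luminal B) | 27 arrays, the study scale |
| `n_probes` / `n_spike` | 2000 / 20 | probe panel and spike-in block |
| `frac_dm` | 0.05 | fraction of truly modified probes |
| `effect_mean`, `effect_sd` | 1.77, 0.25 | log2 effect magnitude in the target group, random sign |
| `noise_sd` | 1.0 | per-probe log2-scale SD |
| `flag_absent_rate` | 0.05 | per-cell probability of an Absent QC flag |

Baselines are N(10, 1.5) on log2; the Sup channel gets a smooth per-probe
offset so the true stoichiometry varies; every array receives a
multiplicative scale factor applied to all probes including spike-ins
(removed exactly by normalization); spike-ins have fixed input amounts
with small technical noise. Genomic categories are drawn with
exonic-majority weights 0.6/0.2/0.1/0.05/0.05. Raw intensities are
2^(log2 value), so they are strictly positive. `noise_sd = 1` is a
convention consistent with the d ≈ 1.45 ↔ log2FC ≈ 1.5 power relation at
this design, not an estimate from real data. One integer seed drives
independent sub-streams for probe-level truth, sample effects, noise and
flags, so enlarging the probe panel does not perturb sample-level draws.

The survival generator draws exponential event times with the hazard
multiplied by `true_hr` for subjects above the latent-marker median, and
independent Uniform(0, u) censoring with u solved (Brent) so the expected
censored fraction matches `censor_rate`. Defaults n = 300, HR = 2.4, 20%
censoring — the scale of strong prognostic effects.

What the generator does **not** emulate: dye bias, spatial artifacts,
probe cross-hybridization, correlated probes, heavy-tailed noise, and
cohort-specific censoring patterns. Passing tests therefore demonstrate
correctness of the statistics under the assumed model, not robustness to
real-array pathologies.

## Numerical conventions

- Tables are TSV (CSV by extension), `NA` is the sole missing token,
  floats serialize to 6 significant digits, column orders are fixed per
  schema.
- Unparseable QC flags degrade to Absent with a logged warning; missing
  flag columns degrade to all-Present with a warning (permissive mode for
  synthetic exports).
- BED export of probe loci is 0-based half-open, score = round(100·log2FC).
- All stochastic operations take explicit integer seeds and record them in
  their reports.

## Known limitations

- The joint |FC| ≥ 2 & p < 0.05 gate has a null acceptance rate of ≈ 2.7%
  at the 9-vs-9, SD-1 design point (the two gates are strongly positively
  dependent), not the product of the marginal rates; interpret significant
  *counts* through the permutation test, not against 0.05×FC-rate
  expectations.
- %Modified on the log2 scale is clamped outside [0, 1] for dim probes;
  use the linear variant when stoichiometry per se is the question.
- No between-array quantile/loess normalization, no moderated-variance
  (empirical Bayes) testing, no multivariate Cox — each is out of scope by
  design.

## Analysis problem sizes

The shipped drivers and acceptance script use 2000-probe panels, 27-sample
designs, B = 1000 permutations, and 40–200 simulation replicates for
calibration/recovery summaries — sizes chosen so the full analysis
reruns in about a minute while keeping Monte-Carlo error well inside the
tolerances the tests assert.
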
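"""Study-level inference diagnostics: permutation significance, p-value
uniformity, and the power / minimum-detectable-effect translation.

The permutation test asks whether the *count* of probes passing the joint
|FC|/p gate exceeds what label shuffling alone produces: group labels are
permuted preserving group sizes, the full contrast+classification pipeline
is rerun per permutation, and the empirical p is the proportion of
permutations whose significant count reaches the observed one.

The KS diagnostic measures departure of the raw p-value distribution from
Uniform(0,1) (left-tail enrichment indicates true signal).  The minimum
detectable effect solves the noncentral-t power function of the two-sided
two-sample t-test for the smallest standardized effect (Cohen's d)
attaining a requested power, and converts it to a log2 fold change through
the pooled SD (MDE = d * sd_pooled).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import classify, group_columns, ttest_rows
from .quantify import QuantificationResult


class DiagnosticsError(ValueError):
    pass


@dataclass
class PermutationResult:
    observed_sig_count: int
    empirical_p: float
    null_counts: np.ndarray
    iterations: int
    seed: int | None

    def as_dict(self) -> dict:
        d = asdict(self)
        d["null_counts"] = [int(c) for c in self.null_counts]
        return d


@dataclass
class DiagnosticsReport:
    contrast: str
    observed_sig_count: int
    permutation_iterations: int
    empirical_p: float
    ks_D: float
    ks_p: float
    cohens_d: float
    mde_log2fc: float
    power: float
    alpha: float
    sd_pooled: float
    seed: int | None

    def as_dict(self) -> dict:
        return asdict(self)


def _sig_count(
    pooled: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
    fc_threshold: float, p_threshold: float, test_variant: str,
) -> int:
    a, b = pooled[:, idx_a], pooled[:, idx_b]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    p, _ = ttest_rows(a, b, variant=test_variant)
    call = classify(np.exp2(log2fc), p, fc_threshold, p_threshold)
    return int((call != "ns").sum())


def permutation_test(
    quant: QuantificationResult,
    samples: pd.DataFrame,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    test_variant: str = "student",
    B: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
    plus_one: bool = False,
) -> PermutationResult:
    """Label-permutation test on the significant-feature count.

    ``exhaustive=True`` enumerates every distinct assignment of the pooled
    samples into groups of the observed sizes (feasible for tiny designs)
    instead of sampling ``B`` permutations with replacement.  ``plus_one``
    switches the plain proportion #{count_b >= observed}/B to the
    never-zero estimator (1 + #)/(1 + B).
    """
    if B < 1:
        raise DiagnosticsError("B must be >= 1")
    cols_a = group_columns(samples, group_a)
    cols_b = group_columns(samples, group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise DiagnosticsError("both groups need >= 2 samples")
    m6a = quant.m6a_quantity.loc[quant.retained]
    pooled = m6a[cols_a + cols_b].to_numpy(float)
    n_a, n = len(cols_a), len(cols_a) + len(cols_b)

    observed = _sig_count(
        pooled, np.arange(n_a), np.arange(n_a, n),
        fc_threshold, p_threshold, test_variant,
    )
    if exhaustive:
        counts = []
        for combo in combinations(range(n), n_a):
            idx_a = np.array(combo)
            idx_b = np.array([i for i in range(n) if i not in combo])
            counts.append(_sig_count(
                pooled, idx_a, idx_b, fc_threshold, p_threshold, test_variant
            ))
        null_counts = np.array(counts)
    else:
        rng = np.random.default_rng(seed)
        counts = np.empty(B, dtype=int)
        for b in range(B):
            perm = rng.permutation(n)
            counts[b] = _sig_count(
                pooled, perm[:n_a], perm[n_a:],
                fc_threshold, p_threshold, test_variant,
            )
        null_counts = counts
    hits = int((null_counts >= observed).sum())
    if plus_one:
        empirical_p = (1 + hits) / (1 + len(null_counts))
    else:
        empirical_p = hits / len(null_counts)
    return PermutationResult(
        observed_sig_count=observed,
        empirical_p=float(empirical_p),
        null_counts=null_counts,
        iterations=len(null_counts),
        seed=seed,
    )


def ks_uniformity(pvalues) -> tuple[float, float]:
    """One-sample two-sided KS test of the p-values against Uniform(0,1)."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise DiagnosticsError("no p-values to test")
    res = stats.kstest(p, "uniform")
    return float(res.statistic), float(res.pvalue)


def power_two_sample_t(
    d, n1: int, n2: int, alpha: float = 0.05
) -> np.ndarray:
    """Power of the two-sided two-sample t-test at standardized effect d.

    Uses the noncentral-t distribution with ncp = d * sqrt(n1*n2/(n1+n2))
    and df = n1 + n2 - 2.
    """
    d = np.asarray(d, dtype=float)
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)


def minimum_detectable_effect(
    n1: int, n2: int, sd_pooled: float,
    power: float = 0.80, alpha: float = 0.05,
) -> tuple[float, float]:
    """Smallest Cohen's d detectable at the given power, and its log2FC.

    Solves power(d) = power by bisection to |delta power| < 1e-6;
    mde_log2fc = d * sd_pooled exactly.
    """
    if n1 < 2 or n2 < 2:
        raise DiagnosticsError("need n >= 2 per group")
    if sd_pooled <= 0:
        raise DiagnosticsError("sd_pooled must be > 0")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise DiagnosticsError("power and alpha must lie in (0, 1)")
    lo, hi = 0.0, 1.0
    while power_two_sample_t(hi, n1, n2, alpha) < power:
        hi *= 2.0
        if hi > 1e4:
            raise DiagnosticsError("requested power unattainable at these n")
    d = hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        pw = float(power_two_sample_t(mid, n1, n2, alpha))
        if abs(pw - power) < 1e-6:
            d = mid
            break
        if pw < power:
            lo = mid
        else:
            hi = mid
        d = mid
    return float(d), float(d * sd_pooled)


def pooled_sd_summary(
    quant: QuantificationResult,
    samples: pd.DataFrame,
    group_a: str,
    group_b: str,
) -> float:
    """Median across retained probes of the per-probe pooled SD (log2 scale)."""
    cols_a = group_columns(samples, group_a)
    cols_b = group_columns(samples, group_b)
    m6a = quant.m6a_quantity.loc[quant.retained]
    a = m6a[cols_a].to_numpy(float)
    b = m6a[cols_b].to_numpy(float)
    n1, n2 = a.shape[1], b.shape[1]
    sp2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / (n1 + n2 - 2)
    return float(np.median(np.sqrt(sp2)))


def diagnose(
    quant: QuantificationResult,
    samples: pd.DataFrame,
    group_a: str,
    group_b: str,
    contrast_pvalues,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    test_variant: str = "student",
    B: int = 1000,
    seed: int | None = None,
    power: float = 0.80,
    alpha: float = 0.05,
) -> tuple[DiagnosticsReport, PermutationResult]:
    """Full diagnostics stage for one contrast."""
    perm = permutation_test(
        quant, samples, group_a, group_b,
        fc_threshold=fc_threshold, p_threshold=p_threshold,
        test_variant=test_variant, B=B, seed=seed,
    )
    ks_D, ks_p = ks_uniformity(contrast_pvalues)
    sd_pooled = pooled_sd_summary(quant, samples, group_a, group_b)
    n1 = len(group_columns(samples, group_a))
    n2 = len(group_columns(samples, group_b))
    d, mde = minimum_detectable_effect(n1, n2, sd_pooled, power=power, alpha=alpha)
    report = DiagnosticsReport(
        contrast=f"{group_a}:{group_b}",
        observed_sig_count=perm.observed_sig_count,
        permutation_iterations=perm.iterations,
        empirical_p=perm.empirical_p,
        ks_D=ks_D,
        ks_p=ks_p,
        cohens_d=d,
        mde_log2fc=mde,
        power=power,
        alpha=alpha,
        sd_pooled=sd_pooled,
        seed=seed,
    )
    return report, perm
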
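"""Group contrasts on the m6A quantity: fold change, t-test, BH, top-k.

A contrast compares two sample groups probe by probe on the normalized log2
IP intensity.  log2FC is the difference of group means (group A minus
group B), FC = 2^log2FC, and the p-value comes from a two-sided unpaired
t-test (pooled-variance Student's t by default, Welch selectable).
Benjamini-Hochberg q-values are computed across all tested probes; the
significance call uses the joint rule |FC| >= fc_threshold and raw
p < p_threshold (the q-value can replace p via ``use_q``), with hyper- and
hypomethylation meaning higher/lower m6A signal in group A.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import QuantificationResult

TEST_VARIANTS = ("student", "welch")
CALLS = ("hyper", "hypo", "ns")


class ContrastError(ValueError):
    pass


def group_columns(samples: pd.DataFrame, group: str) -> list[str]:
    cols = samples.loc[samples["group"] == group, "sample_id"].tolist()
    if not cols:
        raise ContrastError(f"no samples in group {group!r}")
    return cols


def ttest_rows(
    a: np.ndarray, b: np.ndarray, variant: str = "student"
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided unpaired t-test; returns (p, zero_variance mask).

    Degenerate rows: zero variance in both groups with equal means -> p = 1;
    zero variance with unequal means -> p = NaN (flagged), avoiding the
    infinite-t reading of noiseless data.
    """
    if variant not in TEST_VARIANTS:
        raise ContrastError(f"unknown test variant {variant!r}")
    if a.shape[0] != b.shape[0]:
        raise ContrastError("row mismatch between groups")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ContrastError("each group needs >= 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=(variant == "student"))
        p = np.asarray(res.pvalue, dtype=float)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    zero_var = (var_a == 0) & (var_b == 0)
    diff = a.mean(axis=1) - b.mean(axis=1)
    p = np.where(zero_var & (diff == 0), 1.0, p)
    p = np.where(zero_var & (diff != 0), np.nan, p)
    return p, zero_var


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input.

    NA entries are excluded from the adjustment (they do not count toward m)
    and propagate as NA.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ContrastError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if finite.sum():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def classify(
    fc, p, fc_threshold: float = 2.0, p_threshold: float = 0.05
) -> np.ndarray:
    """Direction call: hyper iff fc >= T and p < alpha; hypo iff fc <= 1/T
    and p < alpha; otherwise ns.  ``|FC| >= T`` is symmetric on the linear
    scale.  NA p-values never earn a call."""
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ContrastError("thresholds must be > 0")
    fc = np.atleast_1d(np.asarray(fc, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    sig = ~np.isnan(p) & (p < p_threshold)
    call = np.where(
        sig & (fc >= fc_threshold), "hyper",
        np.where(sig & (fc <= 1.0 / fc_threshold), "hypo", "ns"),
    )
    return call


def contrast(
    quant: QuantificationResult,
    samples: pd.DataFrame,
    group_a: str,
    group_b: str,
    test_variant: str = "student",
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    use_q: bool = False,
) -> pd.DataFrame:
    """One group contrast over all retained probes.

    Returns a ``contrast``-schema DataFrame with one row per retained probe.
    """
    cols_a = group_columns(samples, group_a)
    cols_b = group_columns(samples, group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ContrastError("both groups need >= 2 samples")
    m6a = quant.m6a_quantity.loc[quant.retained]
    a = m6a[cols_a].to_numpy(float)
    b = m6a[cols_b].to_numpy(float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = mean_a - mean_b
    fc = np.exp2(log2fc)
    p, zero_var = ttest_rows(a, b, variant=test_variant)
    q = bh_adjust(p)
    call = classify(fc, q if use_q else p, fc_threshold, p_threshold)
    return pd.DataFrame({
        "probe_id": m6a.index,
        "group_a": group_a,
        "group_b": group_b,
        "n_a": len(cols_a),
        "n_b": len(cols_b),
        "mean_a": mean_a,
        "mean_b": mean_b,
        "log2fc": log2fc,
        "fc": fc,
        "p": p,
        "q": q,
        "call": call,
        "zero_variance": zero_var,
    }).reset_index(drop=True)


def top_k(results: pd.DataFrame, k: int = 20) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k hyper- and hypomethylated probes ranked by fold change.

    Hyper: k largest fc, descending; hypo: k smallest fc, ascending.  Ties
    break by ascending p, then lexicographic probe_id.  Fewer than k
    significant probes simply returns them all.
    """
    hyper = results[results["call"] == "hyper"].sort_values(
        ["fc", "p", "probe_id"], ascending=[False, True, True]
    )
    hypo = results[results["call"] == "hypo"].sort_values(
        ["fc", "p", "probe_id"], ascending=[True, True, True]
    )
    return hyper.head(k).reset_index(drop=True), hypo.head(k).reset_index(drop=True)
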
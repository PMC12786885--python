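"""Per-probe ROC curves and AUC for two-group discrimination.

The AUC is the normalized Mann-Whitney U statistic: the probability that a
random sample from the positive class outscores a random sample from the
negative class, with ties contributing one half.  The curve enumerates all
score thresholds.  Under the default ``auto`` direction policy the
orientation maximizing the AUC is reported together with which group scores
higher; ``fixed`` always treats group A as positive (useful for
antisymmetry checks: AUC(scores) + AUC(-scores) = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .differential import group_columns
from .quantify import QuantificationResult

DIRECTION_POLICIES = ("auto", "fixed")
SCORE_FIELDS = ("m6a_quantity", "percent_modified")


class RocError(ValueError):
    pass


@dataclass
class RocResult:
    probe_id: str | None
    auc: float
    direction: str            # "a_high" | "b_high": which class scores higher
    curve: np.ndarray         # (n_points, 2) columns FPR, TPR; (0,0) .. (1,1)
    n_pos: int
    n_neg: int


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via midranks: (sum of positive ranks - n_pos(n_pos+1)/2) / (n_pos*n_neg)."""
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_auc(
    scores, labels, direction_policy: str = "auto", probe_id: str | None = None
) -> RocResult:
    """ROC curve and AUC for one score vector.

    ``labels`` marks membership of the positive class (group A); both
    classes must be non-empty and the scores finite.
    """
    if direction_policy not in DIRECTION_POLICIES:
        raise RocError(f"unknown direction policy {direction_policy!r}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise RocError("scores and labels must align")
    if not np.isfinite(scores).all():
        raise RocError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise RocError("both classes must be non-empty")

    auc = _auc_rank(scores, labels)
    direction = "a_high" if auc >= 0.5 else "b_high"
    oriented = scores
    if direction_policy == "auto" and auc < 0.5:
        oriented = -scores
        auc = 1.0 - auc
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), oriented, drop_intermediate=False)
    curve = np.column_stack([fpr, tpr])
    return RocResult(
        probe_id=probe_id, auc=float(auc), direction=direction,
        curve=curve, n_pos=n_pos, n_neg=n_neg,
    )


def rank_biomarkers(
    quant: QuantificationResult,
    samples: pd.DataFrame,
    group_a: str,
    group_b: str,
    probes,
    score_field: str = "m6a_quantity",
    direction_policy: str = "auto",
) -> tuple[pd.DataFrame, dict[str, RocResult]]:
    """One ROC per probe of a subset, sorted by AUC descending.

    Group A is the positive class.  Ties in AUC break by probe_id, making
    the ordering deterministic.  Returns the ``roc``-schema table plus the
    full per-probe results (with curves).
    """
    if score_field not in SCORE_FIELDS:
        raise RocError(f"unknown score field {score_field!r}")
    probes = list(probes)
    if not probes:
        raise RocError("empty probe subset")
    values = getattr(quant, score_field)
    missing = [p for p in probes if p not in values.index]
    if missing:
        raise RocError(f"probes absent from quantification: {missing}")
    cols_a = group_columns(samples, group_a)
    cols_b = group_columns(samples, group_b)
    cols = cols_a + cols_b
    labels = np.array([True] * len(cols_a) + [False] * len(cols_b))
    results: dict[str, RocResult] = {}
    for p in probes:
        scores = values.loc[p, cols].to_numpy(float)
        results[p] = roc_auc(scores, labels, direction_policy=direction_policy, probe_id=p)
    table = pd.DataFrame({
        "probe_id": probes,
        "auc": [results[p].auc for p in probes],
        "direction": [results[p].direction for p in probes],
        "n_pos": [results[p].n_pos for p in probes],
        "n_neg": [results[p].n_neg for p in probes],
    }).sort_values(["auc", "probe_id"], ascending=[False, True]).reset_index(drop=True)
    return table, results
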
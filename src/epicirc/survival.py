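"""Median-split survival statistics: Kaplan-Meier, log-rank, univariate Cox.

A cohort table has one row per subject with a follow-up time in days, an
event indicator (1 = dead/relapsed, 0 = censored) and a continuous marker
(expression) value.  Subjects are split at the marker median (strictly
above the median -> ``high``; at or below -> ``low``, so median ties land
in ``low`` deterministically).  The Kaplan-Meier product-limit estimator,
the two-group log-rank test and a univariate Cox proportional-hazards fit
(Efron tie handling) on the high/low indicator summarize the split; the
hazard ratio is high vs low with a Wald 95% CI.

Estimation is delegated to lifelines; this module fixes the conventions
(split rule, HR orientation, separation handling) and the result schema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats


class SurvivalError(ValueError):
    pass


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float
    separation: bool = False   # monotone likelihood; CI unbounded

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SurvivalFit:
    marker: str
    n_high: int
    n_low: int
    km_high: pd.Series
    km_low: pd.Series
    logrank_chi2: float
    logrank_p: float
    cox: CoxResult

    def to_row(self) -> dict:
        return {
            "marker": self.marker, "n_high": self.n_high, "n_low": self.n_low,
            "logrank_chi2": self.logrank_chi2, "logrank_p": self.logrank_p,
            "hr": self.cox.hr, "ci_low": self.cox.ci_low,
            "ci_high": self.cox.ci_high, "cox_p": self.cox.p,
        }


def _check_records(records: pd.DataFrame) -> None:
    required = {"time", "event"}
    if not required <= set(records.columns):
        raise SurvivalError("records need columns time, event")
    if (records["time"] <= 0).any():
        raise SurvivalError("times must be > 0")
    if not records["event"].isin([0, 1]).all():
        raise SurvivalError("event indicator must be 0/1")


def median_split(records: pd.DataFrame, value_col: str = "expression") -> pd.DataFrame:
    """Assign high/low groups at the marker median (ties at the median -> low)."""
    if len(records) < 4:
        raise SurvivalError("need >= 4 records for a median split")
    x = records[value_col].to_numpy(float)
    if np.unique(x).size == 1:
        raise SurvivalError("all marker values identical; no split possible")
    med = float(np.median(x))
    out = records.copy()
    out["group"] = np.where(x > med, "high", "low")
    return out


def km_estimate(records: pd.DataFrame) -> pd.Series:
    """Product-limit survival estimate for one group.

    Returns a step function as a Series survival-probability indexed by
    time, starting at S(0) = 1; censored subjects shrink the risk set
    without creating steps.
    """
    _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], event_observed=records["event"])
    s = kmf.survival_function_["KM_estimate"]
    s.index.name = "time"
    return s


def logrank(records: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2 with 1 df, p)."""
    _check_records(records)
    groups = records["group"].unique()
    if len(groups) != 2:
        raise SurvivalError("log-rank needs exactly 2 groups")
    if records["event"].sum() == 0:
        raise SurvivalError("no events observed")
    a = records[records["group"] == groups[0]]
    b = records[records["group"] == groups[1]]
    res = logrank_test(a["time"], b["time"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(records: pd.DataFrame) -> CoxResult:
    """Univariate Cox PH fit on the high-vs-low indicator (Efron ties).

    HR = exp(coef) for high relative to low; 95% CI = exp(coef +/- 1.96 SE).
    Complete separation of events (monotone likelihood) is flagged and the
    CI reported as unbounded.
    """
    _check_records(records)
    if records["event"].sum() == 0:
        raise SurvivalError("no events observed")
    frame = pd.DataFrame({
        "time": records["time"].to_numpy(float),
        "event": records["event"].to_numpy(int),
        "high": (records["group"] == "high").astype(float),
    })
    if frame["high"].sum() == 0 or frame["high"].sum() == len(frame):
        raise SurvivalError("both groups need >= 1 subject")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                frame, duration_col="time", event_col="event",
                fit_options={"precision": 1e-9},
            )
    except ConvergenceError:
        events_high = frame.loc[frame["event"] == 1, "high"]
        sign = 1.0 if events_high.mean() > 0.5 else -1.0
        return CoxResult(
            hr=float("inf") if sign > 0 else 0.0,
            ci_low=0.0, ci_high=float("inf"),
            p=float("nan"), coef=sign * float("inf"), se=float("inf"),
            separation=True,
        )
    coef = float(cph.params_["high"])
    se = float(cph.standard_errors_["high"])
    z = stats.norm.ppf(0.975)
    hr = float(np.exp(coef))
    p = float(cph.summary.loc["high", "p"])
    # a huge SE relative to the coefficient signals monotone likelihood that
    # stopped short of a ConvergenceError
    separation = bool(se > 1e3)
    return CoxResult(
        hr=hr,
        ci_low=float(np.exp(coef - z * se)) if not separation else 0.0,
        ci_high=float(np.exp(coef + z * se)) if not separation else float("inf"),
        p=p, coef=coef, se=se, separation=separation,
    )


def survival_fit(records: pd.DataFrame, marker: str = "marker") -> SurvivalFit:
    """Median split + KM + log-rank + Cox for one marker."""
    split = median_split(records) if "group" not in records.columns else records
    high = split[split["group"] == "high"]
    low = split[split["group"] == "low"]
    chi2, p = logrank(split)
    cox = cox_univariate(split)
    return SurvivalFit(
        marker=marker,
        n_high=len(high), n_low=len(low),
        km_high=km_estimate(high), km_low=km_estimate(low),
        logrank_chi2=chi2, logrank_p=p, cox=cox,
    )


def read_cohort(path) -> pd.DataFrame:
    """Cohort TSV: subject_id, time_days, event, expression."""
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep)
    required = {"subject_id", "time_days", "event", "expression"}
    if not required <= set(frame.columns):
        raise SurvivalError(f"cohort table needs columns {sorted(required)}")
    return frame.rename(columns={"time_days": "time"})
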
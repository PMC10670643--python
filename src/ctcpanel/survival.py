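"""Kaplan-Meier, log-rank, and Cox proportional-hazards analysis.

Thin, validated interfaces over lifelines.  Conventions: survival times
are positive days; the event flag is 1 for progression (PFS) or death
(OS) and 0 for censoring; at tied times events precede censorings; the
median is the smallest event time at which S(t) <= 0.5, undefined (NaN)
when the curve never reaches 0.5.  Cox models use Efron tie handling,
appropriate for day-resolution times where ties are common; constant
covariates are dropped with a warning instead of breaking the fit, and
non-convergence (e.g. monotone likelihood under complete separation) is
flagged rather than silently reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines import statistics as lls
from lifelines.exceptions import ConvergenceError

from .stats import TestResult


@dataclass
class KMCurve:
    """Product-limit estimate with its risk table."""

    event_times: np.ndarray   # distinct observed times (events or censorings)
    survival: np.ndarray      # S(t) just after each time
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    median: float             # NaN when S never reaches 0.5

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times, "at_risk": self.at_risk,
            "events": self.events, "censored": self.censored,
            "survival": self.survival,
        })


def _validate(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event)
    if t.size == 0:
        raise ValueError("need at least one record")
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    if set(np.unique(e)) - {0, 1, True, False}:
        raise ValueError("event flags must be 0/1")
    return t, e.astype(int)


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    t, e = _validate(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    tab = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index \
        else kmf.event_table
    times = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    med = kmf.median_survival_time_
    return KMCurve(
        event_times=times, survival=surv,
        at_risk=tab["at_risk"].to_numpy(),
        events=tab["observed"].to_numpy(),
        censored=tab["censored"].to_numpy(),
        median=float(med) if np.isfinite(med) else float("nan"),
    )


def median_survival(curve: KMCurve) -> float:
    """Median survival time in days; NaN when undefined."""
    return curve.median


def logrank_test(time_a, event_a, time_b, event_b) -> TestResult:
    """Two-group log-rank test (chi-square, 1 df)."""
    ta, ea = _validate(time_a, event_a)
    tb, eb = _validate(time_b, event_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank is undefined with no events in either group")
    res = lls.logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return TestResult(statistic=float(res.test_statistic),
                      p_value=float(res.p_value), method="logrank")


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary."""

    summary: pd.DataFrame     # per-term: beta, hr, se, z, p
    converged: bool
    dropped: list[str]        # constant covariates removed before fitting
    separation: bool          # monotone-likelihood / non-convergence flag
    n: int
    n_events: int

    def coef(self, term: str) -> float:
        return float(self.summary.loc[term, "beta"])

    def hazard_ratio(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])


def cox_ph(
    records: pd.DataFrame, duration_col: str, event_col: str,
    covariates: list[str], ties: str = "efron",
) -> CoxFit:
    """Cox regression of the given endpoint on the listed covariates.

    Non-numeric covariates are dummy-coded (first level as reference);
    covariates constant across patients are dropped with a warning.
    """
    t, e = _validate(records[duration_col], records[event_col])
    if e.sum() < 1:
        raise ValueError("Cox regression requires at least one event")
    X = records[covariates].copy()
    X = pd.get_dummies(X, drop_first=True, dtype=float)
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant covariate(s): {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    if X.shape[1] == 0:
        # every covariate constant: the model reduces to the null model
        return CoxFit(summary=pd.DataFrame(columns=["beta", "hr", "se", "z", "p"]),
                      converged=True, dropped=dropped, separation=False,
                      n=len(t), n_events=int(e.sum()))
    if X.drop_duplicates().shape[0] < 2:
        raise ValueError("need at least 2 distinct covariate patterns")

    df = X.assign(**{duration_col: t, event_col: e})
    cph = CoxPHFitter()
    converged, separation = True, False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col=duration_col, event_col=event_col)
        except ConvergenceError:
            return CoxFit(summary=pd.DataFrame(
                columns=["beta", "hr", "se", "z", "p"]),
                converged=False, dropped=dropped, separation=True,
                n=len(df), n_events=int(e.sum()))
        for w in caught:
            msg = str(w.message).lower()
            if "convergence" in msg or "complete separation" in msg \
                    or "monotone" in msg:
                separation = separation or "separation" in msg or "monotone" in msg
                converged = converged and "failed" not in msg
    s = cph.summary
    out = pd.DataFrame({
        "beta": s["coef"], "hr": np.exp(s["coef"]), "se": s["se(coef)"],
        "z": s["z"], "p": s["p"],
    })
    out.index.name = "term"
    return CoxFit(summary=out, converged=converged, dropped=dropped,
                  separation=separation, n=len(df), n_events=int(e.sum()))


def km_by_group(records: pd.DataFrame, duration_col: str, event_col: str,
                group_col: str) -> dict[str, KMCurve]:
    """One KM curve per level of a grouping column."""
    return {str(level): km_estimate(sub[duration_col], sub[event_col])
            for level, sub in records.groupby(group_col)}
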
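"""Kaplan–Meier estimation, log-rank tests and Cox proportional-hazards
fits — the statistical substrate of every pipeline stage.

The estimators are delegated to lifelines; this module pins the exact
conventions the pipeline relies on:

* median survival is the smallest time t with S(t) <= 0.5, infinite
  ("not reached") when the curve never drops that far;
* at tied times, events precede censorings;
* Cox fits use the Efron correction for tied event times, Newton-type
  maximization, and report per-covariate Wald z and p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test


class CoxConvergenceError(RuntimeError):
    """The partial-likelihood maximization failed; diagnostics attached."""


@dataclass
class SurvivalCurve:
    event_times: np.ndarray            # sorted distinct observed times
    survival_probabilities: np.ndarray  # S(t) at each time, non-increasing
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median_survival: float             # months; inf when not reached

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median_survival)


@dataclass
class LogrankResult:
    chi_square: float
    degrees_freedom: int
    p_value: float


@dataclass
class CoxFit:
    """Per-covariate partial-likelihood estimates.

    ``summary`` has one row per covariate with columns
    ``beta, hazard_ratio, se, z, p``; ``hazard_ratio`` is exp(beta) exactly.
    """

    summary: pd.DataFrame
    log_likelihood: float
    converged: bool

    def beta(self, name: str) -> float:
        return float(self.summary.loc[name, "beta"])

    def hazard_ratio(self, name: str) -> float:
        return float(self.summary.loc[name, "hazard_ratio"])

    def p_value(self, name: str) -> float:
        return float(self.summary.loc[name, "p"])


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have the same length")
    if (times < 0).any() or not np.isfinite(times).all():
        raise ValueError("times must be finite and non-negative")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return times, events


def kaplan_meier(times, events) -> SurvivalCurve:
    """Product-limit estimate of the survival function."""
    times, events = _check_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    if 0.0 in table.index and table.loc[0.0, "observed"] == 0 and 0.0 not in times:
        table = table.drop(index=0.0)
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index, method="ffill")
    s = surv.to_numpy(dtype=float)
    median = np.inf
    below = np.nonzero(s <= 0.5)[0]
    if below.size:
        median = float(table.index[below[0]])
    return SurvivalCurve(
        event_times=table.index.to_numpy(dtype=float),
        survival_probabilities=s,
        n_at_risk=table["at_risk"].to_numpy(dtype=int),
        n_events=table["observed"].to_numpy(dtype=int),
        median_survival=median,
    )


def logrank_test(times, events, group_labels) -> LogrankResult:
    """k-sample log-rank test with the hypergeometric variance; df = k-1."""
    times, events = _check_surv(times, events)
    groups = np.asarray(group_labels)
    if groups.shape != times.shape:
        raise ValueError("group labels must match times in length")
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    res = multivariate_logrank_test(times, groups, events)
    return LogrankResult(
        chi_square=float(res.test_statistic),
        degrees_freedom=int(uniq.size - 1),
        p_value=float(res.p_value),
    )


def cox_fit(covariates: pd.DataFrame, times, events) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties, Newton maximization).

    ``covariates`` is a patients-x-covariates DataFrame.  Constant
    covariates are rejected up front; convergence failures raise
    :class:`CoxConvergenceError` with lifelines' diagnostics.
    """
    times, events = _check_surv(times, events)
    if not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(np.asarray(covariates, dtype=float))
        covariates.columns = [f"x{i}" for i in range(covariates.shape[1])]
    if covariates.shape[0] != times.size:
        raise ValueError("covariate rows must match number of patients")
    for col in covariates.columns:
        if covariates[col].nunique(dropna=True) <= 1:
            raise ValueError(f"covariate {col!r} is constant across patients")
    if int(events.sum()) < covariates.shape[1]:
        raise ValueError("fewer events than covariates")

    frame = covariates.reset_index(drop=True).astype(float).copy()
    frame["_time"] = times
    frame["_event"] = events
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="_time", event_col="_event")
    except ConvergenceError as exc:
        raise CoxConvergenceError(f"Cox fit did not converge: {exc}") from exc
    summ = pd.DataFrame(
        {
            "beta": cph.params_,
            "hazard_ratio": np.exp(cph.params_),
            "se": cph.standard_errors_,
        }
    )
    summ["z"] = summ["beta"] / summ["se"]
    summ["p"] = cph.summary["p"]
    return CoxFit(
        summary=summ,
        log_likelihood=float(cph.log_likelihood_),
        converged=True,
    )
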
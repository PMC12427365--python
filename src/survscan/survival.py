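"""Kaplan–Meier estimation and the two-group log-rank test.

These are implemented from first principles because the screening rule
downstream needs the observed/expected event decomposition of the
log-rank statistic, not just a p-value: a prognostic gene is labelled
*unfavorable* when the high-expression group accumulates more observed
than expected events, and *favorable* otherwise.

Conventions (the standard ones for right-censored data):

* the risk set at time ``t`` contains every sample with ``time >= t``,
  so samples censored exactly at an event time are still at risk there
  (events are processed before censorings at tied instants);
* the Kaplan–Meier curve steps only at times where at least one event
  occurred; censoring-only times shrink later risk sets but add no step;
* the log-rank p-value is two-sided, from the upper tail of a
  chi-square(1) distribution;
* the hypergeometric variance term at an event time with a risk set of
  size 1 is taken as zero (the 0/0 guard).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

__all__ = ["KMCurve", "LogRankResult", "km_estimate", "logrank_test"]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate evaluated just after each event time."""

    event_times: np.ndarray  # strictly increasing, times with >=1 event
    survival: np.ndarray     # S(t+) at each event time, non-increasing
    at_risk: np.ndarray      # risk-set size n_j at each event time
    n_events: np.ndarray     # d_j events at each event time

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step-function lookup."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    """Two-group log-rank test with per-group observed/expected events."""

    statistic: float           # chi-square(1) scale, >= 0
    p_value: float
    observed: tuple[float, float]   # events in (group0, group1)
    expected: tuple[float, float]   # expected events under the null
    n_per_group: tuple[int, int]


def _validate_time_event(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("time must be a non-empty 1-d array")
    if e.shape != t.shape:
        raise ValueError("time and event must have the same length")
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("all times must be finite and > 0")
    if not np.all(np.isin(e, (0, 1))):
        raise ValueError("event indicators must be 0 or 1")
    return t, e.astype(np.int64)


def _event_time_tables(t_sorted: np.ndarray, e_sorted: np.ndarray):
    """Distinct event times with per-time event counts and risk-set sizes."""
    ut = np.unique(t_sorted[e_sorted == 1])
    start = np.searchsorted(t_sorted, ut, side="left")
    n_at = t_sorted.size - start          # |{time >= ut_j}|
    te = t_sorted[e_sorted == 1]          # sorted event times incl. ties
    d = (
        np.searchsorted(te, ut, side="right")
        - np.searchsorted(te, ut, side="left")
    )
    return ut, n_at, d


def km_estimate(time, event) -> KMCurve:
    """Kaplan–Meier product-limit estimate.

    Parameters
    ----------
    time : array of positive follow-up times
    event : array of 0/1 indicators (1 = event observed, 0 = censored)
    """
    t, e = _validate_time_event(time, event)
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    ut, n_at, d = _event_time_tables(ts, es)
    surv = np.cumprod(1.0 - d / n_at)
    return KMCurve(event_times=ut, survival=surv, at_risk=n_at, n_events=d)


def logrank_test(time, event, group) -> LogRankResult:
    """Standard (unweighted) two-group log-rank test.

    At each distinct event time j with d_j pooled events, n_j at risk and
    n_1j at risk in group 1: E_1j = d_j n_1j / n_j and
    V_j = d_j (n_1j/n_j)(1 - n_1j/n_j)(n_j - d_j)/(n_j - 1).
    The statistic is (sum(O_1j - E_1j))^2 / sum(V_j), referred to
    chi-square(1); a zero total variance yields statistic 0, p 1.

    ``group`` is a 0/1 label per sample; observed/expected pairs are
    reported as (group 0, group 1).
    """
    t, e = _validate_time_event(time, event)
    g = np.asarray(group)
    if g.shape != t.shape:
        raise ValueError("group must match time in length")
    if not np.all(np.isin(g, (0, 1))):
        raise ValueError("group labels must be 0 or 1")
    g = g.astype(bool)
    n1_total = int(g.sum())
    n0_total = t.size - n1_total
    if n1_total == 0 or n0_total == 0:
        raise ValueError("both groups must be non-empty")
    if not np.any(e == 1):
        raise ValueError("no events observed; log-rank test undefined")

    order = np.argsort(t, kind="stable")
    ts, es, gs = t[order], e[order], g[order]
    ut, n_at, d = _event_time_tables(ts, es)

    t1 = ts[gs]                                   # already sorted
    n1_at = n1_total - np.searchsorted(t1, ut, side="left")
    te1 = ts[gs & (es == 1)]
    d1 = (
        np.searchsorted(te1, ut, side="right")
        - np.searchsorted(te1, ut, side="left")
    )

    frac1 = n1_at / n_at
    e1 = d * frac1
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * frac1 * (1.0 - frac1) * (n_at - d) / (n_at - 1.0)
    v = np.where(n_at <= 1, 0.0, v)

    o1 = float(d1.sum())
    e1_sum = float(e1.sum())
    v_sum = float(v.sum())
    d_sum = float(d.sum())
    if v_sum > 0.0:
        stat = (o1 - e1_sum) ** 2 / v_sum
        p = float(chi2.sf(stat, 1))
    else:
        stat, p = 0.0, 1.0
    return LogRankResult(
        statistic=float(stat),
        p_value=p,
        observed=(d_sum - o1, o1),
        expected=(d_sum - e1_sum, e1_sum),
        n_per_group=(n0_total, n1_total),
    )
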
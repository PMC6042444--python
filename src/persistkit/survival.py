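"""Product-limit survival estimation and two-sample tests, written from scratch.

The estimator is the standard Kaplan-Meier product limit
``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` over distinct event times, with
Greenwood's variance ``S(t)^2 * sum d_i / (n_i (n_i - d_i))`` and a
symmetric 95% confidence band ``S +/- 1.96 SE`` on the plain scale, clipped
to [0, 1] (a log-log band is available behind a flag).  When every subject
at risk fails at some event time (``n_i == d_i``) the Greenwood term is
undefined; the band is flagged unavailable from that time on rather than
silently reported.

Two-sample tests pool the distinct event times and compare observed with
hypergeometric-expected events in the first group; weights of 1 give the
log-rank test and weights equal to the total number at risk give the
Gehan-Breslow generalisation of the Wilcoxon test (the standard reading of
"Wilcoxon rank sum" for censored persistence data).  Ties between events and
censorings at the same time are resolved events-first.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

Z95 = 1.959963984540054


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier estimate at the distinct event times (ascending)."""

    times: np.ndarray       # distinct event times
    at_risk: np.ndarray     # n_i just before each event time
    events: np.ndarray      # d_i at each event time
    survival: np.ndarray    # S(t_i)
    se: np.ndarray          # Greenwood standard error (nan once undefined)
    ci_low: np.ndarray
    ci_high: np.ndarray
    ci_available: np.ndarray  # bool per time point
    n: int

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly ascending")


def km_estimate(time, event, ci_scale: str = "plain") -> KMCurve:
    """Product-limit estimate from per-subject (time, event-indicator) pairs.

    ``event`` is truthy for an observed discontinuation and falsy for a
    censored record.  ``ci_scale`` is ``"plain"`` (symmetric, matching
    rate +/- CI reporting) or ``"loglog"``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise ValueError("empty sample")
    if np.any(time < 0):
        raise ValueError("times must be non-negative")

    event_times = np.unique(time[event])
    n_total = time.size
    at_risk = np.empty(event_times.size, dtype=np.int64)
    d = np.empty(event_times.size, dtype=np.int64)
    for i, t in enumerate(event_times):
        at_risk[i] = np.sum(time >= t)  # events-first tie convention
        d[i] = np.sum((time == t) & event)

    frac = 1.0 - d / at_risk
    survival = np.cumprod(frac)
    # Greenwood: variance undefined from the first time with n_i == d_i
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(at_risk > d, d / (at_risk * (at_risk - d).astype(float)), np.nan)
        cum = np.cumsum(terms)
        var = survival**2 * cum
    se = np.sqrt(var)
    available = ~np.isnan(se)

    with np.errstate(invalid="ignore", divide="ignore"):
        if ci_scale == "plain":
            lo = np.clip(survival - Z95 * se, 0.0, 1.0)
            hi = np.clip(survival + Z95 * se, 0.0, 1.0)
        elif ci_scale == "loglog":
            # exp(-exp(log(-log S) -/+ z * se(log(-log S))))
            logS = np.log(survival)
            se_cll = np.sqrt(cum) / np.abs(logS)
            theta = np.log(-logS)
            lo = np.exp(-np.exp(theta + Z95 * se_cll))
            hi = np.exp(-np.exp(theta - Z95 * se_cll))
        else:
            raise ValueError(f"unknown ci_scale {ci_scale!r}")
    lo = np.where(available, lo, np.nan)
    hi = np.where(available, hi, np.nan)
    return KMCurve(event_times, at_risk, d, survival, se, lo, hi, available, n_total)


def survival_at(curve: KMCurve, t: float):
    """Right-continuous read-out of the curve at time ``t``.

    Returns ``(estimate, (lo, hi))``; the interval is ``None`` when the
    Greenwood band is unavailable at ``t``.  Before the first event the
    estimate is 1 with a degenerate interval.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0, (1.0, 1.0)
    est = float(curve.survival[idx])
    if not curve.ci_available[idx]:
        return est, None
    return est, (float(curve.ci_low[idx]), float(curve.ci_high[idx]))


@dataclass(frozen=True)
class TestResult:
    name: str  # "log-rank" | "wilcoxon"
    statistic: float  # chi-squared form, df = 1
    df: int
    p_value: float


def two_sample_test(time_a, event_a, time_b, event_b, weight: str = "log-rank") -> TestResult:
    """Weighted two-sample test of equal discontinuation distributions.

    ``weight="log-rank"`` uses unit weights; ``weight="wilcoxon"`` uses the
    total number at risk (Gehan-Breslow).  With no events in either sample
    the statistic is 0 and p = 1.
    """
    if weight not in ("log-rank", "wilcoxon"):
        raise ValueError(f"unknown weight {weight!r}")
    time_a = np.asarray(time_a, dtype=float)
    time_b = np.asarray(time_b, dtype=float)
    event_a = np.asarray(event_a, dtype=bool)
    event_b = np.asarray(event_b, dtype=bool)
    if time_a.size == 0 or time_b.size == 0:
        raise ValueError("both samples must be nonempty")

    all_times = np.concatenate([time_a[event_a], time_b[event_b]])
    event_times = np.unique(all_times)
    z = 0.0
    var = 0.0
    for t in event_times:
        n1 = np.sum(time_a >= t)
        n2 = np.sum(time_b >= t)
        d1 = np.sum((time_a == t) & event_a)
        d2 = np.sum((time_b == t) & event_b)
        n = n1 + n2
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        e1 = d * n1 / n
        v = (d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)) if n > 1 else 0.0
        w = float(n) if weight == "wilcoxon" else 1.0
        z += w * (d1 - e1)
        var += w * w * v
    if var == 0.0:
        return TestResult(weight, 0.0, 1, 1.0)
    stat = z * z / var
    return TestResult(weight, float(stat), 1, float(stats.chi2.sf(stat, df=1)))


def pairwise_vs_reference(samples: dict, reference: str):
    """Log-rank and Wilcoxon tests of each group against a reference group.

    ``samples`` maps group label -> (times, events).  Returns a list of dicts
    (group, test, statistic, p_value); the reference is not compared with
    itself.
    """
    if reference not in samples:
        raise KeyError(f"reference group {reference!r} not among {sorted(samples)}")
    t_ref, e_ref = samples[reference]
    rows = []
    for label, (t, e) in samples.items():
        if label == reference:
            continue
        for weight in ("log-rank", "wilcoxon"):
            res = two_sample_test(t, e, t_ref, e_ref, weight=weight)
            rows.append({
                "group": label,
                "reference": reference,
                "test": res.name,
                "statistic": res.statistic,
                "p_value": res.p_value,
            })
    return rows
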
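"""Survival machinery built from first principles.

Implements the three estimators the screening pipeline rests on:

* the Kaplan-Meier product-limit estimator of a survival function under
  right censoring,
* the two-group logrank test (hypergeometric expected events and variance
  at each distinct event time, chi-square with 1 df),
* Cox proportional hazards for a single binary group covariate, maximizing
  the partial likelihood by Newton-Raphson with Efron (default) or Breslow
  handling of tied event times.

These are the ranking engines behind every per-gene screen, so they are
written here rather than delegated; lifelines serves as an independent
cross-check in the test suite only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "LogrankResult",
    "CoxBinary",
    "CoxBinaryResults",
    "km_estimate",
    "logrank_test",
    "cox_fit_binary",
]

_MAX_BETA = 20.0
_SCORE_TOL = 1e-9
_MAX_ITER = 50


def _as_survival_arrays(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be equal-length 1-d vectors")
    if t.size == 0:
        raise ValueError("empty survival input")
    if np.any(np.isnan(t)) or np.any(t < 0):
        raise ValueError("times must be non-negative and non-missing")
    e = e.astype(float)
    if not np.isin(e, [0.0, 1.0]).all():
        raise ValueError("events must be binary 0/1")
    return t, e.astype(int)


@dataclass
class SurvivalCurve:
    """Kaplan-Meier step function with at-risk/event bookkeeping.

    ``event_times`` are the distinct times at which events occurred;
    ``survival_prob[i]`` is S(t) just after ``event_times[i]``.  The median is
    the smallest event time with S(t) <= 0.5, or None if the curve never
    reaches 0.5 (e.g. heavy censoring).
    """

    event_times: np.ndarray
    survival_prob: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_total: int
    median_survival: float | None

    def survival_at(self, t: float) -> float:
        """S(t): step-function evaluation (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival_prob[idx - 1])

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival_prob,
            }
        )


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Censored subjects at time t leave the risk set after the events at t
    (the standard convention).  All-censored input yields a flat curve at 1
    with an undefined median.
    """
    t, e = _as_survival_arrays(times, events)
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    n = t.size

    ev_times = np.unique(t[e == 1])
    if ev_times.size == 0:
        return SurvivalCurve(
            event_times=np.empty(0),
            survival_prob=np.empty(0),
            n_at_risk=np.empty(0, dtype=int),
            n_events=np.empty(0, dtype=int),
            n_total=n,
            median_survival=None,
        )
    # risk set size just before each event time; events at each time
    n_at_risk = n - np.searchsorted(t, ev_times, side="left")
    d = np.array([int(np.sum((t == tt) & (e == 1))) for tt in ev_times])
    surv = np.cumprod(1.0 - d / n_at_risk)
    reached = surv <= 0.5
    median = float(ev_times[np.argmax(reached)]) if reached.any() else None
    return SurvivalCurve(
        event_times=ev_times,
        survival_prob=surv,
        n_at_risk=n_at_risk.astype(int),
        n_events=d,
        n_total=n,
        median_survival=median,
    )


@dataclass
class LogrankResult:
    chi_square: float
    p_value: float
    observed: np.ndarray  # events per group (group order = sorted labels)
    expected: np.ndarray
    groups: tuple
    zero_events: bool = False


def _two_group_arrays(times, events, group_labels):
    t, e = _as_survival_arrays(times, events)
    g = np.asarray(group_labels)
    if g.shape != t.shape:
        raise ValueError("group_labels must match times in length")
    labels = sorted(set(g.tolist()))
    if len(labels) != 2:
        raise ValueError(f"exactly two non-empty groups required, got {labels}")
    x = (g == labels[1]).astype(int)
    return t, e, x, tuple(labels)


def _event_time_table(t, e, x):
    """Per distinct event time: (d, d1, n, n1) with risk sets by >= time."""
    order = np.argsort(t, kind="mergesort")
    t, e, x = t[order], e[order], x[order]
    n_total = t.size
    ev_times = np.unique(t[e == 1])
    n_at_risk = n_total - np.searchsorted(t, ev_times, side="left")
    # suffix sums of x give group-1 members still at risk
    x_suffix = np.concatenate([np.cumsum(x[::-1])[::-1], [0]])
    n1_at_risk = x_suffix[np.searchsorted(t, ev_times, side="left")]
    d = np.zeros(ev_times.size, dtype=int)
    d1 = np.zeros(ev_times.size, dtype=int)
    ev_mask = e == 1
    idx = np.searchsorted(ev_times, t[ev_mask])
    np.add.at(d, idx, 1)
    np.add.at(d1, idx, x[ev_mask])
    return ev_times, d, d1, n_at_risk, n1_at_risk


def logrank_test(times, events, group_labels) -> LogrankResult:
    """Two-group logrank test.

    At each distinct event time the expected number of group-1 events is the
    hypergeometric mean d * n1 / n; the variance is the hypergeometric
    variance.  The statistic (O - E)^2 / V is referred to chi-square with
    1 df.  Zero total events yields p = 1 with a flag rather than an error.
    """
    t, e, x, labels = _two_group_arrays(times, events, group_labels)
    ev_times, d, d1, n, n1 = _event_time_table(t, e, x)
    if ev_times.size == 0:
        return LogrankResult(0.0, 1.0, np.zeros(2), np.zeros(2), labels, zero_events=True)
    exp1 = d * n1 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var1 = d * (n1 / n) * (1 - n1 / n) * (n - d) / np.maximum(n - 1, 1)
    O1, E1, V = d1.sum(), exp1.sum(), var1.sum()
    total = d.sum()
    observed = np.array([total - O1, O1], dtype=float)
    expected = np.array([total - E1, E1], dtype=float)
    if V <= 0:
        chi = 0.0
    else:
        chi = float((O1 - E1) ** 2 / V)
    p = float(stats.chi2.sf(chi, df=1)) if V > 0 else 1.0
    return LogrankResult(chi, max(p, np.finfo(float).tiny), observed, expected, labels)


# ---------------------------------------------------------------------------
# Cox proportional hazards, single binary covariate
# ---------------------------------------------------------------------------

@dataclass
class CoxBinaryResults:
    """Fit of a binary-covariate Cox model.

    ``beta`` is the log hazard ratio of the second group (sorted label order)
    relative to the first; ``p_value`` is the two-sided Wald test.  When the
    partial likelihood is monotone (one group's events all precede the
    other's exposure) the fit is flagged ``converged=False`` with ``beta``
    capped at +/-20 and the p-value must be treated as unreliable.
    """

    beta: float
    se_beta: float
    wald_z: float
    p_value: float
    ties_method: str
    converged: bool
    n_used: int
    n_events: int
    groups: tuple
    loglik: float
    score_stat: float  # score test statistic at beta = 0 (chi-square, 1 df)
    n_iter: int = 0

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.beta))

    def summary(self) -> str:
        lines = [
            "Cox proportional hazards (binary covariate)",
            f"  groups: {self.groups[1]} vs {self.groups[0]} (reference)",
            f"  n = {self.n_used}, events = {self.n_events}, ties = {self.ties_method}",
            f"  log HR (beta) = {self.beta:.6g}   HR = {self.hazard_ratio:.6g}",
            f"  SE(beta) = {self.se_beta:.6g}   Wald z = {self.wald_z:.4g}   "
            f"p = {self.p_value:.4g}",
            f"  converged: {self.converged} ({self.n_iter} iterations)",
        ]
        return "\n".join(lines)


class CoxBinary:
    """Cox proportional-hazards model with a single binary group covariate.

    Parameters
    ----------
    times, events : array-like
        Right-censored follow-up times and 1/0 event indicators.
    group_labels : array-like
        Exactly two distinct labels; the second in sorted order is coded 1.

    ``fit(ties_method=...)`` maximizes the partial likelihood by
    Newton-Raphson and returns :class:`CoxBinaryResults`.
    """

    def __init__(self, times, events, group_labels):
        self.times, self.events, self.x, self.groups = _two_group_arrays(
            times, events, group_labels
        )
        (self._ev_times, self._d, self._d1, self._n, self._n1) = _event_time_table(
            self.times, self.events, self.x
        )

    def _tie_expansion(self, ties_method: str):
        """Flatten event times into one row per (event time, within-tie index).

        For Efron the within-tie index l contributes a fraction l/d of the
        tied events' weight to the denominator; Breslow uses fraction 0.
        """
        d, d1, n, n1 = self._d, self._d1, self._n, self._n1
        rep = np.repeat(np.arange(d.size), d)
        if ties_method == "efron":
            frac = (np.arange(d.sum()) - np.repeat(np.cumsum(d) - d, d)) / np.repeat(d, d)
        elif ties_method == "breslow":
            frac = np.zeros(int(d.sum()))
        else:
            raise ValueError(f"ties_method must be 'efron' or 'breslow', got {ties_method!r}")
        return (
            np.repeat(n - n1, d).astype(float),   # n0 at risk
            np.repeat(n1, d).astype(float),       # n1 at risk
            frac * np.repeat(d - d1, d),          # tie correction, group 0
            frac * np.repeat(d1, d),              # tie correction, group 1
        )

    def _derivatives(self, beta: float, expansion):
        n0, n1, c0, c1 = expansion
        eb = np.exp(beta)
        denom = (n0 - c0) + (n1 - c1) * eb
        w = (n1 - c1) * eb
        u = w / denom
        s_total = float(self._d1.sum())
        loglik = s_total * beta - float(np.sum(np.log(denom)))
        score = s_total - float(np.sum(u))
        info = float(np.sum(u * (1.0 - u)))  # x binary => E[x^2] = E[x]
        return loglik, score, info

    def loglik(self, beta: float, ties_method: str = "efron") -> float:
        """Partial log-likelihood at ``beta`` (used by oracle cross-checks)."""
        return self._derivatives(beta, self._tie_expansion(ties_method))[0]

    def fit(self, ties_method: str = "efron") -> CoxBinaryResults:
        expansion = self._tie_expansion(ties_method)
        n_events = int(self._d.sum())
        # score test at beta = 0 (equals the logrank statistic under Breslow)
        _, score0, info0 = self._derivatives(0.0, expansion)
        score_stat = score0**2 / info0 if info0 > 0 else 0.0

        beta, converged, it = 0.0, False, 0
        loglik = score = info = 0.0
        if n_events == 0 or self._n1[0] in (0,) or info0 == 0:
            # no information about the group effect
            loglik, score, info = self._derivatives(0.0, expansion)
            se = np.inf
            return CoxBinaryResults(
                0.0, se, 0.0, 1.0, ties_method, False, self.times.size,
                n_events, self.groups, loglik, score_stat, 0,
            )
        for it in range(1, _MAX_ITER + 1):
            loglik, score, info = self._derivatives(beta, expansion)
            if abs(score) < _SCORE_TOL:
                converged = True
                break
            if info <= 0:
                break
            step = score / info
            step = np.clip(step, -2.0, 2.0)  # damp early overshoot
            beta = float(np.clip(beta + step, -_MAX_BETA, _MAX_BETA))
            if abs(beta) >= _MAX_BETA:
                converged = False  # monotone likelihood
                loglik, score, info = self._derivatives(beta, expansion)
                break
        se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf
        z = beta / se if np.isfinite(se) and se > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        return CoxBinaryResults(
            beta=float(beta),
            se_beta=se,
            wald_z=float(z),
            p_value=max(min(p, 1.0), np.finfo(float).tiny),
            ties_method=ties_method,
            converged=converged,
            n_used=int(self.times.size),
            n_events=n_events,
            groups=self.groups,
            loglik=float(loglik),
            score_stat=float(score_stat),
            n_iter=it,
        )


def cox_fit_binary(times, events, group_labels, ties_method: str = "efron") -> CoxBinaryResults:
    """Convenience wrapper: ``CoxBinary(times, events, group_labels).fit(...)``."""
    return CoxBinary(times, events, group_labels).fit(ties_method=ties_method)
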
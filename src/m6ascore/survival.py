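"""Kaplan-Meier estimation, log-rank tests, univariate Cox regression and
maximally-selected cutpoint search.

KM curves, the multi-group log-rank test and Cox fits delegate to lifelines
(Efron handling of tied event times, Wald inference from the observed
information).  The maximally-selected rank-statistic cutpoint — pick the
threshold on a continuous score that maximises the standardized two-group
log-rank statistic, subject to a minimum group-size fraction — is
implemented here directly: for each candidate cut (midpoints of sorted
distinct score values) the statistic (O - E) / sqrt(V) is computed with the
hypergeometric variance at each event time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "km_fit",
    "logrank_test",
    "CoxFit",
    "cox_univariate",
    "prognostic_filter",
    "CutpointResult",
    "max_sel_cutpoint",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray
    group: str = ""

    def survival_at(self, t: float) -> float:
        """S(t): step-function evaluation (S(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def plot(self, ax=None, max_time: float | None = None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.concatenate([[0.0], self.times])
        s = np.concatenate([[1.0], self.survival])
        if max_time is not None:
            keep = t <= max_time
            t, s = t[keep], s[keep]
        ax.step(t, s, where="post", label=self.group or None, **kwargs)
        ax.set_ylim(0, 1.05)
        ax.set_xlabel("time")
        ax.set_ylabel("S(t)")
        return ax


def _as_arrays(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time <= 0).any():
        raise ValueError("survival times must be > 0")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    return time, event


def km_fit(time, event, group_labels=None) -> dict[str, KMCurve]:
    """Product-limit estimator per group (estimation always uses all data)."""
    time, event = _as_arrays(time, event)
    if group_labels is None:
        group_labels = np.repeat("all", len(time))
    group_labels = np.asarray(group_labels)
    out: dict[str, KMCurve] = {}
    for g in pd.unique(group_labels):
        mask = group_labels == g
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        tbl = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
        ev = tbl[tbl["observed"] > 0]
        times = ev.index.to_numpy(dtype=float)
        surv = kmf.survival_function_at_times(times).to_numpy()
        at_risk = ev["at_risk"].to_numpy()
        out[str(g)] = KMCurve(
            times=times,
            survival=surv,
            at_risk=at_risk,
            censor_times=np.sort(time[mask][event[mask] == 0]),
            group=str(g),
        )
    return out


def logrank_test(time, event, group_labels) -> tuple[float, int, float]:
    """Multi-group log-rank test; returns (chi2, df, p)."""
    time, event = _as_arrays(time, event)
    group_labels = np.asarray(group_labels)
    if event.sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")
    groups = pd.unique(group_labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    res = multivariate_logrank_test(time, group_labels, event)
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


@dataclass
class CoxFit:
    """Univariate Cox proportional-hazards fit (Efron ties, Wald inference)."""

    beta: float
    se: float
    z: float
    p: float
    ci_low: float
    ci_high: float
    converged: bool
    ties: str = "efron"

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "beta": self.beta,
                "HR": self.hr,
                "se": self.se,
                "z": self.z,
                "p": self.p,
                "HR_ci_low": float(np.exp(self.ci_low)),
                "HR_ci_high": float(np.exp(self.ci_high)),
                "converged": self.converged,
            }
        )


def cox_univariate(time, event, covariate) -> CoxFit:
    """Fit a single-covariate Cox model.

    Monotone (perfectly separating) likelihoods are flagged non-converged;
    the returned beta is the capped value at the point lifelines stopped.
    """
    time, event = _as_arrays(time, event)
    covariate = np.asarray(covariate, dtype=float)
    if not np.isfinite(covariate).all():
        raise ValueError("covariate must be finite")
    if event.sum() < 1:
        raise ValueError("need at least one event")
    if np.ptp(covariate) == 0:
        # no variation: the partial likelihood is flat, beta = 0 exactly
        return CoxFit(0.0, np.inf, 0.0, 1.0, -np.inf, np.inf, converged=True)
    df = pd.DataFrame({"time": time, "event": event, "x": covariate})
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError:
            converged = False
            cph = CoxPHFitter(penalizer=1e-6)
            cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary.loc["x"]
    return CoxFit(
        beta=float(s["coef"]),
        se=float(s["se(coef)"]),
        z=float(s["z"]),
        p=float(s["p"]),
        ci_low=float(s["coef lower 95%"]),
        ci_high=float(s["coef upper 95%"]),
        converged=converged,
    )


def prognostic_filter(
    x, time, event, genes: list[str] | None = None, p_cut: float = 0.05
) -> pd.DataFrame:
    """Univariate Cox per gene; returns the per-gene summary with a 'selected' flag.

    Genes whose Wald p < ``p_cut`` form the prognostic signature.
    """
    values = x.values if hasattr(x, "unit") else x
    genes = list(values.index) if genes is None else [g for g in genes if g in values.index]
    rows = {}
    for g in genes:
        fit = cox_univariate(time, event, values.loc[g].to_numpy())
        rows[g] = fit.summary()
    out = pd.DataFrame(rows).T
    out["selected"] = out["p"] < p_cut
    return out


# ---------------------------------------------------------------------------
# Maximally selected rank statistics
# ---------------------------------------------------------------------------

def _logrank_z(time: np.ndarray, event: np.ndarray, in_high: np.ndarray) -> float:
    """Standardized two-group log-rank statistic (O - E)/sqrt(V) for the high group."""
    order = np.argsort(time, kind="mergesort")
    t, e, g = time[order], event[order], in_high[order]
    n = len(t)
    obs = exp = var = 0.0
    i = 0
    n_risk = n
    n_risk_high = int(g.sum())
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0:
            d_high = int(e[i:j][g[i:j] == 1].sum())
            obs += d_high
            exp += d * n_risk_high / n_risk
            if n_risk > 1:
                var += (
                    d
                    * (n_risk_high / n_risk)
                    * (1 - n_risk_high / n_risk)
                    * (n_risk - d)
                    / (n_risk - 1)
                )
        n_risk -= j - i
        n_risk_high -= int(g[i:j].sum())
        i = j
    if var <= 0:
        return 0.0
    return (obs - exp) / np.sqrt(var)


@dataclass
class CutpointResult:
    """Outcome of the maximally-selected cutpoint search."""

    cutpoint: float
    statistic: float
    n_low: int
    n_high: int
    minprop: float

    def groups(self, score) -> pd.Series:
        score = pd.Series(score)
        return pd.Series(
            np.where(score > self.cutpoint, "high", "low"), index=score.index, name="score_group"
        )


def max_sel_cutpoint(time, event, score, minprop: float = 0.1) -> CutpointResult:
    """Cutpoint maximising the standardized two-group log-rank statistic.

    Candidates are midpoints between sorted distinct score values with both
    resulting groups at least ceil(minprop * n); ties in the maximum go to
    the lower cut.  The statistic is reported unadjusted for the selection
    (group comparison after the split should be interpreted accordingly).
    """
    time, event = _as_arrays(time, event)
    score = np.asarray(score, dtype=float)
    if not 0 < minprop < 0.5:
        raise ValueError("minprop must be in (0, 0.5)")
    distinct = np.unique(score)
    if len(distinct) < 2:
        raise ValueError("score must have at least 2 distinct values")
    n = len(score)
    min_n = int(np.ceil(minprop * n))
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best: tuple[float, float] | None = None
    for c in candidates:
        in_high = (score > c).astype(int)
        n_high = int(in_high.sum())
        if n_high < min_n or n - n_high < min_n:
            continue
        z = abs(_logrank_z(time, event, in_high))
        if best is None or z > best[1]:
            best = (c, z)
    if best is None:
        raise ValueError(f"no candidate cut leaves both groups >= {min_n} samples")
    cut, stat = best
    n_high = int((score > cut).sum())
    return CutpointResult(cutpoint=float(cut), statistic=float(stat), n_low=n - n_high, n_high=n_high, minprop=minprop)
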
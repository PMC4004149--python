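"""Life-table attrition curves on the discrete session grid.

Product-limit (Kaplan-Meier) survival over sessions 1..6 with Greenwood
variance and 95% confidence bands on the log(-log) scale, plus
median-split stratified curves for visualising how a covariate separates
dropout trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import N_SESSIONS, Cohort


@dataclass
class LifeTable:
    """Per-session attrition table with product-limit estimates.

    Events are counted before censoring within a session: a participant
    censored at session 6 is still at risk for a session-6 dropout.
    """

    table: pd.DataFrame  # session, at_risk, events, censored, survival, se, ci

    @property
    def survival(self) -> np.ndarray:
        return self.table["survival"].to_numpy()

    def __getitem__(self, session: int) -> float:
        """S(session); S(0) = 1."""
        if session == 0:
            return 1.0
        return float(
            self.table.loc[self.table["session"] == session, "survival"].iloc[0]
        )


def fit_km(
    event_times: np.ndarray,
    event_indicators: np.ndarray,
    n_sessions: int = N_SESSIONS,
    level: float = 0.95,
) -> LifeTable:
    """Product-limit estimator with Greenwood SEs and log(-log) CIs.

    The Greenwood variance is Var[S(j)] = S(j)^2 * sum_{s<=j} d_s /
    (r_s (r_s - d_s)); the confidence band is computed on the
    log(-log S) scale and back-transformed, which keeps it inside [0, 1]
    and behaves better than a plain Wald band at survival near 0 or 1.
    When no events have occurred by session j the band collapses to the
    point estimate.
    """
    times = np.asarray(event_times, dtype=np.int64)
    ind = np.asarray(event_indicators, dtype=np.int64)
    if times.size == 0:
        raise ValueError("empty input")
    if times.min() < 1 or times.max() > n_sessions:
        raise ValueError(f"event times must lie in 1..{n_sessions}")
    if not np.isin(ind, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    at_risk = len(times)
    surv = 1.0
    greenwood = 0.0  # running sum d/(r(r-d))
    for s in range(1, n_sessions + 1):
        d = int(((times == s) & (ind == 1)).sum())
        c = int(((times == s) & (ind == 0)).sum())
        if at_risk > 0 and d > 0:
            surv *= 1.0 - d / at_risk
            if at_risk > d:
                greenwood += d / (at_risk * (at_risk - d))
            else:
                greenwood = np.inf  # survival hit zero
        se = surv * np.sqrt(greenwood) if np.isfinite(greenwood) else 0.0
        if surv in (0.0, 1.0) or greenwood == 0.0 or not np.isfinite(greenwood):
            # band degenerates where the log(-log) transform is undefined
            lo = hi = surv
        else:
            # theta = log(-log S); se_theta by the delta method
            se_theta = np.sqrt(greenwood) / abs(np.log(surv))
            lo = surv ** np.exp(z * se_theta)
            hi = surv ** np.exp(-z * se_theta)
        rows.append(
            {
                "session": s,
                "at_risk": at_risk,
                "events": d,
                "censored": c,
                "survival": surv,
                "se": se,
                "ci_low": min(max(lo, 0.0), 1.0),
                "ci_high": min(max(hi, 0.0), 1.0),
            }
        )
        at_risk -= d + c
    return LifeTable(pd.DataFrame(rows))


def median_split(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Dichotomize at the sample median; ties go to the low stratum.

    Returns (labels, split_value) with labels in {"low", "high"}; low
    means value <= median, where the median of an even-sized sample is
    the midpoint of the two central order statistics.
    """
    vals = np.asarray(values, dtype=np.float64)
    if vals.size == 0:
        raise ValueError("empty input")
    if np.all(vals == vals[0]):
        raise ValueError("median split undefined for a constant covariate")
    med = float(np.median(vals))
    labels = np.where(vals <= med, "low", "high")
    return labels, med


def stratified_curves(
    cohort: Cohort, covariate_name: str
) -> dict[str, LifeTable | float]:
    """Median-split a covariate and fit a life table per stratum."""
    if covariate_name not in cohort.frame.columns:
        raise KeyError(f"unknown covariate {covariate_name!r}")
    vals = cohort.frame[covariate_name].to_numpy(dtype=np.float64)
    labels, med = median_split(vals)
    out: dict[str, LifeTable | float] = {"split_value": med}
    for group in ("low", "high"):
        mask = labels == group
        out[group] = fit_km(cohort.event_times[mask], cohort.events[mask])
    return out
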
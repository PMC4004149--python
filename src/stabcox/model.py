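"""Model-object interface to the penalized Cox machinery.

``PenalizedCox`` holds the (standardized) design and outcomes;
``fit``/``fit_path``/``fit_cv`` return results objects carrying
estimates, diagnostics and a ``summary()``.  This is the convenient
front door; the functional layer in :mod:`stabcox.cox` and
:mod:`stabcox.cv` is what it delegates to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import COVARIATES, Cohort, standardize_matrix
from .cox import (
    CoxFit,
    fit_cox_lasso,
    fit_coxph,
    lambda_max,
    lambda_path,
    neg_log_partial_likelihood,
)
from .cv import CVResult, cv_select


class PenalizedCox:
    """Cox proportional hazards with an optional L1 penalty.

    Parameters
    ----------
    X : array-like, n x p
        Predictor matrix on its native scale; standardized internally
        (mean 0, sample SD 1 per column).
    event_times, event_indicators : array-like
        Discrete session index (1..6) and dropout indicator per subject.
    names : list of str, optional
        Covariate names for reporting.
    """

    def __init__(self, X, event_times, event_indicators, names=None):
        X = np.asarray(X, dtype=np.float64)
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
        self.names = list(names)
        self.Z, self.scale = standardize_matrix(X, self.names)
        self.event_times = np.asarray(event_times, dtype=np.int64)
        self.event_indicators = np.asarray(event_indicators, dtype=np.int64)

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "PenalizedCox":
        return cls(
            cohort.covariate_matrix(),
            cohort.event_times,
            cohort.events,
            names=list(COVARIATES),
        )

    # -- likelihood surface --------------------------------------------------

    def neg_log_pl(self, beta) -> tuple[float, np.ndarray]:
        """Per-n Breslow negative log partial likelihood and gradient."""
        return neg_log_partial_likelihood(
            beta, self.Z, self.event_times, self.event_indicators
        )

    @property
    def lambda_max(self) -> float:
        return lambda_max(self.Z, self.event_times, self.event_indicators)

    # -- fitting -------------------------------------------------------------

    def fit(self, alpha: float = 0.0) -> "PenalizedCoxResults":
        """Fit at one penalty; alpha = 0 gives the Newton-Raphson MLE."""
        if alpha == 0.0:
            raw = fit_coxph(
                self.Z, self.event_times, self.event_indicators, names=self.names
            )
        else:
            raw = fit_cox_lasso(
                self.Z,
                self.event_times,
                self.event_indicators,
                alpha,
                names=self.names,
            )
        return PenalizedCoxResults(self, raw)

    def fit_path(
        self, n_lambda: int = 100, min_ratio: float = 0.01
    ) -> tuple[np.ndarray, list[CoxFit]]:
        """Warm-started fits along the decreasing penalty path."""
        return lambda_path(
            self.Z,
            self.event_times,
            self.event_indicators,
            n_lambda=n_lambda,
            min_ratio=min_ratio,
            names=self.names,
        )

    def fit_cv(
        self,
        K: int = 50,
        seed: int = 0,
        rule: str = "min",
        n_lambda: int = 100,
        min_ratio: float = 0.01,
    ) -> "PenalizedCoxResults":
        """Cross-validate the penalty, then fit at the selected value."""
        cv = cv_select(
            self.Z,
            self.event_times,
            self.event_indicators,
            K=K,
            seed=seed,
            n_lambda=n_lambda,
            min_ratio=min_ratio,
            rule=rule,
        )
        raw = fit_cox_lasso(
            self.Z,
            self.event_times,
            self.event_indicators,
            cv.selected_lambda,
            names=self.names,
        )
        return PenalizedCoxResults(self, raw, cv=cv)


@dataclass
class PenalizedCoxResults:
    """Fitted coefficients with scale metadata and a text summary."""

    model: PenalizedCox
    fit: CoxFit
    cv: CVResult | None = None

    @property
    def params(self) -> pd.Series:
        """Log hazard ratios per SD of each covariate."""
        return pd.Series(self.fit.beta, index=self.model.names, name="coef_std")

    @property
    def params_native(self) -> pd.Series:
        """Log hazard ratios per native unit of each covariate."""
        return pd.Series(
            self.model.scale.coef_to_native(self.fit.beta),
            index=self.model.names,
            name="coef_native",
        )

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params).rename("HR_per_SD")

    @property
    def active_set(self) -> list[str]:
        return self.fit.active_set

    def summary(self) -> str:
        head = [
            "Penalized Cox proportional hazards (Breslow ties, per-n likelihood)",
            f"  n={len(self.model.event_times)}, "
            f"events={int(self.model.event_indicators.sum())}, "
            f"p={len(self.model.names)}",
            f"  lambda={self.fit.lam:.6g}"
            + (f" (CV rule {self.cv.rule!r}, K folds)" if self.cv else ""),
            f"  converged={self.fit.converged} in {self.fit.n_iter} iterations; "
            f"objective={self.fit.neg_log_pl:.6f}",
            "",
            f"{'covariate':<24}{'coef/SD':>10}{'HR/SD':>8}{'coef/unit':>11}",
        ]
        body = [
            f"{name:<24}{b:>10.4f}{np.exp(b):>8.3f}{bn:>11.4f}"
            for name, b, bn in zip(
                self.model.names, self.fit.beta, self.params_native
            )
        ]
        return "\n".join(head + body)
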
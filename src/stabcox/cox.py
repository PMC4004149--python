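"""L1-penalized Cox proportional hazards on a discrete session grid.

The partial likelihood uses the Breslow tie approximation (one shared
risk-set denominator per session), which is the natural choice for
session-grid data where ties are massive, and is normalized by n so the
penalty weight lambda is comparable between samples of equal size (in
particular between a full sample and its bootstrap pseudosamples).

Fitting routes:

* ``fit_coxph`` — unpenalized Newton-Raphson with step-halving.
* ``fit_cox_lasso`` — cyclic coordinate descent on an iteratively
  reweighted quadratic approximation, with soft-threshold updates; the
  penalized objective is nonincreasing across outer iterations.
* ``lambda_path`` — warm-started fits along a log-spaced penalty path
  from ``lambda_max`` (the smallest penalty with an all-zero solution)
  downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _coxnet
from .cohort import N_SESSIONS

#: Convergence tolerance on the largest coefficient update (final fits).
DEFAULT_TOL = 1e-7

#: Newton-Raphson tolerance for the unpenalized fit.
NEWTON_TOL = 1e-8

MAX_OUTER = 500


@dataclass
class CoxFit:
    """One fitted coefficient vector with its penalty and diagnostics."""

    beta: np.ndarray  # log hazard ratios, standardized predictor scale
    lam: float
    neg_log_pl: float  # penalized per-n objective at the solution
    n_iter: int
    converged: bool
    names: list[str] = field(default_factory=list)

    @property
    def active_set(self) -> list[str]:
        names = self.names or [f"x{j}" for j in range(len(self.beta))]
        return [names[j] for j in np.nonzero(self.beta)[0]]


def _as_arrays(X, event_times, event_indicators):
    X = np.ascontiguousarray(X, dtype=np.float64)
    t = np.ascontiguousarray(event_times, dtype=np.int64)
    d = np.ascontiguousarray(event_indicators, dtype=np.int64)
    if X.ndim != 2 or X.shape[0] != t.shape[0] or t.shape != d.shape:
        raise ValueError("X, event_times and event_indicators shapes disagree")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if t.min() < 1:
        raise ValueError("event times must be positive session indices")
    if not np.isin(d, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    return X, t, d


def _n_sessions(t) -> int:
    return max(int(t.max()), N_SESSIONS) if t.size else N_SESSIONS


def neg_log_partial_likelihood(
    beta, X, event_times, event_indicators
) -> tuple[float, np.ndarray]:
    """Per-n Breslow negative log partial likelihood and analytic gradient.

    With no events the partial likelihood is an empty product, so the
    value is 0 and the gradient vanishes for every beta.
    """
    X, t, d = _as_arrays(X, event_times, event_indicators)
    beta = np.ascontiguousarray(beta, dtype=np.float64)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta contains non-finite values")
    val, grad = _coxnet.negpl_grad(X, t, d, beta, _n_sessions(t))
    return float(val), grad


def fit_coxph(X, event_times, event_indicators, names=None) -> CoxFit:
    """Unpenalized Cox MLE by Newton-Raphson with step-halving.

    A monotone partial likelihood (risk-set separation) drives some
    coefficient beyond +-20 on the standardized scale; such fits are
    returned with ``converged=False`` rather than raising.
    """
    X, t, d = _as_arrays(X, event_times, event_indicators)
    if d.sum() == 0:
        raise ValueError("cannot fit a Cox model with zero events")
    beta, n_iter, converged, diverged = _coxnet.newton_cox(X, t, d, NEWTON_TOL, 200)
    val = _coxnet.negpl(X, t, d, beta, _n_sessions(t))
    return CoxFit(
        beta=beta,
        lam=0.0,
        neg_log_pl=float(val),
        n_iter=int(n_iter),
        converged=bool(converged and not diverged),
        names=list(names) if names else [],
    )


def lambda_max(X, event_times, event_indicators) -> float:
    """Smallest penalty at which the LASSO solution is identically zero.

    Equals the sup-norm of the gradient of the per-n negative log partial
    likelihood at beta = 0 (the KKT boundary).
    """
    X, t, d = _as_arrays(X, event_times, event_indicators)
    _, grad = _coxnet.negpl_grad(
        X, t, d, np.zeros(X.shape[1]), _n_sessions(t)
    )
    return float(np.abs(grad).max())


def fit_cox_lasso(
    X,
    event_times,
    event_indicators,
    lam: float,
    beta_init=None,
    tol: float = DEFAULT_TOL,
    names=None,
) -> CoxFit:
    """L1-penalized fit at one penalty value by coordinate descent."""
    X, t, d = _as_arrays(X, event_times, event_indicators)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if d.sum() == 0:
        raise ValueError("cannot fit a Cox model with zero events")
    if beta_init is None:
        beta_init = np.zeros(X.shape[1])
    beta_init = np.ascontiguousarray(beta_init, dtype=np.float64)
    ns = _n_sessions(t)
    beta, n_iter, converged = _coxnet.cd_lasso(
        X, t, d, float(lam), beta_init, ns, tol, MAX_OUTER
    )
    beta[np.abs(beta) < 1e-12] = 0.0
    obj = _coxnet.negpl(X, t, d, beta, ns) + lam * np.abs(beta).sum()
    return CoxFit(
        beta=beta,
        lam=float(lam),
        neg_log_pl=float(obj),
        n_iter=int(n_iter),
        converged=bool(converged),
        names=list(names) if names else [],
    )


def make_lambda_seq(
    lam_max: float, n_lambda: int = 100, min_ratio: float = 0.01
) -> np.ndarray:
    """Log-spaced decreasing penalty sequence from lam_max down."""
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    return lam_max * np.logspace(0.0, np.log10(min_ratio), n_lambda)


def lambda_path(
    X,
    event_times,
    event_indicators,
    n_lambda: int = 100,
    min_ratio: float = 0.01,
    tol: float = DEFAULT_TOL,
    names=None,
) -> tuple[np.ndarray, list[CoxFit]]:
    """Warm-started LASSO fits along a decreasing penalty sequence.

    Returns (lambda_seq, fits); the first entry sits exactly at
    ``lambda_max`` and therefore has an empty active set.
    """
    X, t, d = _as_arrays(X, event_times, event_indicators)
    if d.sum() == 0:
        raise ValueError("cannot fit a Cox model with zero events")
    lams = make_lambda_seq(
        lambda_max(X, t, d), n_lambda=n_lambda, min_ratio=min_ratio
    )
    ns = _n_sessions(t)
    betas, iters, convs = _coxnet.path_fit(X, t, d, lams, ns, tol, MAX_OUTER)
    betas[np.abs(betas) < 1e-12] = 0.0
    fits = []
    for k, lam in enumerate(lams):
        obj = _coxnet.negpl(X, t, d, betas[k], ns) + lam * np.abs(betas[k]).sum()
        fits.append(
            CoxFit(
                beta=betas[k],
                lam=float(lam),
                neg_log_pl=float(obj),
                n_iter=int(iters[k]),
                converged=bool(convs[k]),
                names=list(names) if names else [],
            )
        )
    return lams, fits
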
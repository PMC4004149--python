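"""Numerical core: Breslow partial likelihood and L1 coordinate descent.

All functions here are numba-compiled and operate on plain arrays.  Event
times are integer session indices on a short discrete grid (1..n_sessions),
so risk-set sums are accumulated per session rather than per subject.  The
negative log partial likelihood is normalized by n throughout, which makes
the penalty weight comparable between the full sample and bootstrap
pseudosamples of the same size.

The public, validated API lives in :mod:`stabcox.cox`; nothing in this
module checks its inputs.
"""

import numpy as np
from numba import njit

# Coefficients beyond this magnitude on a standardized scale indicate a
# monotone partial likelihood (risk-set separation); flagged, not an error.
DIVERGENCE_BOUND = 20.0


@njit(cache=True)
def _session_sums(eta, times, events, n_sessions):
    """Per-session risk-set denominators and event counts.

    Returns (d_count, denom) where d_count[s-1] is the number of events at
    session s and denom[s-1] = sum of exp(eta_j) over subjects with
    times_j >= s (events counted before censoring, so subjects censored at
    a session remain in that session's risk set).
    """
    n = times.shape[0]
    d_count = np.zeros(n_sessions, dtype=np.float64)
    w_sum = np.zeros(n_sessions, dtype=np.float64)
    for i in range(n):
        s = times[i] - 1
        w_sum[s] += np.exp(eta[i])
        if events[i] == 1:
            d_count[s] += 1.0
    denom = np.empty(n_sessions, dtype=np.float64)
    acc = 0.0
    for s in range(n_sessions - 1, -1, -1):
        acc += w_sum[s]
        denom[s] = acc
    return d_count, denom


@njit(cache=True)
def negpl(X, times, events, beta, n_sessions):
    """Per-n Breslow negative log partial likelihood."""
    n, p = X.shape
    eta = X @ beta
    d_count, denom = _session_sums(eta, times, events, n_sessions)
    ll = 0.0
    for i in range(n):
        if events[i] == 1:
            ll += eta[i]
    for s in range(n_sessions):
        if d_count[s] > 0.0:
            ll -= d_count[s] * np.log(denom[s])
    return -ll / n


@njit(cache=True)
def negpl_grad(X, times, events, beta, n_sessions):
    """Per-n negative log partial likelihood and its analytic gradient."""
    n, p = X.shape
    eta = X @ beta
    d_count, denom = _session_sums(eta, times, events, n_sessions)
    # weighted covariate sums over risk sets, accumulated from the last
    # session backwards
    wx_sum = np.zeros((n_sessions, p), dtype=np.float64)
    for i in range(n):
        s = times[i] - 1
        w = np.exp(eta[i])
        for j in range(p):
            wx_sum[s, j] += w * X[i, j]
    for s in range(n_sessions - 2, -1, -1):
        for j in range(p):
            wx_sum[s, j] += wx_sum[s + 1, j]
    ll = 0.0
    grad = np.zeros(p, dtype=np.float64)
    for i in range(n):
        if events[i] == 1:
            ll += eta[i]
            for j in range(p):
                grad[j] += X[i, j]
    for s in range(n_sessions):
        if d_count[s] > 0.0:
            ll -= d_count[s] * np.log(denom[s])
            for j in range(p):
                grad[j] -= d_count[s] * wx_sum[s, j] / denom[s]
    return -ll / n, -grad / n


@njit(cache=True)
def negpl_batch(X, times, events, betas, n_sessions):
    """Unnormalized negative log partial likelihood for each row of betas.

    Used by cross-validation, where fold contributions are differences of
    unnormalized (sum-form) log partial likelihoods.
    """
    m = betas.shape[0]
    n = X.shape[0]
    out = np.empty(m, dtype=np.float64)
    for k in range(m):
        out[k] = negpl(X, times, events, betas[k], n_sessions) * n
    return out


@njit(cache=True)
def _eta_score_hess(eta, times, events, n_sessions):
    """Per-subject score u_i and diagonal Hessian d_i of the unnormalized
    log partial likelihood with respect to eta."""
    n = times.shape[0]
    d_count, denom = _session_sums(eta, times, events, n_sessions)
    # cumulative hazard increments: A_s = sum_{r<=s} d_r/denom_r and the
    # squared version B_s used by the diagonal Hessian
    A = np.zeros(n_sessions, dtype=np.float64)
    B = np.zeros(n_sessions, dtype=np.float64)
    accA = 0.0
    accB = 0.0
    for s in range(n_sessions):
        if d_count[s] > 0.0:
            accA += d_count[s] / denom[s]
            accB += d_count[s] / (denom[s] * denom[s])
        A[s] = accA
        B[s] = accB
    u = np.empty(n, dtype=np.float64)
    h = np.empty(n, dtype=np.float64)
    for i in range(n):
        s = times[i] - 1
        w = np.exp(eta[i])
        u[i] = (1.0 if events[i] == 1 else 0.0) - w * A[s]
        h[i] = w * A[s] - w * w * B[s]
        if h[i] < 1e-9:
            h[i] = 1e-9
    return u, h


@njit(cache=True)
def cd_lasso(X, times, events, lam, beta_init, n_sessions, tol, max_outer):
    """Cyclic coordinate descent on the IRLS quadratic approximation.

    Outer loop: quadratic (weighted least squares) approximation of the
    per-n Breslow negative log partial likelihood at the current beta,
    with per-subject weights from the diagonal of the Hessian.  Inner
    loop: soft-threshold coordinate updates until the largest coefficient
    move is below tol.  Step-halving on the outer update keeps the
    penalized objective nonincreasing.

    Returns (beta, n_outer, converged).
    """
    n, p = X.shape
    beta = beta_init.copy()
    xsq = np.empty(p, dtype=np.float64)
    obj_old = negpl(X, times, events, beta, n_sessions)
    for j in range(p):
        obj_old += lam * abs(beta[j])
    converged = False
    it = 0
    for outer in range(max_outer):
        it = outer + 1
        eta = X @ beta
        u, h = _eta_score_hess(eta, times, events, n_sessions)
        # working response z_i = eta_i + u_i/h_i; solve the penalized WLS
        # problem min (1/2n) sum h_i (z_i - x_i b)^2 + lam |b|_1
        r = u / h  # residual z - eta at the expansion point
        for j in range(p):
            acc = 0.0
            for i in range(n):
                acc += h[i] * X[i, j] * X[i, j]
            xsq[j] = acc / n
        beta_new = beta.copy()
        for sweep in range(1000):
            max_move = 0.0
            for j in range(p):
                if xsq[j] <= 0.0:
                    continue
                gj = 0.0
                for i in range(n):
                    gj += h[i] * X[i, j] * r[i]
                gj = gj / n + xsq[j] * beta_new[j]
                if gj > lam:
                    bj = (gj - lam) / xsq[j]
                elif gj < -lam:
                    bj = (gj + lam) / xsq[j]
                else:
                    bj = 0.0
                move = bj - beta_new[j]
                if move != 0.0:
                    for i in range(n):
                        r[i] -= move * X[i, j]
                    beta_new[j] = bj
                    if abs(move) > max_move:
                        max_move = abs(move)
            if max_move < tol:
                break
        # step-halving line search on the outer move
        step = 1.0
        delta = beta_new - beta
        outer_move = 0.0
        for j in range(p):
            if abs(delta[j]) > outer_move:
                outer_move = abs(delta[j])
        improved = False
        for half in range(30):
            cand = beta + step * delta
            obj = negpl(X, times, events, cand, n_sessions)
            for j in range(p):
                obj += lam * abs(cand[j])
            if obj <= obj_old + 1e-14:
                beta = cand
                obj_old = obj
                improved = True
                break
            step *= 0.5
        if not improved:
            # no improving step: already at a stationary point
            converged = True
            break
        if outer_move * step < tol:
            converged = True
            break
    return beta, it, converged


@njit(cache=True)
def newton_cox(X, times, events, tol, max_iter):
    """Unpenalized Newton-Raphson fit with step-halving.

    Returns (beta, n_iter, converged, diverged).  diverged is set when any
    coefficient magnitude exceeds DIVERGENCE_BOUND, the signature of a
    monotone partial likelihood.
    """
    n, p = X.shape
    n_sessions = int(times.max())
    beta = np.zeros(p, dtype=np.float64)
    obj_old, grad = negpl_grad(X, times, events, beta, n_sessions)
    converged = False
    diverged = False
    it = 0
    for outer in range(max_iter):
        it = outer + 1
        eta = X @ beta
        d_count, denom = _session_sums(eta, times, events, n_sessions)
        # full Hessian of the per-n neg log PL (Breslow)
        H = np.zeros((p, p), dtype=np.float64)
        wx = np.zeros((n_sessions, p), dtype=np.float64)
        wxx = np.zeros((n_sessions, p, p), dtype=np.float64)
        for i in range(n):
            s = times[i] - 1
            w = np.exp(eta[i])
            for j in range(p):
                wx[s, j] += w * X[i, j]
                for k in range(p):
                    wxx[s, j, k] += w * X[i, j] * X[i, k]
        for s in range(n_sessions - 2, -1, -1):
            for j in range(p):
                wx[s, j] += wx[s + 1, j]
                for k in range(p):
                    wxx[s, j, k] += wxx[s + 1, j, k]
        for s in range(n_sessions):
            if d_count[s] > 0.0:
                for j in range(p):
                    for k in range(p):
                        H[j, k] += d_count[s] * (
                            wxx[s, j, k] / denom[s]
                            - wx[s, j] * wx[s, k] / (denom[s] * denom[s])
                        )
        H /= n
        _, grad = negpl_grad(X, times, events, beta, n_sessions)
        # ridge jitter for singular Hessians
        for j in range(p):
            H[j, j] += 1e-10
        step_dir = np.linalg.solve(H, -grad)
        step = 1.0
        improved = False
        for half in range(40):
            cand = beta + step * step_dir
            obj = negpl(X, times, events, cand, n_sessions)
            if obj <= obj_old + 1e-14:
                improved = True
                break
            step *= 0.5
        if not improved:
            converged = True
            break
        move = 0.0
        for j in range(p):
            if abs(step * step_dir[j]) > move:
                move = abs(step * step_dir[j])
        beta = beta + step * step_dir
        obj_old = obj
        for j in range(p):
            if abs(beta[j]) > DIVERGENCE_BOUND:
                diverged = True
        if diverged:
            break
        if move < tol:
            converged = True
            break
    return beta, it, converged, diverged


@njit(cache=True)
def path_fit(X, times, events, lambdas, n_sessions, tol, max_outer):
    """Warm-started coordinate-descent fits along a decreasing lambda path.

    Returns (betas, n_iters, convergeds) with one row per lambda.
    """
    m = lambdas.shape[0]
    p = X.shape[1]
    betas = np.zeros((m, p), dtype=np.float64)
    iters = np.zeros(m, dtype=np.int64)
    convs = np.zeros(m, dtype=np.bool_)
    beta = np.zeros(p, dtype=np.float64)
    for k in range(m):
        beta, it, conv = cd_lasso(
            X, times, events, lambdas[k], beta, n_sessions, tol, max_outer
        )
        betas[k] = beta
        iters[k] = it
        convs[k] = conv
    return betas, iters, convs
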
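"""Coordinate-descent solver for L1-penalized logistic regression.

Minimizes the penalized negative log-likelihood

    f(beta, b) = sum_i [log(1 + exp(z_i)) - y_i z_i] + lam * sum_j |beta_j|,
    z = X beta + b,

with an unpenalized intercept, by iteratively reweighted least squares:
each outer step builds the local quadratic (Newton) approximation and
solves the penalized weighted least-squares problem by cyclic coordinate
descent with soft thresholding. A step-halving safeguard makes the outer
objective sequence non-increasing. Exact zeros are produced, and at
lam >= lam_max = max_j |X_j'(y - ybar)| the all-zero solution is an exact
fixed point.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_WMIN = 1e-5  # lower clip for IRLS weights (glmnet convention)


@njit(cache=True)
def _objective(X, y, beta, b, lam):
    """Penalized negative log-likelihood (the minimized objective)."""
    n, p = X.shape
    f = 0.0
    for i in range(n):
        z = b
        for j in range(p):
            z += X[i, j] * beta[j]
        if z > 0.0:  # overflow-safe log(1+exp(z)) - y z
            f += z + np.log1p(np.exp(-z)) - y[i] * z
        else:
            f += np.log1p(np.exp(z)) - y[i] * z
    pen = 0.0
    for j in range(p):
        pen += abs(beta[j])
    return f + lam * pen


@njit(cache=True)
def _pls_logistic(X, y, lam, beta, b_arr, max_outer, tol_obj, inner_tol,
                  max_inner, trace):
    """In-place IRLS/coordinate-descent fit. Returns (n_outer, converged).

    ``trace`` (if non-empty) receives the objective after each outer step.
    """
    n, p = X.shape
    b = b_arr[0]
    z = np.empty(n)
    for i in range(n):
        zi = b
        for j in range(p):
            zi += X[i, j] * beta[j]
        z[i] = zi
    obj = _objective(X, y, beta, b, lam)
    w = np.empty(n)
    r = np.empty(n)       # working residual: (working response) - z
    beta_new = np.empty(p)
    n_outer = 0
    converged = False
    for it in range(max_outer):
        n_outer = it + 1
        # Newton weights and working residual at the current iterate
        for i in range(n):
            pr = 1.0 / (1.0 + np.exp(-z[i]))
            wi = pr * (1.0 - pr)
            if wi < _WMIN:
                wi = _WMIN
            w[i] = wi
            r[i] = (y[i] - pr) / wi
        H = np.empty(p)
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += w[i] * X[i, j] * X[i, j]
            H[j] = s
        Hb = 0.0
        for i in range(n):
            Hb += w[i]
        for j in range(p):
            beta_new[j] = beta[j]
        db_total = 0.0
        # inner CD on the penalized weighted least-squares subproblem;
        # full passes alternate with cheap active-set-only passes
        inner_iter = 0
        active_only = False
        while inner_iter < max_inner:
            inner_iter += 1
            max_step = 0.0
            gb = 0.0
            for i in range(n):
                gb += w[i] * r[i]
            db = gb / Hb
            if db != 0.0:
                db_total += db
                for i in range(n):
                    r[i] -= db
                if abs(db) > max_step:
                    max_step = abs(db)
            for j in range(p):
                if H[j] <= 0.0 or (active_only and beta_new[j] == 0.0):
                    continue
                g = 0.0
                for i in range(n):
                    g += w[i] * X[i, j] * r[i]
                u = beta_new[j] * H[j] + g
                # tolerance absorbs summation-order noise at lam == lam_max
                lam_tol = lam + 1e-12 * (1.0 + lam)
                if u > lam_tol:
                    nb = (u - lam) / H[j]
                elif u < -lam_tol:
                    nb = (u + lam) / H[j]
                else:
                    nb = 0.0
                d = nb - beta_new[j]
                if d != 0.0:
                    beta_new[j] = nb
                    for i in range(n):
                        r[i] -= d * X[i, j]
                    if abs(d) > max_step:
                        max_step = abs(d)
            if max_step < inner_tol:
                if active_only:
                    active_only = False  # verify with a full pass
                else:
                    break
            else:
                active_only = True
        # step-halving safeguard: never let the true objective increase
        t = 1.0
        cand = np.empty(p)
        for _ in range(40):
            cand_b = b + t * db_total
            for j in range(p):
                cand[j] = beta[j] + t * (beta_new[j] - beta[j])
            cand_obj = _objective(X, y, cand, cand_b, lam)
            if cand_obj <= obj + 1e-12:
                for j in range(p):
                    beta[j] = cand[j]
                b = cand_b
                new_obj = cand_obj
                break
            t *= 0.5
        else:
            new_obj = obj  # no acceptable step: we are at a stationary point
        for i in range(n):
            zi = b
            for j in range(p):
                zi += X[i, j] * beta[j]
            z[i] = zi
        if trace.shape[0] >= n_outer:
            trace[it] = new_obj
        if obj - new_obj < tol_obj:
            obj = new_obj
            converged = True
            break
        obj = new_obj
    b_arr[0] = b
    return n_outer, converged


@njit(cache=True)
def _pls_path(X, y, lambdas, max_outer, tol_obj, inner_tol, max_inner):
    """Warm-started fits along a descending lambda path.

    Returns (betas [L x p], intercepts [L], converged flags [L]).
    """
    n, p = X.shape
    L = lambdas.shape[0]
    betas = np.zeros((L, p))
    intercepts = np.zeros(L)
    flags = np.zeros(L, dtype=np.bool_)
    beta = np.zeros(p)
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    b_arr = np.empty(1)
    b_arr[0] = np.log(ybar / (1.0 - ybar))
    trace = np.empty(0)
    for li in range(L):
        _, conv = _pls_logistic(X, y, lambdas[li], beta, b_arr, max_outer,
                                tol_obj, inner_tol, max_inner, trace)
        for j in range(p):
            betas[li, j] = beta[j]
        intercepts[li] = b_arr[0]
        flags[li] = conv
    return betas, intercepts, flags


def warmup() -> None:
    """Trigger JIT compilation on a tiny problem (no-op afterwards)."""
    X = np.array([[0.1, -0.2], [-0.3, 0.4], [0.5, 0.1], [-0.2, -0.4]])
    y = np.array([0.0, 1.0, 1.0, 0.0])
    _pls_path(X, y, np.array([1.0, 0.1]), 10, 1e-8, 1e-6, 100)
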
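"""Brute-force reference implementations used only by the tests.

Everything here enumerates risk sets with explicit Python loops and stays
deliberately independent of the vectorized code paths it checks.
"""

import numpy as np


def loop_neg_log_pl(data, beta, weights, risk_set_mode):
    """Explicit double-loop weighted negative log partial likelihood."""
    beta = np.atleast_1d(np.asarray(beta, float))
    w = np.asarray(weights, float)
    n = data.n_subjects
    total = 0.0
    for i in range(n):
        if data.status[i] != 1 or w[i] <= 0:
            continue
        s = 0.0
        for j in range(n):
            if data.times[j] >= data.times[i]:
                wr = w[j] if risk_set_mode == "weighted" else 1.0
                s += wr * np.exp(beta @ data.covariates[j])
        total += w[i] * (beta @ data.covariates[i] - np.log(s))
    return -total / n


def fd_gradient(fun, beta, h=1e-6):
    """Central finite-difference gradient."""
    beta = np.asarray(beta, float)
    g = np.zeros_like(beta)
    for k in range(beta.size):
        e = np.zeros_like(beta)
        e[k] = h
        g[k] = (fun(beta + e) - fun(beta - e)) / (2 * h)
    return g


def fd_hessian(grad_fun, beta, h=1e-6):
    """Central finite differences of an analytic gradient."""
    beta = np.asarray(beta, float)
    p = beta.size
    H = np.zeros((p, p))
    for k in range(p):
        e = np.zeros(p)
        e[k] = h
        H[:, k] = (grad_fun(beta + e) - grad_fun(beta - e)) / (2 * h)
    return 0.5 * (H + H.T)


def loop_sandwich(data, beta, weights, risk_set_mode):
    """Explicit-loop score-residual sandwich covariance.

    Residual for subject i: Delta_i (X_i - xbar_i) minus
    exp(beta'X_i) * sum over events k with Y_k <= Y_i of
    w_k (X_i - xbar_k) / S_k; bread is the per-unit-weight information
    (finite differences of the loop objective), meat is
    sum w_i^2 U_i U_i' / (sum w)^2.
    """
    beta = np.atleast_1d(np.asarray(beta, float))
    w = np.asarray(weights, float)
    if risk_set_mode == "weighted":
        keep = w > 0
        times = data.times[keep]
        status = np.asarray(data.status[keep], float)
        X = data.covariates[keep]
        w_out = w[keep]
        w_risk = w_out
    else:
        times, status, X = data.times, np.asarray(data.status, float), data.covariates
        w_out = w
        w_risk = np.ones_like(w)
    m = times.shape[0]
    p = X.shape[1]

    S = np.zeros(m)
    xbar = np.zeros((m, p))
    for i in range(m):
        num = np.zeros(p)
        for j in range(m):
            if times[j] >= times[i]:
                a = w_risk[j] * np.exp(beta @ X[j])
                S[i] += a
                num += a * X[j]
        xbar[i] = num / S[i]

    U = np.zeros((m, p))
    for i in range(m):
        if status[i] == 1:
            U[i] += X[i] - xbar[i]
        for k in range(m):
            if status[k] == 1 and w_out[k] > 0 and times[k] <= times[i]:
                U[i] -= (
                    np.exp(beta @ X[i]) * w_out[k] * (X[i] - xbar[k]) / S[k]
                )

    W = w_out.sum()
    G = np.zeros((p, p))
    for i in range(m):
        G += w_out[i] ** 2 * np.outer(U[i], U[i])
    G /= W**2

    def obj(b):
        return loop_neg_log_pl(data, b, w, risk_set_mode)

    def grad(b):
        return fd_gradient(obj, b, h=1e-5)

    H = fd_hessian(grad, beta, h=1e-4) * (data.n_subjects / W)
    Hinv = np.linalg.inv(H)
    return Hinv @ G @ Hinv
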
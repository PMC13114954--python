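"""Weighted Cox partial likelihood, derivatives, and a Newton-type fitter.

The objective is the weighted negative log partial likelihood

    l(beta) = -(1/n) sum_i omega_i Delta_i [beta'X_i - log S_i(beta)],

where the risk-set sum ``S_i`` runs over ``{j : Y_j >= Y_i}`` (Breslow
convention, ties share a risk set) and is either itself omega-weighted
(``risk_set_mode="weighted"``, the default) or unweighted over the full sample
(``"full"``).  With all weights equal to one both modes coincide and l is the
ordinary full-data objective, so the full-data maximum partial likelihood
estimator is the all-ones special case of :func:`fit_weighted_cox`.

The weighted mode is the computational point of perturbation subsampling: only
subjects with omega_i > 0 are touched, so a fit on a subsample of expected
size r costs O(r log r) per Newton step regardless of n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import SurvivalDataset

RISK_SET_MODES = ("weighted", "full")

#: Armijo sufficient-decrease constant for the step-halving line search.
_ARMIJO = 1e-4
_MIN_STEP = 2.0**-30


class DegenerateRiskSetError(ValueError):
    """An event with positive weight has a non-positive risk-set sum."""


class SeparationError(RuntimeError):
    """Monotone partial likelihood: no finite minimizer (separation)."""


@dataclass
class CoxFit:
    """Result of a weighted partial-likelihood fit.

    Attributes
    ----------
    beta
        Estimated coefficient vector.
    covariance
        Optional ``(p, p)`` covariance estimate (filled by the inference
        module; ``None`` straight out of the optimizer).
    converged
        True iff the gradient max-norm reached ``tol``.
    iterations
        Newton iterations performed.
    final_gradient_norm
        Max-norm of the gradient at ``beta``.
    objective
        Objective value at ``beta``.
    """

    beta: np.ndarray
    covariance: np.ndarray | None
    converged: bool
    iterations: int
    final_gradient_norm: float
    objective: float


@dataclass
class _Prepared:
    """Time-sorted view of the rows that can contribute to the objective."""

    times: np.ndarray      # ascending
    status: np.ndarray
    X: np.ndarray
    w_out: np.ndarray      # outer-sum weights (omega)
    w_risk: np.ndarray     # risk-set weights (omega or all-ones)
    first: np.ndarray      # first index of each tie group (risk-set start)
    n_scale: int           # the full-sample n in the 1/n factor
    p: int


def _check_weights(data: SurvivalDataset, weights) -> np.ndarray:
    if weights is None:
        return np.ones(data.n_subjects)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (data.n_subjects,):
        raise ValueError("weights must be a length-n vector")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be nonnegative and finite")
    return w


def _prepare(
    data: SurvivalDataset, weights, risk_set_mode: str
) -> _Prepared:
    if risk_set_mode not in RISK_SET_MODES:
        raise ValueError(f"risk_set_mode must be one of {RISK_SET_MODES}")
    w = _check_weights(data, weights)
    if risk_set_mode == "weighted":
        # zero-weight rows contribute to neither sum; drop them up front
        active = w > 0
        times = data.times[active]
        status = np.asarray(data.status[active], dtype=np.float64)
        X = data.covariates[active]
        w_out = w[active]
        w_risk = w_out
    else:
        times = data.times
        status = np.asarray(data.status, dtype=np.float64)
        X = data.covariates
        w_out = w
        w_risk = np.ones_like(w)
    order = np.argsort(times, kind="stable")
    times = times[order]
    first = np.searchsorted(times, times, side="left")
    return _Prepared(
        times=times,
        status=status[order],
        X=np.ascontiguousarray(X[order]),
        w_out=w_out[order],
        w_risk=w_risk[order],
        first=first,
        n_scale=data.n_subjects,
        p=data.n_covariates,
    )


def _evaluate(prep: _Prepared, beta: np.ndarray, order: int):
    """Objective (order>=0), gradient (order>=1), Hessian (order==2).

    Risk-set sums are reverse cumulative sums over the ascending time order;
    exponentials are shifted by max(beta'X) for overflow safety.
    """
    n = prep.n_scale
    p = prep.p
    value = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    if prep.times.shape[0] == 0:
        return value, grad, hess

    lin = prep.X @ beta
    shift = float(np.max(lin))
    a = prep.w_risk * np.exp(lin - shift)
    S = np.cumsum(a[::-1])[::-1][prep.first]  # S_i = sum_{Y_j >= Y_i} a_j

    ev = (prep.status > 0) & (prep.w_out > 0)
    if not np.any(ev):
        return value, grad, hess
    if np.any(S[ev] <= 0.0):
        bad = prep.times[ev][np.asarray(S[ev] <= 0.0).nonzero()[0][0]]
        raise DegenerateRiskSetError(
            f"non-positive risk-set sum at event time {bad!r}"
        )

    w_ev = prep.w_out[ev]
    value = -float(
        np.sum(w_ev * (lin[ev] - (np.log(S[ev]) + shift)))
    ) / n
    if order < 1:
        return value, grad, hess

    M = np.cumsum((a[:, None] * prep.X)[::-1], axis=0)[::-1][prep.first]
    xbar = M[ev] / S[ev, None]
    grad = -(w_ev[:, None] * (prep.X[ev] - xbar)).sum(axis=0) / n
    if order < 2:
        return value, grad, hess

    outer = prep.X[:, :, None] * (a[:, None] * prep.X)[:, None, :]
    V = np.cumsum(outer[::-1], axis=0)[::-1][prep.first]
    hess = (
        w_ev[:, None, None]
        * (V[ev] / S[ev, None, None] - xbar[:, :, None] * xbar[:, None, :])
    ).sum(axis=0) / n
    hess = 0.5 * (hess + hess.T)
    return value, grad, hess


def neg_log_partial_likelihood(
    data: SurvivalDataset,
    beta,
    weights=None,
    risk_set_mode: str = "weighted",
) -> float:
    """Weighted negative log partial likelihood at ``beta``."""
    beta = np.atleast_1d(np.asarray(beta, dtype=np.float64))
    prep = _prepare(data, weights, risk_set_mode)
    return _evaluate(prep, beta, order=0)[0]


def score(
    data: SurvivalDataset,
    beta,
    weights=None,
    risk_set_mode: str = "weighted",
) -> np.ndarray:
    """Analytic gradient of :func:`neg_log_partial_likelihood`."""
    beta = np.atleast_1d(np.asarray(beta, dtype=np.float64))
    prep = _prepare(data, weights, risk_set_mode)
    return _evaluate(prep, beta, order=1)[1]


def information(
    data: SurvivalDataset,
    beta,
    weights=None,
    risk_set_mode: str = "weighted",
) -> np.ndarray:
    """Hessian of the objective (symmetric PSD: the objective is convex)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=np.float64))
    prep = _prepare(data, weights, risk_set_mode)
    return _evaluate(prep, beta, order=2)[2]


def _newton_direction(hess: np.ndarray, grad: np.ndarray) -> np.ndarray:
    p = grad.shape[0]
    ridge = 0.0
    scale = max(float(np.trace(hess)) / p, 1e-12)
    for _ in range(8):
        try:
            d = np.linalg.solve(hess + ridge * np.eye(p), -grad)
        except np.linalg.LinAlgError:
            d = None
        if d is not None and np.dot(d, grad) < 0:
            return d
        ridge = scale * 1e-8 if ridge == 0.0 else ridge * 100.0
    return -grad  # steepest descent fallback


def fit_weighted_cox(
    data: SurvivalDataset,
    weights=None,
    risk_set_mode: str = "weighted",
    init=None,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_bound: float = 50.0,
) -> CoxFit:
    """Minimize the weighted negative log partial likelihood.

    Newton iterations with Armijo step-halving from ``init`` (zero vector by
    default) until the gradient max-norm drops below ``tol`` or ``max_iter``
    is reached.  Non-convergence is flagged on the returned fit, not raised.

    Raises
    ------
    SeparationError
        If the iterates leave the box ``|beta|_inf <= separation_bound``
        while the gradient is still above ``tol`` — the signature of a
        monotone partial likelihood with no finite minimizer.
    ValueError
        If no event has positive weight.
    """
    w = _check_weights(data, weights)
    if not np.any((np.asarray(data.status) == 1) & (w > 0)):
        raise ValueError("need at least one event with positive weight")
    prep = _prepare(data, w, risk_set_mode)
    p = prep.p
    beta = (
        np.zeros(p)
        if init is None
        else np.array(init, dtype=np.float64, copy=True)
    )
    if beta.shape != (p,):
        raise ValueError("init must be a p-vector")

    value, grad, hess = _evaluate(prep, beta, order=2)
    gnorm = float(np.max(np.abs(grad))) if p else 0.0
    converged = gnorm <= tol
    iterations = 0
    while not converged and iterations < max_iter:
        d = _newton_direction(hess, grad)
        slope = float(np.dot(grad, d))
        step = 1.0
        while step >= _MIN_STEP:
            trial = beta + step * d
            trial_value = _evaluate(prep, trial, order=0)[0]
            if trial_value <= value + _ARMIJO * step * slope:
                break
            step *= 0.5
        else:  # no acceptable step: stop where we are
            break
        beta = beta + step * d
        value, grad, hess = _evaluate(prep, beta, order=2)
        gnorm = float(np.max(np.abs(grad)))
        iterations += 1
        if gnorm <= tol:
            converged = True
        elif float(np.max(np.abs(beta))) > separation_bound:
            raise SeparationError(
                "estimate escaped |beta|_inf <= "
                f"{separation_bound} with gradient max-norm {gnorm:.3e}; "
                "the partial likelihood appears monotone (separation)"
            )
    return CoxFit(
        beta=beta,
        covariance=None,
        converged=converged,
        iterations=iterations,
        final_gradient_norm=gnorm,
        objective=value,
    )
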
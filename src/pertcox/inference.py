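"""Variance estimation and Wald intervals for the subsampling estimator.

The default covariance is a score-residual sandwich

    Sigma = H^{-1} G H^{-1},
    H = weighted information (per-subject average) at beta,
    G = n^{-2} sum_i omega_i^2 U_i U_i',

where U_i is the Cox score residual of subject i: the event term
Delta_i (X_i - Xbar(Y_i)) minus the cumulated risk-weighted mean-covariate
terms exp(beta'X_i) sum_{events k: Y_k <= Y_i} omega_k / S_k (X_i - Xbar(Y_k)).
With all weights one this is the standard robust (score-residual) covariance
of the full-data estimator.  The omega^2 weighting in G captures both the
sampling variability of the data and the extra noise injected by the
perturbation weights: with omega = eta * delta, E[omega^2] = 1 + 1/pi_n, so
the sandwich scales like 1/r rather than 1/n, matching the dispersion of the
subsample estimator.

A replicate-dispersion estimator (empirical covariance of the M aggregated
replicates, divided by M) is provided as a labelled diagnostic; it measures
only the perturbation-noise component, not the full sampling variance, and is
never the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cox import _evaluate, _prepare
from .datasets import SurvivalDataset
from .perturb import AggregatedFit


class SingularInformationError(np.linalg.LinAlgError):
    """The weighted information matrix is numerically singular."""


@dataclass(frozen=True)
class VarianceEstimate:
    """Covariance matrix, its implied standard errors, and the method label."""

    covariance: np.ndarray
    method: str

    @property
    def ese(self) -> np.ndarray:
        """Per-coefficient standard errors (sqrt of the diagonal)."""
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))


def weighted_information(
    data: SurvivalDataset,
    beta,
    weights=None,
    risk_set_mode: str = "weighted",
) -> np.ndarray:
    """Per-unit-weight average information H-tilde at ``beta``.

    The objective's Hessian rescaled by n / sum(omega): an average over
    weight mass rather than row count, so duplicating every subject while
    halving its weight leaves it unchanged.  With all weights one it equals
    the plain :func:`pertcox.cox.information`.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=np.float64))
    prep = _prepare(data, weights, risk_set_mode)
    total = float(np.sum(prep.w_out))
    if total <= 0:
        raise ValueError("total weight must be positive")
    _, _, H = _evaluate(prep, beta, order=2)
    return H * (prep.n_scale / total)


def sandwich_covariance(
    data: SurvivalDataset,
    beta,
    weights=None,
    risk_set_mode: str = "weighted",
) -> VarianceEstimate:
    """Score-residual sandwich covariance at a converged estimate ``beta``."""
    beta = np.atleast_1d(np.asarray(beta, dtype=np.float64))
    prep = _prepare(data, weights, risk_set_mode)
    n = prep.n_scale
    p = prep.p
    total = float(np.sum(prep.w_out))
    if total <= 0:
        raise ValueError("total weight must be positive")
    _, _, H = _evaluate(prep, beta, order=2)
    H = H * (n / total)  # per-unit-weight average (see weighted_information)

    cond = np.linalg.cond(H)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularInformationError(
            f"weighted information is numerically singular (cond={cond:.3e})"
        )

    # score residuals on the rows that can contribute (omega > 0 in weighted
    # mode), in ascending time order
    lin = prep.X @ beta
    shift = float(np.max(lin)) if lin.size else 0.0
    elin = np.exp(lin - shift)
    a = prep.w_risk * elin
    S = np.cumsum(a[::-1])[::-1][prep.first]
    M = np.cumsum((a[:, None] * prep.X)[::-1], axis=0)[::-1][prep.first]
    xbar = M / S[:, None]

    # forward (time-ascending) cumulations over events, ties inclusive:
    # A_i = sum_{events k: Y_k <= Y_i} omega_k / S_k
    # B_i = sum_{events k: Y_k <= Y_i} omega_k xbar_k / S_k
    last = np.searchsorted(prep.times, prep.times, side="right") - 1
    ev_w = prep.w_out * prep.status  # omega_k Delta_k
    A = np.cumsum(ev_w / S)[last]
    B = np.cumsum(ev_w[:, None] * xbar / S[:, None], axis=0)[last]

    U = prep.status[:, None] * (prep.X - xbar) - elin[:, None] * (
        prep.X * A[:, None] - B
    )
    wU = prep.w_out[:, None] * U
    G = (wU.T @ wU) / total**2

    Hinv_G = np.linalg.solve(H, G)
    cov = np.linalg.solve(H, Hinv_G.T).T
    cov = 0.5 * (cov + cov.T)
    assert cov.shape == (p, p)
    return VarianceEstimate(covariance=cov, method="sandwich")


def replicate_covariance(fits: AggregatedFit) -> VarianceEstimate:
    """Empirical dispersion of the M replicate estimates, divided by M.

    Diagnostic only: estimates the perturbation-noise component of the
    aggregated estimator's variance, not the full sampling variance.
    """
    betas = np.asarray(
        [f.beta for f in fits.per_replicate if f.converged], dtype=np.float64
    )
    if betas.shape[0] < 2:
        raise ValueError("replicate covariance needs M >= 2 converged fits")
    cov = np.cov(betas, rowvar=False, ddof=1) / betas.shape[0]
    cov = np.atleast_2d(cov)
    return VarianceEstimate(covariance=cov, method="replicate")


def wald_interval(
    beta, variance: VarianceEstimate, level: float = 0.95
) -> np.ndarray:
    """Per-coordinate Wald intervals beta_k +- z_{(1+level)/2} * ese_k.

    Returns an ``(p, 2)`` array of (lower, upper) pairs.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    beta = np.atleast_1d(np.asarray(beta, dtype=np.float64))
    z = stats.norm.ppf(0.5 * (1.0 + level))
    half = z * variance.ese
    return np.column_stack([beta - half, beta + half])
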
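"""Synthetic right-censored survival data with censoring-rate calibration.

The generator emulates a standard large-n Cox simulation design: p = 5
covariates with AR(1)-type covariance Sigma_ij = 0.5^|i-j|, drawn either from
a multivariate normal ("normal") or a heavy-tailed multivariate t with 10
degrees of freedom rescaled to the same covariance ("t10"); event times from
a Cox model with constant baseline hazard lambda0 (exponential baseline, the
standard choice when the baseline is otherwise unspecified); censoring times
Uniform(0, U) with U calibrated by Monte-Carlo bisection so the censoring
rate hits a target (e.g. 20% or 60%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .datasets import SurvivalDataset

COVARIATE_CASES = ("normal", "t10")

#: Default true coefficient vector.
DEFAULT_BETA0 = (-1.0, -0.5, 0.0, 0.5, 1.0)


class CalibrationError(RuntimeError):
    """The target censoring rate could not be bracketed in U."""


def ar1_covariance(p: int, rho: float = 0.5) -> np.ndarray:
    """Covariance matrix with entries rho^|i-j|."""
    idx = np.arange(p)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass(frozen=True)
class SimulationDesign:
    """One simulation scenario.

    Parameters
    ----------
    n
        Sample size.
    beta0
        True coefficient vector (default (-1, -0.5, 0, 0.5, 1)).
    covariate_case
        ``"normal"`` (Gaussian) or ``"t10"`` (multivariate t, 10 df, rescaled
        so its covariance matches the Gaussian case).
    baseline_rate
        Constant baseline hazard lambda0 (> 0).
    censor_target
        Target censoring rate in (0, 1).
    censor_bound
        Upper endpoint U of the Uniform(0, U) censoring law; ``None`` until
        resolved by :func:`calibrate_censoring`.
    """

    n: int
    beta0: tuple = DEFAULT_BETA0
    covariate_case: str = "normal"
    baseline_rate: float = 1.0
    censor_target: float = 0.2
    censor_bound: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.covariate_case not in COVARIATE_CASES:
            raise ValueError(f"covariate_case must be one of {COVARIATE_CASES}")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if not (0.0 < self.censor_target < 1.0):
            raise ValueError("censor_target must lie in (0, 1)")
        if self.censor_bound is not None and self.censor_bound <= 0:
            raise ValueError("censor_bound must be positive")
        object.__setattr__(self, "beta0", tuple(float(b) for b in self.beta0))

    @property
    def p(self) -> int:
        return len(self.beta0)

    @property
    def covariance(self) -> np.ndarray:
        return ar1_covariance(self.p)

    def with_censor_bound(self, U: float) -> "SimulationDesign":
        return replace(self, censor_bound=float(U))


def gen_covariates(
    n: int, design: SimulationDesign, rng: np.random.Generator
) -> np.ndarray:
    """Draw n covariate rows for the design's case.

    The t10 case is scaled by sqrt((nu-2)/nu) so its covariance equals the
    Gaussian-case Sigma (a raw t with dispersion Sigma has covariance
    Sigma * nu/(nu-2)).
    """
    sigma = design.covariance
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance matrix must be positive definite") from err
    z = rng.standard_normal((n, design.p)) @ chol.T
    if design.covariate_case == "normal":
        return z
    nu = 10.0
    w = rng.chisquare(nu, size=n) / nu
    t = z / np.sqrt(w)[:, None]
    return t * np.sqrt((nu - 2.0) / nu)


def gen_event_times(
    X: np.ndarray, beta0, baseline_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Event times T_i = -log(V_i) / (lambda0 * exp(beta0'X_i)), V ~ U(0,1).

    Inverse-transform sampling for the Cox model with constant baseline
    hazard lambda0: the integrated hazard lambda0 * exp(beta0'X) * T is
    standard exponential.
    """
    beta0 = np.asarray(beta0, dtype=np.float64)
    rate = baseline_rate * np.exp(X @ beta0)
    e = rng.exponential(1.0, size=X.shape[0])
    return np.maximum(e, np.finfo(np.float64).tiny) / rate


def calibrate_censoring(
    design: SimulationDesign,
    rng: np.random.Generator,
    mc_size: int = 100_000,
    tol: float = 0.005,
) -> tuple[float, float]:
    """Resolve the Uniform(0, U) bound hitting the target censoring rate.

    Draws one Monte-Carlo sample of event times and root-finds on U: given
    T_i, the probability the subject is censored (C_i < T_i with
    C_i ~ Uniform(0, U)) is min(T_i / U, 1), so the expected censoring rate
    at bound U is mean_i min(T_i / U, 1) — smooth and decreasing in U, which
    bisection/Brent solves to well within ``tol``.

    Returns ``(U, achieved_rate)`` where the achieved rate is evaluated on
    the same Monte-Carlo sample.
    """
    X = gen_covariates(mc_size, design, rng)
    T = gen_event_times(X, design.beta0, design.baseline_rate, rng)

    def rate(U: float) -> float:
        return float(np.mean(np.minimum(T / U, 1.0)))

    target = design.censor_target
    lo, hi = 1e-8, 1.0
    for _ in range(200):
        if rate(hi) < target:
            break
        hi *= 2.0
    else:
        raise CalibrationError("could not bracket the target censoring rate")
    U = optimize.brentq(lambda u: rate(u) - target, lo, hi, xtol=1e-10)
    achieved = rate(U)
    if abs(achieved - target) > tol:
        raise CalibrationError(
            f"calibration stalled at rate {achieved:.4f} for target {target}"
        )
    return float(U), achieved


def gen_dataset(
    design: SimulationDesign, rng: np.random.Generator
) -> SurvivalDataset:
    """Draw a full dataset (Y, Delta, X) under the design.

    Requires a resolved ``censor_bound``; T and C are independent given X,
    Y = min(T, C), Delta = I(T <= C).
    """
    if design.censor_bound is None:
        raise ValueError(
            "design.censor_bound is unresolved; run calibrate_censoring first"
        )
    X = gen_covariates(design.n, design, rng)
    T = gen_event_times(X, design.beta0, design.baseline_rate, rng)
    C = rng.uniform(0.0, design.censor_bound, size=design.n)
    C = np.maximum(C, np.finfo(np.float64).tiny)
    Y = np.minimum(T, C)
    delta = (T <= C).astype(np.int8)
    return SurvivalDataset(times=Y, status=delta, covariates=X)
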
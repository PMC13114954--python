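"""Bernoulli selection, perturbation weights, and the subsampling estimators.

A subsample of expected size r is drawn by keeping subject i when
delta_i ~ Bernoulli(pi_n), pi_n = r/n.  Independent nonnegative disturbances
eta_i with mean 1/pi_n are drawn from a known family, and the fit weights are
omega_i = eta_i * delta_i, so E[omega_i] = 1 and the weighted objective is
conditionally unbiased for the full-data one.  Repeating the draw M times and
averaging the M estimates gives the aggregated estimator.

Supported disturbance families (both have mean 1/pi_n):

- ``geometric``: number-of-trials Geometric(pi_n) on {1, 2, ...},
  variance (1 - pi_n) / pi_n^2;
- ``gamma``: Gamma(shape = 1/pi_n, scale = 1), variance 1/pi_n.

RNG stream order is fixed for reproducibility: within one subsample draw,
all n delta's are drawn first, then all n eta's; repeated-draw replicates
consume the stream in replicate-major order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cox import CoxFit, fit_weighted_cox
from .datasets import SurvivalDataset

logger = logging.getLogger(__name__)

FAMILIES = ("geometric", "gamma")


class ZeroEventSubsampleError(RuntimeError):
    """Two consecutive subsample draws contained no event."""


@dataclass(frozen=True)
class PerturbationScheme:
    """Perturbation family plus subsample-size bookkeeping.

    Parameters
    ----------
    family
        ``"geometric"`` or ``"gamma"``.
    n
        Full-sample size.
    r
        Target subsample size, r << n; the inclusion probability is
        ``pi_n = r / n``.
    """

    family: str
    n: int
    r: int

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if not (1 <= self.r <= self.n):
            raise ValueError("need 1 <= r <= n")

    @property
    def pi_n(self) -> float:
        return self.r / self.n

    @property
    def weight_variance(self) -> float:
        """Variance b_n^2 of the disturbance eta (mean is 1/pi_n)."""
        if self.family == "geometric":
            return (1.0 - self.pi_n) / self.pi_n**2
        return 1.0 / self.pi_n


@dataclass(frozen=True)
class WeightRealization:
    """One draw of selection indicators and disturbances.

    ``omega = eta * delta`` elementwise; ``r_star`` is the realized subsample
    size ``sum(delta)``.
    """

    delta: np.ndarray
    eta: np.ndarray
    omega: np.ndarray = field(init=False)
    r_star: int = field(init=False)

    def __post_init__(self) -> None:
        delta = np.asarray(self.delta)
        eta = np.asarray(self.eta, dtype=np.float64)
        if delta.shape != eta.shape or delta.ndim != 1:
            raise ValueError("delta and eta must be equal-length 1-d arrays")
        if np.any(eta < 0):
            raise ValueError("eta must be nonnegative")
        object.__setattr__(self, "delta", delta.astype(np.int8))
        object.__setattr__(self, "eta", eta)
        object.__setattr__(self, "omega", eta * (delta != 0))
        object.__setattr__(self, "r_star", int(np.count_nonzero(delta)))


@dataclass
class AggregatedFit:
    """M replicate fits and their coordinatewise-mean estimate beta_M."""

    per_replicate: list[CoxFit]
    beta_M: np.ndarray
    M: int
    realizations: list[WeightRealization] = field(default_factory=list)


def draw_selection(n: int, pi_n: float, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. Bernoulli(pi_n) selection indicators delta."""
    if not (0.0 < pi_n <= 1.0):
        raise ValueError("pi_n must lie in (0, 1]")
    return (rng.random(n) < pi_n).astype(np.int8)


def draw_perturbation(
    n: int, scheme: PerturbationScheme, rng: np.random.Generator
) -> np.ndarray:
    """n i.i.d. disturbances eta from the scheme's family (mean 1/pi_n)."""
    if scheme.family == "geometric":
        return rng.geometric(scheme.pi_n, size=n).astype(np.float64)
    return rng.gamma(shape=1.0 / scheme.pi_n, scale=1.0, size=n)


def _draw_realization(
    n: int, scheme: PerturbationScheme, rng: np.random.Generator
) -> WeightRealization:
    delta = draw_selection(n, scheme.pi_n, rng)
    eta = draw_perturbation(n, scheme, rng)
    return WeightRealization(delta=delta, eta=eta)


def perturb_subsample_fit(
    data: SurvivalDataset,
    scheme: PerturbationScheme,
    rng: np.random.Generator,
    risk_set_mode: str = "weighted",
    **fit_options,
) -> tuple[CoxFit, WeightRealization]:
    """One perturbation-subsampling estimate.

    Draws (delta, eta), forms omega, and minimizes the omega-weighted partial
    likelihood.  A subsample with no event is redrawn once (logged); if the
    redraw also has no event a :class:`ZeroEventSubsampleError` is raised —
    silent repeated redraws would bias small-r studies.
    """
    if scheme.n != data.n_subjects:
        raise ValueError("scheme.n must equal the dataset size")
    real = _draw_realization(data.n_subjects, scheme, rng)
    if not np.any((data.status == 1) & (real.omega > 0)):
        logger.warning(
            "subsample of size r*=%d contained no event; redrawing once",
            real.r_star,
        )
        real = _draw_realization(data.n_subjects, scheme, rng)
        if not np.any((data.status == 1) & (real.omega > 0)):
            raise ZeroEventSubsampleError(
                "two consecutive subsamples contained no event "
                f"(r={scheme.r}, n={scheme.n})"
            )
    fit = fit_weighted_cox(
        data, weights=real.omega, risk_set_mode=risk_set_mode, **fit_options
    )
    return fit, real


def repeated_perturb_fit(
    data: SurvivalDataset,
    scheme: PerturbationScheme,
    M: int,
    rng: np.random.Generator,
    risk_set_mode: str = "weighted",
    **fit_options,
) -> AggregatedFit:
    """M independent perturbation-subsampling fits, averaged coordinatewise.

    beta_M is the mean of the converged replicate estimates; replicates that
    fail to converge are excluded from the average (and an error is raised if
    none converge).
    """
    if M < 1:
        raise ValueError("M must be at least 1")
    fits = []
    reals = []
    for _ in range(M):
        fit, real = perturb_subsample_fit(
            data, scheme, rng, risk_set_mode=risk_set_mode, **fit_options
        )
        fits.append(fit)
        reals.append(real)
    good = [f.beta for f in fits if f.converged]
    if not good:
        raise RuntimeError("all replicate fits failed to converge")
    beta_M = np.mean(np.asarray(good), axis=0)
    return AggregatedFit(
        per_replicate=fits, beta_M=beta_M, M=M, realizations=reals
    )
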
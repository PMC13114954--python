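import numpy as np
import pytest

from pertcox import (
    PerturbationScheme,
    SimulationDesign,
    SurvivalDataset,
    run_replications,
)
from pertcox.simulate import calibrate_censoring, gen_dataset


@pytest.fixture
def toy4():
    """Four subjects, scalar covariate, mixed events, one tie in time."""
    return SurvivalDataset(
        times=np.array([2.0, 1.0, 3.0, 2.0]),
        status=np.array([1, 1, 0, 1]),
        covariates=np.array([[0.5], [-1.0], [2.0], [0.3]]),
    )


def random_dataset(rng, n, p, censor=0.3):
    """Small random right-censored instance for property sweeps."""
    X = rng.normal(size=(n, p))
    beta = rng.normal(scale=0.5, size=p)
    T = rng.exponential(1.0, n) / np.exp(X @ beta)
    C = rng.exponential(1.0 / max(censor, 1e-6), n) * T.mean() * 3
    Y = np.minimum(T, C)
    status = (T <= C).astype(int)
    if status.sum() == 0:  # ensure at least one event
        status[np.argmin(Y)] = 1
    return SurvivalDataset(times=Y, status=status, covariates=X)


@pytest.fixture
def make_random_dataset():
    return random_dataset


def simulated_case(case="normal", censor=0.2, n=2000, seed=7):
    rng = np.random.default_rng(seed)
    design = SimulationDesign(n=n, covariate_case=case, censor_target=censor)
    U, _ = calibrate_censoring(design, rng, mc_size=40_000)
    design = design.with_censor_bound(U)
    return design, gen_dataset(design, rng)


@pytest.fixture(scope="session")
def case1_data():
    """One calibrated Gaussian-case dataset, n=2000, ~20% censoring."""
    return simulated_case()


@pytest.fixture(scope="session")
def standard_tables():
    """Replication tables for the four standard designs at r=1000.

    Desk-scale study: n=20000 per dataset, 200 replications, gamma weights,
    M=1.  The subsample estimator's error is governed by r, so the reduced n
    leaves the table metrics essentially unchanged.
    """
    tables = {}
    for i, (case, censor) in enumerate(
        [("normal", 0.2), ("normal", 0.6), ("t10", 0.2), ("t10", 0.6)]
    ):
        design = SimulationDesign(
            n=20_000, covariate_case=case, censor_target=censor
        )
        scheme = PerturbationScheme(family="gamma", n=20_000, r=1000)
        tables[(case, censor)] = run_replications(
            design,
            scheme,
            M=1,
            n_reps=200,
            rng=np.random.default_rng(1000 + i),
            calibration_size=40_000,
        )
    return tables
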
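"""Right-censored survival data container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SurvivalDataset:
    """A right-censored sample ``{(Y_i, Delta_i, X_i) : i = 1..n}``.

    Parameters
    ----------
    times
        Observed times ``Y_i = min(T_i, C_i)``; strictly positive, finite.
    status
        Event indicators ``Delta_i = I(T_i <= C_i)`` in {0, 1}.
    covariates
        ``(n, p)`` covariate matrix with rows ``X_i``; no missing entries.
    """

    times: np.ndarray
    status: np.ndarray
    covariates: np.ndarray

    def __post_init__(self) -> None:
        times = np.ascontiguousarray(self.times, dtype=np.float64)
        status = np.ascontiguousarray(self.status, dtype=np.int8)
        cov = np.ascontiguousarray(self.covariates, dtype=np.float64)
        if times.ndim != 1:
            raise ValueError("times must be a 1-d array")
        n = times.shape[0]
        if n < 1:
            raise ValueError("dataset must contain at least one subject")
        if status.shape != (n,):
            raise ValueError("status must have the same length as times")
        if cov.ndim == 1:
            cov = cov.reshape(n, 1)
        if cov.shape[0] != n or cov.shape[1] < 1:
            raise ValueError("covariates must be an (n, p) matrix with p >= 1")
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise ValueError("times must be strictly positive and finite")
        if not np.isin(np.asarray(self.status), (0, 1)).all():
            raise ValueError("status entries must be 0 or 1")
        if not np.all(np.isfinite(cov)):
            raise ValueError("covariates must be finite with no missing entries")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "status", status)
        object.__setattr__(self, "covariates", cov)

    @property
    def n_subjects(self) -> int:
        return self.times.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(np.sum(self.status))

    @property
    def censoring_rate(self) -> float:
        """Fraction of subjects with Delta_i = 0."""
        return 1.0 - self.n_events / self.n_subjects

    def subset(self, mask: np.ndarray) -> "SurvivalDataset":
        """Row subset (boolean mask or index array)."""
        return SurvivalDataset(
            self.times[mask], self.status[mask], self.covariates[mask]
        )

    def to_frame(
        self,
        time_col: str = "time",
        status_col: str = "status",
        covariate_cols: list[str] | None = None,
    ) -> pd.DataFrame:
        if covariate_cols is None:
            covariate_cols = [f"x{k + 1}" for k in range(self.n_covariates)]
        if len(covariate_cols) != self.n_covariates:
            raise ValueError("covariate_cols length must equal p")
        frame = pd.DataFrame({time_col: self.times, status_col: self.status})
        for k, name in enumerate(covariate_cols):
            frame[name] = self.covariates[:, k]
        return frame

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        time_col: str = "time",
        status_col: str = "status",
        covariate_cols: list[str] | None = None,
    ) -> "SurvivalDataset":
        if covariate_cols is None:
            covariate_cols = [
                c for c in frame.columns if c not in (time_col, status_col)
            ]
        return cls(
            frame[time_col].to_numpy(dtype=np.float64),
            frame[status_col].to_numpy(),
            frame[covariate_cols].to_numpy(dtype=np.float64),
        )
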
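"""Readers and writers for survival CSVs, fit documents, and tables.

Every run's resolved configuration (seed, pi_n, calibrated censoring bound,
column names, tolerances) is echoed into the output document so any published
run can be re-executed bit-identically from that document alone.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import SurvivalDataset
from .evaluation import ReplicationTable


def read_survival_csv(
    path,
    time_col: str = "time",
    status_col: str = "status",
    covariate_cols: list[str] | None = None,
    sep: str = ",",
) -> SurvivalDataset:
    """Read a delimited survival table into a validated dataset.

    Raises descriptive errors naming the offending rows for missing values,
    nonpositive times, and non-binary status entries.
    """
    frame = pd.read_csv(path, sep=sep)
    if covariate_cols is None:
        covariate_cols = [
            c for c in frame.columns if c not in (time_col, status_col)
        ]
    needed = [time_col, status_col, *covariate_cols]
    missing_cols = [c for c in needed if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"missing columns in {path}: {missing_cols}")
    sub = frame[needed]
    na_rows = sub.index[sub.isna().any(axis=1)].tolist()
    if na_rows:
        raise ValueError(f"rows with missing values in {path}: {na_rows[:20]}")
    times = sub[time_col].to_numpy(dtype=np.float64)
    bad_time = sub.index[(times <= 0) | ~np.isfinite(times)].tolist()
    if bad_time:
        raise ValueError(f"nonpositive or nonfinite times at rows {bad_time[:20]}")
    status = sub[status_col].to_numpy()
    bad_status = sub.index[~np.isin(status, (0, 1))].tolist()
    if bad_status:
        raise ValueError(f"status not in {{0,1}} at rows {bad_status[:20]}")
    return SurvivalDataset(
        times=times,
        status=status.astype(np.int8),
        covariates=sub[covariate_cols].to_numpy(dtype=np.float64),
    )


def write_survival_csv(data: SurvivalDataset, path, **frame_kwargs) -> None:
    data.to_frame(**frame_kwargs).to_csv(path, index=False)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_fit_json(document: dict, path) -> None:
    """Serialize a fit document (coefficients, covariance, diagnostics,
    config echo) as JSON at full float precision."""
    Path(path).write_text(json.dumps(_jsonify(document), indent=2) + "\n")


def read_fit_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_table_csv(table: ReplicationTable, path) -> None:
    """Tidy long-format table with a ``# key=value`` metadata header."""
    lines = [
        f"# {key}={table.metadata[key]}" for key in sorted(table.metadata)
    ]
    body = table.to_frame().to_csv(index=False)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else "") + body)


def read_table_csv(path) -> tuple[pd.DataFrame, dict]:
    """Read a tidy replication table; returns (frame, metadata)."""
    metadata = {}
    text = Path(path).read_text().splitlines(keepends=True)
    start = 0
    for line in text:
        if not line.startswith("#"):
            break
        key, _, value = line[1:].strip().partition("=")
        metadata[key.strip()] = value
        start += 1
    frame = pd.read_csv(io.StringIO("".join(text[start:])))
    return frame, metadata
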
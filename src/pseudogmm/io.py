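"""CSV readers and JSON report writers."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pseudo import PseudoObservationMatrix, SurvivalSample

__all__ = ["read_survival_csv", "write_report", "read_report", "write_pseudo_csv"]

REQUIRED = ["id", "time", "status", "arm"]


def read_survival_csv(path) -> SurvivalSample:
    """Read subject-level data: header id,time,status,arm[,covariate...].

    Extra columns become covariates in header order.  Errors name the first
    offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if col != "id" and bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(f"{path}: non-numeric value in column {col!r} at row {row}")
    status = pd.to_numeric(df["status"])
    bad = ~status.isin([0, 1])
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise ValueError(
            f"{path}: status must be 0/1; offending value at row {row}"
        )
    time = pd.to_numeric(df["time"])
    bad = ~(time > 0)
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise ValueError(f"{path}: time must be positive; offending value at row {row}")
    return SurvivalSample.from_dataframe(df)


def write_report(result, path, config: dict | None = None) -> None:
    """JSON report for any Results object; round-trips numerics losslessly."""
    payload = result.to_dict()
    payload["config"] = config or {}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def write_pseudo_csv(pseudo: PseudoObservationMatrix, long_path=None, wide_path=None):
    """Write pseudo-observations in long (id, t_index, t_value, pseudo) and/or
    wide n x K layouts."""
    if long_path is not None:
        pseudo.to_long().to_csv(long_path, index=False)
    if wide_path is not None:
        ids = pseudo.ids if pseudo.ids is not None else np.arange(1, pseudo.n + 1)
        wide = pd.DataFrame(
            pseudo.values,
            columns=[f"t{k + 1}" for k in range(pseudo.grid.K)],
        )
        wide.insert(0, "id", ids)
        wide.to_csv(wide_path, index=False)
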
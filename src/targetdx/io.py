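"""CSV input for 2x2 tables and score-label data.

Tables CSV: header ``tp,fp,fn,tn`` with an optional ``label`` column, one
row per study or testing strategy.  Scores CSV: columns ``score`` and
``status`` with status in {0, 1}.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .accuracy import ContingencyTable

__all__ = ["read_tables_csv", "read_scores_csv"]

_TABLE_COLS = ("tp", "fp", "fn", "tn")


def read_tables_csv(path: str | Path) -> list[tuple[str, ContingencyTable]]:
    """Read labeled contingency tables; labels default to the row number."""
    df = pd.read_csv(path)
    missing = [c for c in _TABLE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing} (header must include tp,fp,fn,tn)")
    out: list[tuple[str, ContingencyTable]] = []
    for i, row in df.iterrows():
        label = str(row["label"]) if "label" in df.columns else f"row{i + 1}"
        try:
            cells = {c: int(row[c]) for c in _TABLE_COLS}
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {i + 2}: non-integer cell count ({exc})") from exc
        try:
            out.append((label, ContingencyTable(**cells)))
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    if not out:
        raise ValueError(f"{path}: no data rows")
    return out


def read_scores_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a score,status table; returns (scores, status) arrays."""
    df = pd.read_csv(path)
    for col in ("score", "status"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    scores = df["score"].to_numpy(dtype=float)
    status = df["status"].to_numpy()
    if not np.isin(status, (0, 1)).all():
        bad = df.index[~np.isin(status, (0, 1))][0]
        raise ValueError(f"{path}: line {bad + 2}: status must be 0 or 1")
    if not np.all(np.isfinite(scores)):
        bad = df.index[~np.isfinite(scores)][0]
        raise ValueError(f"{path}: line {bad + 2}: score must be finite")
    return scores, status.astype(int)
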
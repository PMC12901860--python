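"""Spike-train CSV input/output.

The on-disk format is a plain CSV with header ``trial_id, unit_label,
time_ms`` and one spike per row, at 0.01 ms resolution or better.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .spikes import SpikeTrain, TrialEnsemble

__all__ = ["read_spiketrains", "write_spiketrains"]

_COLUMNS = ["trial_id", "unit_label", "time_ms"]


def write_spiketrains(ensemble: TrialEnsemble, path) -> None:
    """Write an ensemble as tidy CSV (one spike per row)."""
    rows = {c: [] for c in _COLUMNS}
    for trial, train in enumerate(ensemble):
        rows["trial_id"].extend([trial] * len(train))
        rows["unit_label"].extend([train.label] * len(train))
        rows["time_ms"].extend(np.round(train.times, 6))
    pd.DataFrame(rows).to_csv(path, index=False)


def read_spiketrains(path, duration: float | None = None) -> TrialEnsemble:
    """Read an ensemble from CSV; trains are sorted on read.

    ``duration`` defaults to the latest spike time (rounded up to the
    next ms) when the file contains spikes; an empty file needs it to be
    given explicitly only if a non-degenerate ensemble is required.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed CSV ({err})") from err
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df.index[pd.to_numeric(df["time_ms"], errors="coerce").isna()]
    if len(bad):
        # +2 accounts for the header line and 1-based numbering
        raise ValueError(f"{path}: non-numeric time_ms at line {bad[0] + 2}")
    if df.empty:
        return TrialEnsemble([], duration or 1.0)
    if duration is None:
        duration = float(np.ceil(df["time_ms"].max() + 1e-9))
    trains = []
    for trial_id, group in df.groupby("trial_id", sort=True):
        label = str(group["unit_label"].iloc[0])
        times = np.sort(group["time_ms"].to_numpy(dtype=float))
        trains.append(SpikeTrain(times, duration, label))
    return TrialEnsemble(trains, duration)
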
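"""Plain-text readers and writers for count and score series.

Count files are delimited text with ``#``-prefixed header lines::

    # sample_interval_s: 10
    # mode_tag: ZCM
    # start_time: 2024-03-01T22:00:00      (optional)
    timestamp,count                         (or a single count column)
    2024-03-01T22:00:00,12
    ...

Timestamps are optional; without them uniform sampling at the header
interval is assumed.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ActivitySeries, ScoreSeries, SleepWakeSeries

__all__ = ["read_counts", "write_counts", "write_scores"]


def read_counts(path: str | Path) -> ActivitySeries:
    path = Path(path)
    header: dict[str, str] = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, value = line.lstrip("#").partition(":")
            header[key.strip()] = value.strip()
    if "sample_interval_s" not in header:
        raise ValueError(f"{path}: missing '# sample_interval_s:' header")
    df = pd.read_csv(path, skiprows=skip)
    if "count" not in df.columns:
        if df.shape[1] == 1:
            df.columns = ["count"]
        else:
            raise ValueError(f"{path}: expected a 'count' column")
    start = None
    if "start_time" in header:
        start = datetime.fromisoformat(header["start_time"])
    elif "timestamp" in df.columns and len(df):
        start = datetime.fromisoformat(str(df["timestamp"].iloc[0]))
    return ActivitySeries(
        values=df["count"].to_numpy(dtype=float),
        sample_interval=float(header["sample_interval_s"]),
        mode_tag=header.get("mode_tag", "unknown"),
        start_time=start,
    )


def write_counts(series: ActivitySeries, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sample_interval_s: {series.sample_interval:g}\n")
        fh.write(f"# mode_tag: {series.mode_tag}\n")
        if series.start_time is not None:
            fh.write(f"# start_time: {series.start_time.isoformat()}\n")
        fh.write("count\n")
        np.savetxt(fh, series.values, fmt="%g")
    return path


def write_scores(
    scores: ScoreSeries, labels: SleepWakeSeries, path: str | Path
) -> Path:
    """Write per-epoch index, raw score and label as delimited text."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "epoch_index": scores.epoch_indices,
            "score": scores.values,
            "label": np.where(labels.labels == 1, "wake", "sleep"),
        }
    )
    df.to_csv(path, index=False)
    return path


def write_labels(labels: SleepWakeSeries, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(labels.start_index, labels.start_index + len(labels)),
            "label": np.where(labels.labels == 1, "wake", "sleep"),
        }
    )
    df.to_csv(path, index=False)
    return path
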
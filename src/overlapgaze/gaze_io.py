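"""Reading, writing and trial segmentation of raw gaze streams.

Gaze logs are tab-delimited UTF-8 text with a header ``t_ms  x_deg  y_deg
valid`` ('.' decimal separator); event logs carry one row per trial with
``trial_index  condition  central_onset_ms  distractor_onset_ms
distractor_side``.  Sample and event timestamps share one session clock in
milliseconds.  In memory both are plain pandas DataFrames; a segmented trial
is a :class:`TrialRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GAZE_COLUMNS = ["t_ms", "x_deg", "y_deg", "valid"]
EVENT_COLUMNS = [
    "trial_index",
    "condition",
    "central_onset_ms",
    "distractor_onset_ms",
    "distractor_side",
]

#: nominal rate of the eye tracker of record; the 8-month video path is 25 Hz
DEFAULT_SAMPLING_HZ = 300.0


class GazeLogError(ValueError):
    """Malformed or contract-violating gaze/event log."""


@dataclass
class TrialRecord:
    """Samples of one trial, restricted to [central onset, distractor onset +
    analysis window]; the right edge is closed (1000 ms is the last measured
    time point of the index)."""

    event: pd.Series  # one row of an event log
    samples: pd.DataFrame  # GAZE_COLUMNS, sorted by t_ms
    sampling_rate_hz: float = DEFAULT_SAMPLING_HZ
    #: unfilled gaps, populated by scoring.interpolate_gaps: (t_start, t_end)
    gaps: list[tuple[float, float]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return len(self.samples) == 0

    @property
    def distractor_onset_ms(self) -> float:
        return float(self.event["distractor_onset_ms"])

    @property
    def central_onset_ms(self) -> float:
        return float(self.event["central_onset_ms"])

    @property
    def condition(self) -> str:
        return str(self.event["condition"])

    @property
    def distractor_side(self) -> str:
        return str(self.event["distractor_side"])


def _check_numeric(df: pd.DataFrame, raw: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    for col in cols:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise GazeLogError(f"{path}: malformed value in column {col!r} at line {line}")
        if raw[col].isna().any():
            line = int(raw[col].isna().idxmax()) + 2
            raise GazeLogError(f"{path}: missing value in column {col!r} at line {line}")
        # exact strtod conversion (pandas' fast parser can be off by 1 ulp)
        df[col] = np.asarray(raw[col].to_numpy(dtype=object), dtype=np.float64)
    return df


def read_gaze_log(path: str | Path) -> pd.DataFrame:
    """Read a gaze log; enforces the header and monotone nondecreasing time."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GAZE_COLUMNS if c not in raw.columns]
    if missing:
        raise GazeLogError(f"{path}: missing columns {missing}")
    df = pd.DataFrame(index=raw.index)
    df = _check_numeric(df, raw, ["t_ms", "x_deg", "y_deg"], path)
    valid_raw = raw["valid"].str.strip().str.lower()
    mapping = {"1": True, "0": False, "true": True, "false": False}
    if not valid_raw.isin(mapping).all():
        line = int((~valid_raw.isin(mapping)).idxmax()) + 2
        raise GazeLogError(f"{path}: malformed value in column 'valid' at line {line}")
    df["valid"] = valid_raw.map(mapping).astype(bool)
    t = df["t_ms"].to_numpy()
    if len(t) > 1 and np.any(np.diff(t) < 0):
        line = int(np.argmax(np.diff(t) < 0)) + 3
        raise GazeLogError(f"{path}: non-monotone timestamps at line {line}")
    return df[GAZE_COLUMNS]


def write_gaze_log(samples: pd.DataFrame, path: str | Path) -> None:
    """Write a gaze log (round-trips losslessly through :func:`read_gaze_log`)."""
    out = samples[GAZE_COLUMNS].copy()
    out["valid"] = out["valid"].astype(int)
    # 17 significant digits: float64 round-trips bit-exactly through text
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_event_log(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in EVENT_COLUMNS if c not in raw.columns]
    if missing:
        raise GazeLogError(f"{path}: missing columns {missing}")
    df = pd.DataFrame(index=raw.index)
    df = _check_numeric(df, raw, ["trial_index", "central_onset_ms", "distractor_onset_ms"], path)
    df["trial_index"] = df["trial_index"].astype(int)
    df["condition"] = raw["condition"].astype(str)
    df["distractor_side"] = raw["distractor_side"].astype(str)
    return df[EVENT_COLUMNS]


def write_event_log(events: pd.DataFrame, path: str | Path) -> None:
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


def segment_trials(
    samples: pd.DataFrame,
    events: pd.DataFrame,
    window_end_ms: float = 1000.0,
    sampling_rate_hz: float = DEFAULT_SAMPLING_HZ,
) -> list[TrialRecord]:
    """Cut one continuous gaze stream into per-trial records.

    Each trial covers [central_onset_ms, distractor_onset_ms + window_end_ms],
    both edges closed.  Trials with no samples are retained and flagged empty.
    Overlapping trial intervals are an error; non-overlapping closed intervals
    partition the in-window samples without duplication.
    """
    events = events.sort_values("trial_index").reset_index(drop=True)
    starts = events["central_onset_ms"].to_numpy(dtype=float)
    ends = events["distractor_onset_ms"].to_numpy(dtype=float) + window_end_ms
    order = np.argsort(starts, kind="stable")
    if np.any(ends[order][:-1] >= starts[order][1:]):
        raise GazeLogError("overlapping trial intervals in event log")
    t = samples["t_ms"].to_numpy(dtype=float)
    records = []
    for i in range(len(events)):
        lo = int(np.searchsorted(t, starts[i], side="left"))
        hi = int(np.searchsorted(t, ends[i], side="right"))
        records.append(
            TrialRecord(
                event=events.iloc[i],
                samples=samples.iloc[lo:hi].reset_index(drop=True),
                sampling_rate_hz=sampling_rate_hz,
            )
        )
    return records


__all__ = [
    "GAZE_COLUMNS",
    "EVENT_COLUMNS",
    "DEFAULT_SAMPLING_HZ",
    "GazeLogError",
    "TrialRecord",
    "read_gaze_log",
    "write_gaze_log",
    "read_event_log",
    "write_event_log",
    "segment_trials",
]
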
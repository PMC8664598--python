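"""Shared builders for synthetic single-trial gaze fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from overlapgaze.gaze_io import TrialRecord
from overlapgaze.protocol import ProtocolSpec, build_aois


CENTRAL_ONSET = 0.0
DISTRACTOR_ONSET = 1000.0
WINDOW_END = 2000.0


@pytest.fixture(scope="session")
def aois():
    return build_aois(ProtocolSpec())


def make_event(trial_index=0, condition="fearful", side="right") -> pd.Series:
    return pd.Series(
        {
            "trial_index": trial_index,
            "condition": condition,
            "central_onset_ms": CENTRAL_ONSET,
            "distractor_onset_ms": DISTRACTOR_ONSET,
            "distractor_side": side,
        }
    )


def make_trial(
    segments: list[tuple[float, float, tuple[float, float] | None]],
    side: str = "right",
    dt: float = 10.0 / 3.0,
    condition: str = "fearful",
    rate: float = 300.0,
) -> TrialRecord:
    """Build a TrialRecord from (t_start, t_end, position) segments.

    Position None marks invalid samples.  Segment intervals are half-open
    [t_start, t_end) except that WINDOW_END itself is included.  Times run on
    a regular grid from 0 to 2000 ms; the distractor onset is at 1000 ms.
    """
    n = int(round(WINDOW_END / dt))
    t = np.linspace(0.0, WINDOW_END, n + 1)
    x = np.zeros_like(t)
    y = np.zeros_like(t)
    valid = np.zeros_like(t, dtype=bool)
    filled = np.zeros_like(t, dtype=bool)
    for t0, t1, pos in segments:
        m = (t >= t0) & ((t < t1) | ((t1 >= WINDOW_END) & (t <= WINDOW_END)))
        filled |= m
        if pos is None:
            valid[m] = False
        else:
            x[m], y[m] = pos
            valid[m] = True
    samples = pd.DataFrame({"t_ms": t, "x_deg": x, "y_deg": y, "valid": valid})
    samples = samples[filled].reset_index(drop=True)
    return TrialRecord(
        event=make_event(condition=condition, side=side),
        samples=samples,
        sampling_rate_hz=rate,
    )


CENTER = (0.0, 0.0)
RIGHT = (29.4, 0.0)  # center of the right distractor AOI
LEFT = (-29.4, 0.0)
OFF = (0.0, -25.0)  # outside every AOI
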
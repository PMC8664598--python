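"""Overlap-task session protocol: conditions, timing, geometry, trial order.

The Overlap paradigm presents a central face (happy, fearful, neutral with
eyes open, neutral with eyes closed) alone for 1000 ms, then flanks it with a
lateral distractor for 3000 ms while the face stays on.  Attention
disengagement is measured as the latency of the first saccade from the face
to the distractor.  This module defines the session parameters, generates the
constrained-random trial order, and builds the screen areas of interest
(AOIs) used by the scoring module.

Coordinates are degrees of visual angle relative to screen center, x
rightward, y upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONDITIONS: tuple[str, ...] = ("happy", "fearful", "neutral_open", "neutral_closed")
SIDES: tuple[str, str] = ("left", "right")

#: retry budget for the rejection sampler before deterministic repair kicks in
_MAX_RETRIES = 10_000


class InfeasibleScheduleError(ValueError):
    """No trial order can satisfy the run-length constraints."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Parameters of one Overlap-task session.

    Defaults are the task as administered: 24 trials (6 per face condition),
    1000 ms central-solo period, 3000 ms overlap period, 15.8 x 11.4 deg face,
    15.8 x 4.0 deg distractor at 13.6 deg separation, at most 4 consecutive
    same-emotion trials and 3 consecutive same-side distractors.
    """

    conditions: tuple[str, ...] = CONDITIONS
    trials_per_condition: int = 6
    central_solo_ms: float = 1000.0
    overlap_ms: float = 3000.0
    face_size_deg: tuple[float, float] = (15.8, 11.4)  # width, height
    distractor_size_deg: tuple[float, float] = (15.8, 4.0)
    face_distractor_separation_deg: float = 13.6
    separation_convention: str = "nearest_edge"  # or "center_to_center"
    max_emotion_run: int = 4
    max_side_run: int = 3
    anticipatory_ms: dict[str, float] = field(
        default_factory=lambda: {"infant8": 160.0, "toddler24": 150.0}
    )
    window_end_ms: float = 1000.0
    frame_ms: float = 40.0  # manual video-coding frame, 8-month path only

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions) or not self.conditions:
            raise ValueError("conditions must be a non-empty set of distinct labels")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be positive")
        for a in self.anticipatory_ms.values():
            if not (0 < a < self.window_end_ms):
                raise ValueError("anticipatory threshold must lie in (0, window_end_ms)")
        if not (self.window_end_ms <= self.overlap_ms):
            raise ValueError("window_end_ms must not exceed overlap_ms")
        for extent in (*self.face_size_deg, *self.distractor_size_deg):
            if extent <= 0:
                raise ValueError("geometric extents must be strictly positive")
        if self.face_distractor_separation_deg < 0:
            raise ValueError("separation must be nonnegative")
        if self.separation_convention not in ("nearest_edge", "center_to_center"):
            raise ValueError(f"unknown separation convention {self.separation_convention!r}")
        if self.max_emotion_run < 1 or self.max_side_run < 1:
            raise ValueError("run-length caps must be at least 1")

    @property
    def total_trials(self) -> int:
        return self.trials_per_condition * len(self.conditions)


@dataclass(frozen=True)
class TrialPlan:
    index: int
    condition: str
    distractor_side: str


@dataclass(frozen=True)
class Rect:
    """Closed axis-aligned rectangle in degrees (ties resolve as inside)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError("degenerate rectangle")

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max

    def contains_vec(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x_min) & (x <= self.x_max) & (y >= self.y_min) & (y <= self.y_max)
        )

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def interior_overlaps(self, other: "Rect") -> bool:
        return (
            self.x_min < other.x_max
            and other.x_min < self.x_max
            and self.y_min < other.y_max
            and other.y_min < self.y_max
        )


@dataclass(frozen=True)
class AOISet:
    """Central face AOI plus the two mirror-image distractor AOIs.

    Rectangles are closed; a gaze point on a shared boundary is labeled
    central (central precedence in :func:`label`).  Disjointness is required
    of the interiors, so abutting rectangles (zero separation) are legal.
    """

    central: Rect
    distractor_left: Rect
    distractor_right: Rect

    def __post_init__(self) -> None:
        for d in (self.distractor_left, self.distractor_right):
            if self.central.interior_overlaps(d):
                raise ValueError("central and distractor AOIs overlap")
        # mirror symmetry about the vertical midline
        l, r = self.distractor_left, self.distractor_right
        if not (
            np.isclose(l.x_min, -r.x_max)
            and np.isclose(l.x_max, -r.x_min)
            and np.isclose(l.y_min, r.y_min)
            and np.isclose(l.y_max, r.y_max)
        ):
            raise ValueError("distractor AOIs are not mirror images")

    def distractor(self, side: str) -> Rect:
        if side == "left":
            return self.distractor_left
        if side == "right":
            return self.distractor_right
        raise ValueError(f"unknown side {side!r}")

    def label(self, x: np.ndarray, y: np.ndarray, side: str) -> np.ndarray:
        """Label samples 'C' (central), 'D' (cued distractor) or 'O' (elsewhere)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(x.shape, "O", dtype="<U1")
        out[self.distractor(side).contains_vec(x, y)] = "D"
        out[self.central.contains_vec(x, y)] = "C"  # central precedence on ties
        return out


def build_aois(spec: ProtocolSpec) -> AOISet:
    """Build the AOI set: screen-centered face, laterally placed distractors.

    Under the default ``nearest_edge`` convention the separation is measured
    between the facing edges of the face and the distractor; under
    ``center_to_center`` between their centers.
    """
    fw, fh = spec.face_size_deg
    dw, dh = spec.distractor_size_deg
    sep = spec.face_distractor_separation_deg
    central = Rect(-fw / 2, fw / 2, -fh / 2, fh / 2)
    if spec.separation_convention == "nearest_edge":
        inner = fw / 2 + sep
    else:
        inner = sep - dw / 2
    right = Rect(inner, inner + dw, -dh / 2, dh / 2)
    left = Rect(-(inner + dw), -inner, -dh / 2, dh / 2)
    return AOISet(central=central, distractor_left=left, distractor_right=right)


def _max_run(seq: Sequence) -> int:
    best = run = 0
    prev = object()
    for item in seq:
        run = run + 1 if item == prev else 1
        prev = item
        best = max(best, run)
    return best


def _repair(seq: list, max_run: int, rng: np.random.Generator) -> list:
    """Deterministic swap repair: break each excessive run with a later
    differing element whose swap does not itself create a violation."""
    seq = list(seq)
    for _ in range(len(seq) * len(seq)):
        # locate first violating position
        viol = None
        run = 0
        for i in range(len(seq)):
            run = run + 1 if i > 0 and seq[i] == seq[i - 1] else 1
            if run > max_run:
                viol = i
                break
        if viol is None:
            return seq
        fixed = False
        for j in range(viol + 1, len(seq)):
            if seq[j] == seq[viol]:
                continue
            seq[viol], seq[j] = seq[j], seq[viol]
            if _max_run(seq) <= max_run:
                fixed = True
                break
            seq[viol], seq[j] = seq[j], seq[viol]
        if not fixed:
            raise InfeasibleScheduleError(
                f"cannot satisfy run-length cap {max_run} for sequence of "
                f"{len(seq)} trials"
            )
    raise InfeasibleScheduleError("repair did not converge")


def _constrained_permutation(
    items: list, max_run: int, rng: np.random.Generator
) -> list:
    for _ in range(_MAX_RETRIES):
        perm = [items[i] for i in rng.permutation(len(items))]
        if _max_run(perm) <= max_run:
            return perm
    return _repair([items[i] for i in rng.permutation(len(items))], max_run, rng)


def generate_schedule(spec: ProtocolSpec, seed: int) -> list[TrialPlan]:
    """Constrained-random trial order, a pure function of (spec, seed).

    Emotion order and distractor side are sampled independently by rejection
    over random permutations (deterministic swap repair as fallback).  Sides
    are balanced as evenly as the trial count allows (12/12 by default).
    """
    rng = np.random.default_rng(seed)
    conditions = [c for c in spec.conditions for _ in range(spec.trials_per_condition)]
    n = len(conditions)
    n_left = n // 2
    sides = ["left"] * n_left + ["right"] * (n - n_left)
    cond_order = _constrained_permutation(conditions, spec.max_emotion_run, rng)
    side_order = _constrained_permutation(sides, spec.max_side_run, rng)
    return [
        TrialPlan(index=i, condition=c, distractor_side=s)
        for i, (c, s) in enumerate(zip(cond_order, side_order))
    ]


def write_schedule(schedule: Iterable[TrialPlan], path: str | Path) -> None:
    df = pd.DataFrame(
        [(t.index, t.condition, t.distractor_side) for t in schedule],
        columns=["trial_index", "condition", "distractor_side"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_schedule(path: str | Path) -> list[TrialPlan]:
    df = pd.read_csv(path, sep="\t")
    required = {"trial_index", "condition", "distractor_side"}
    if not required.issubset(df.columns):
        raise ValueError(f"schedule file missing columns {sorted(required - set(df.columns))}")
    return [
        TrialPlan(index=int(r.trial_index), condition=str(r.condition),
                  distractor_side=str(r.distractor_side))
        for r in df.itertuples()
    ]


__all__ = [
    "CONDITIONS",
    "SIDES",
    "ProtocolSpec",
    "TrialPlan",
    "Rect",
    "AOISet",
    "InfeasibleScheduleError",
    "build_aois",
    "generate_schedule",
    "read_schedule",
    "write_schedule",
    "replace",
]
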
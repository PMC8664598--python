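"""Trial validity rules, disengagement latency and the normalized dwell index.

The dwell-time index maps the disengagement latency x (ms from distractor
onset) linearly onto [0, 1]:

    index(x) = 1 - (1000 - x) / 840 = (x - 160) / 840

so the shortest acceptable saccade (160 ms) scores 0 and a trial with no
saccade by the 1000-ms window end scores 1 (the timeout folds into the
formula as x = 1000).  A condition's dwell index is the mean over its
scorable trials; at least two scorable trials per condition are required for
a participant to enter the analysis.

Two age modes mirror the two coding pipelines: ``infant8`` (manual video
coding at 40-ms frames, anticipatory threshold 160 ms, an excessive-movement
rejection) and ``toddler24`` (automated eye-tracker coding, anticipatory
threshold 150 ms, >=70% central fixation, <=200-ms gap interpolation, and
rejection of saccades that fall inside missing data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gaze_io import TrialRecord
from .protocol import AOISet

SCORABLE_STATUSES = ("scorable_saccade", "scorable_timeout")
REJECTED_STATUSES = (
    "rejected_no_initial_fixation",
    "rejected_anticipatory",
    "rejected_wrong_direction",
    "rejected_gap",
    "rejected_insufficient_fixation",
    "rejected_excess_movement",
    "rejected_missing_at_saccade",
)


@dataclass(frozen=True)
class ScoringParams:
    """Validity-rule and normalization constants for one age mode.

    ``norm_min_ms``/``norm_span_ms`` are kept at the printed 160/840 for both
    ages; 24-month latencies in [150, 160) produce a negative raw term and
    are clamped to 0.
    """

    age_mode: str  # "infant8" | "toddler24"
    anticipatory_ms: float
    window_end_ms: float = 1000.0
    norm_min_ms: float = 160.0
    norm_span_ms: float = 840.0
    min_fixation_fraction: float = 0.70  # toddler24 only
    max_gap_ms: float = 200.0  # toddler24 only
    frame_ms: float = 40.0  # infant8 only
    min_scorable_per_condition: int = 2
    max_central_exits: int = 2  # infant8 "excessive movement" ceiling (convention)
    landing_window_ms: float = 200.0  # directedness test for saccades

    def __post_init__(self) -> None:
        if self.age_mode not in ("infant8", "toddler24"):
            raise ValueError(f"unknown age mode {self.age_mode!r}")
        if not math.isclose(self.norm_min_ms + self.norm_span_ms, self.window_end_ms):
            raise ValueError("norm_min_ms + norm_span_ms must equal window_end_ms")
        if not (0 < self.min_fixation_fraction <= 1):
            raise ValueError("min_fixation_fraction must lie in (0, 1]")

    @classmethod
    def for_age(cls, age_mode: str, **overrides) -> "ScoringParams":
        anticipatory = {"infant8": 160.0, "toddler24": 150.0}[age_mode]
        return cls(age_mode=age_mode, anticipatory_ms=anticipatory, **overrides)


@dataclass(frozen=True)
class TrialScore:
    status: str
    latency_ms: float = math.nan  # defined only for scorable_saccade
    index: float = math.nan  # defined for both scorable statuses
    trial_index: int = -1
    condition: str = ""

    @property
    def scorable(self) -> bool:
        return self.status in SCORABLE_STATUSES


@dataclass(frozen=True)
class ConditionScore:
    condition: str
    n_scorable: int
    dwell_index: float  # nan when n_scorable == 0

    @property
    def defined(self) -> bool:
        return self.n_scorable >= 1


@dataclass(frozen=True)
class ParticipantScores:
    participant_id: str
    age_mode: str
    conditions: dict[str, ConditionScore]
    included: bool
    trial_scores: tuple[TrialScore, ...] = ()


def trial_index_value(latency_ms: float, params: ScoringParams, timeout: bool = False) -> float:
    """Per-trial dwell index: timeout -> 1, else clamp((x - 160) / 840, 0, 1)."""
    if timeout:
        return 1.0
    raw = (latency_ms - params.norm_min_ms) / params.norm_span_ms
    return float(min(1.0, max(0.0, raw)))


def trial_index(score: TrialScore, params: ScoringParams) -> float:
    """Index of a scorable trial; rejected trials have no defined index."""
    if score.status == "scorable_timeout":
        return 1.0
    if score.status == "scorable_saccade":
        return trial_index_value(score.latency_ms, params)
    raise ValueError(f"trial index undefined for status {score.status!r}")


def interpolate_gaps(trial: TrialRecord, max_gap_ms: float) -> tuple[TrialRecord, list[dict]]:
    """Fill short dropouts of the eye tracker; report the rest.

    Runs of invalid samples whose flanking-valid time span is <= ``max_gap_ms``
    are linearly interpolated; longer runs (and runs touching the trial
    boundary) stay invalid and are reported with their extents.  The returned
    record carries unfilled gaps in ``record.gaps``.
    """
    s = trial.samples
    report: list[dict] = []
    if trial.empty:
        return replace_samples(trial, s, []), report
    valid = s["valid"].to_numpy(copy=True)
    t = s["t_ms"].to_numpy()
    x = s["x_deg"].to_numpy(copy=True)
    y = s["y_deg"].to_numpy(copy=True)
    if not valid.any():
        gap = {"t_start": float(t[0]), "t_end": float(t[-1]),
               "extent_ms": float(t[-1] - t[0]), "filled": False}
        return replace_samples(trial, s, [(gap["t_start"], gap["t_end"])]), [gap]
    inv = ~valid
    # maximal runs of invalid samples
    edges = np.flatnonzero(np.diff(np.concatenate(([0], inv.view(np.int8), [0]))))
    unfilled: list[tuple[float, float]] = []
    for a, b in zip(edges[::2], edges[1::2]):  # run is [a, b)
        has_left = a > 0
        has_right = b < len(s)
        if has_left and has_right:
            extent = float(t[b] - t[a - 1])
            if extent <= max_gap_ms:
                frac = (t[a:b] - t[a - 1]) / (t[b] - t[a - 1])
                x[a:b] = x[a - 1] + frac * (x[b] - x[a - 1])
                y[a:b] = y[a - 1] + frac * (y[b] - y[a - 1])
                valid[a:b] = True
                report.append({"t_start": float(t[a]), "t_end": float(t[b - 1]),
                               "extent_ms": extent, "filled": True})
                continue
        else:
            extent = float(t[min(b, len(s) - 1)] - t[max(a - 1, 0)])
        report.append({"t_start": float(t[a]), "t_end": float(t[b - 1]),
                       "extent_ms": extent, "filled": False})
        unfilled.append((float(t[max(a - 1, 0)]), float(t[min(b, len(s) - 1)])))
    out = s.copy()
    out["x_deg"], out["y_deg"], out["valid"] = x, y, valid
    return replace_samples(trial, out, unfilled), report


def replace_samples(
    trial: TrialRecord, samples: pd.DataFrame, gaps: list[tuple[float, float]]
) -> TrialRecord:
    return TrialRecord(
        event=trial.event,
        samples=samples,
        sampling_rate_hz=trial.sampling_rate_hz,
        gaps=list(gaps),
    )


def frame_quantize(trial: TrialRecord, frame_ms: float) -> TrialRecord:
    """Emulate 40-ms manual video coding: floor sample times to the frame
    grid anchored at distractor onset, keeping the first sample per frame.
    Idempotent."""
    if trial.empty:
        return trial
    s = trial.samples
    onset = trial.distractor_onset_ms
    t = s["t_ms"].to_numpy(dtype=float)
    frames = np.floor((t - onset) / frame_ms)
    tq = onset + frames * frame_ms
    keep = np.concatenate(([True], np.diff(frames) != 0))
    out = s.loc[keep].copy().reset_index(drop=True)
    out["t_ms"] = tq[keep]
    return replace_samples(trial, out, trial.gaps)


def _gap_overlaps(gaps: Sequence[tuple[float, float]], lo: float, hi: float) -> bool:
    return any(g0 < hi and lo < g1 for g0, g1 in gaps)


def find_disengagement(trial: TrialRecord, aois: AOISet, params: ScoringParams) -> TrialScore:
    """Apply the validity rules and extract the disengagement latency.

    The latency x is the last time the gaze is inside the central AOI before
    the first transition that subsequently lands in the cued distractor AOI
    (within ``landing_window_ms`` of leaving the face), minus distractor
    onset.  See the module docstring for the rejection rules per age mode.
    """
    meta = dict(trial_index=int(trial.event["trial_index"]), condition=trial.condition)
    s = trial.samples
    if trial.empty or not s["valid"].any():
        return TrialScore(status="rejected_no_initial_fixation", **meta)
    v = s[s["valid"]]
    t = v["t_ms"].to_numpy(dtype=float)
    labels = aois.label(v["x_deg"].to_numpy(), v["y_deg"].to_numpy(), trial.distractor_side)
    onset = trial.distractor_onset_ms
    win_end = onset + params.window_end_ms

    # gaze must be on the face at trial start and at distractor onset
    if labels[0] != "C":
        return TrialScore(status="rejected_no_initial_fixation", **meta)
    pre = t <= onset
    if not pre.any() or labels[pre][-1] != "C":
        return TrialScore(status="rejected_no_initial_fixation", **meta)

    if params.age_mode == "infant8":
        # "excessive movements": too many departures from the face before
        # the distractor appears (convention; the rule has no printed number)
        pl = labels[pre]
        exits = int(np.sum((pl[:-1] == "C") & (pl[1:] != "C")))
        if exits > params.max_central_exits:
            return TrialScore(status="rejected_excess_movement", **meta)

    last_c_t = float(t[pre][(labels[pre] == "C")][-1])
    win = (t >= onset) & (t <= win_end)
    tw, lw = t[win], labels[win]

    # Walk the analysis window.  A departure from the face that returns to it
    # within the landing window is a tolerated wobble (it lowers the fixation
    # fraction); a departure that lands in the cued distractor is the
    # saccade; one that does neither is not directed at the distractor.
    dep_idx = None
    wrong_direction = False
    i = 0
    while i < len(tw):
        if lw[i] == "C":
            last_c_t = float(tw[i])
            i += 1
            continue
        t_dep = float(tw[i])
        j = i
        landed = returned = None
        while j < len(tw) and tw[j] <= t_dep + params.landing_window_ms:
            if lw[j] == "D":
                landed = j
                break
            if lw[j] == "C":
                returned = j
                break
            j += 1
        if landed is not None:
            dep_idx = i
            break
        if returned is not None:
            i = returned
            continue
        wrong_direction = True
        dep_idx = i
        break

    if dep_idx is None:
        # no departure: a timeout only if data actually reach the window end
        if params.age_mode == "toddler24" and _gap_overlaps(trial.gaps, onset, win_end):
            return TrialScore(status="rejected_gap", **meta)
        if len(tw) == 0:
            return TrialScore(status="rejected_no_initial_fixation", **meta)
        if params.age_mode == "toddler24":
            frac = float(np.mean(lw == "C"))
            if frac < params.min_fixation_fraction:
                return TrialScore(status="rejected_insufficient_fixation", **meta)
        return TrialScore(status="scorable_timeout", index=1.0, **meta)

    t_dep = float(tw[dep_idx])
    if params.age_mode == "toddler24":
        if _gap_overlaps(trial.gaps, last_c_t, t_dep):
            # the eye movement happened inside missing data
            return TrialScore(status="rejected_missing_at_saccade", **meta)
        if _gap_overlaps(trial.gaps, onset, last_c_t):
            return TrialScore(status="rejected_gap", **meta)

    if wrong_direction:
        return TrialScore(status="rejected_wrong_direction", **meta)

    x = last_c_t - onset
    if x < params.anticipatory_ms:
        return TrialScore(status="rejected_anticipatory", **meta)
    if params.age_mode == "toddler24":
        span = (tw >= onset) & (tw <= last_c_t)
        frac = float(np.mean(lw[span] == "C")) if span.any() else 0.0
        if frac < params.min_fixation_fraction:
            return TrialScore(status="rejected_insufficient_fixation", **meta)
    return TrialScore(
        status="scorable_saccade",
        latency_ms=float(x),
        index=trial_index_value(x, params),
        **meta,
    )


def condition_dwell(
    scores: Iterable[TrialScore], condition: str, params: ScoringParams
) -> ConditionScore:
    """Mean per-trial index over the scorable trials of one condition."""
    idx = [trial_index(sc, params) for sc in scores
           if sc.condition == condition and sc.scorable]
    if not idx:
        return ConditionScore(condition=condition, n_scorable=0, dwell_index=math.nan)
    return ConditionScore(condition=condition, n_scorable=len(idx),
                          dwell_index=float(np.mean(idx)))


def score_trial(trial: TrialRecord, aois: AOISet, params: ScoringParams) -> TrialScore:
    """Full per-trial pipeline for one age mode (gap handling / frame
    quantization, then the disengagement walk)."""
    if params.age_mode == "toddler24":
        trial, _ = interpolate_gaps(trial, params.max_gap_ms)
    else:
        trial = frame_quantize(trial, params.frame_ms)
    return find_disengagement(trial, aois, params)


def score_participant(
    participant_id: str,
    trials: Sequence[TrialRecord],
    aois: AOISet,
    params: ScoringParams,
    conditions: Sequence[str] = ("happy", "fearful", "neutral_open", "neutral_closed"),
) -> ParticipantScores:
    """Score a full session and apply the >=2-scorable-per-condition rule."""
    scores = tuple(score_trial(tr, aois, params) for tr in trials)
    cond_scores = {c: condition_dwell(scores, c, params) for c in conditions}
    included = all(
        cs.n_scorable >= params.min_scorable_per_condition for cs in cond_scores.values()
    )
    return ParticipantScores(
        participant_id=participant_id,
        age_mode=params.age_mode,
        conditions=cond_scores,
        included=included,
        trial_scores=scores,
    )


def trial_score_table(
    scored: Iterable[tuple[str, str, ParticipantScores]]
) -> pd.DataFrame:
    """Long per-trial table: participant, age, trial_index, condition, status,
    latency_ms, index."""
    rows = []
    for pid, age, ps in scored:
        for sc in ps.trial_scores:
            rows.append((pid, age, sc.trial_index, sc.condition, sc.status,
                         sc.latency_ms, sc.index))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "age", "trial_index", "condition", "status",
                 "latency_ms", "index"],
    )


def participant_score_table(
    scored: Iterable[tuple[str, str, ParticipantScores]]
) -> pd.DataFrame:
    """Wide per-participant table: dwell index and n per condition, inclusion."""
    rows = []
    for pid, age, ps in scored:
        row: dict = {"participant_id": pid, "age": age, "included": ps.included}
        for c, cs in ps.conditions.items():
            row[f"dwell_{c}"] = cs.dwell_index
            row[f"n_{c}"] = cs.n_scorable
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "SCORABLE_STATUSES",
    "REJECTED_STATUSES",
    "ScoringParams",
    "TrialScore",
    "ConditionScore",
    "ParticipantScores",
    "trial_index_value",
    "trial_index",
    "interpolate_gaps",
    "frame_quantize",
    "find_disengagement",
    "condition_dwell",
    "score_trial",
    "score_participant",
    "trial_score_table",
    "participant_score_table",
]
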
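"""Trial scoring: validity rules, latency extraction, dwell index."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from overlapgaze.scoring import (
    ScoringParams,
    TrialScore,
    condition_dwell,
    find_disengagement,
    frame_quantize,
    interpolate_gaps,
    score_participant,
    score_trial,
    trial_index,
    trial_index_value,
)

from conftest import CENTER, LEFT, OFF, RIGHT, make_trial

P8 = ScoringParams.for_age("infant8")
P24 = ScoringParams.for_age("toddler24")


# ---------------------------------------------------------------------------
# independent brute-force oracle: per-sample AOI labeling + first-transition
# scan, written as plain loops from the scoring rules


def oracle_walk(trial, aois, params):
    """Returns (status, latency or None)."""
    onset = trial.distractor_onset_ms
    win_end = onset + params.window_end_ms
    pts = [
        (r.t_ms, r.x_deg, r.y_deg)
        for r in trial.samples.itertuples()
        if r.valid
    ]
    if not pts:
        return "rejected_no_initial_fixation", None

    def lab(x, y):
        if aois.central.contains(x, y):
            return "C"
        if aois.distractor(trial.distractor_side).contains(x, y):
            return "D"
        return "O"

    labs = [(t, lab(x, y)) for t, x, y in pts]
    if labs[0][1] != "C":
        return "rejected_no_initial_fixation", None
    pre = [(t, l) for t, l in labs if t <= onset]
    if not pre or pre[-1][1] != "C":
        return "rejected_no_initial_fixation", None
    if params.age_mode == "infant8":
        exits = sum(
            1 for (_, a), (_, b) in zip(pre, pre[1:]) if a == "C" and b != "C"
        )
        if exits > params.max_central_exits:
            return "rejected_excess_movement", None
    win = [(t, l) for t, l in labs if onset <= t <= win_end]
    last_c = max(t for t, l in pre if l == "C")
    dep = None
    wrong = False
    i = 0
    while i < len(win):
        t, l = win[i]
        if l == "C":
            last_c = t
            i += 1
            continue
        # departure: does it land in the distractor, return to the face
        # within the landing window, or neither?
        outcome = "lost"
        nxt = i
        for j in range(i, len(win)):
            if win[j][0] > t + params.landing_window_ms:
                break
            if win[j][1] == "D":
                outcome = "landed"
                break
            if win[j][1] == "C":
                outcome = "returned"
                nxt = j
                break
        if outcome == "landed":
            dep = t
            break
        if outcome == "returned":
            i = nxt
            continue
        dep = t
        wrong = True
        break
    gaps = trial.gaps
    if dep is None:
        if params.age_mode == "toddler24" and any(
            g0 < win_end and onset < g1 for g0, g1 in gaps
        ):
            return "rejected_gap", None
        if not win:
            return "rejected_no_initial_fixation", None
        if params.age_mode == "toddler24":
            frac = sum(l == "C" for _, l in win) / len(win)
            if frac < params.min_fixation_fraction:
                return "rejected_insufficient_fixation", None
        return "scorable_timeout", None
    if params.age_mode == "toddler24":
        if any(g0 < dep and last_c < g1 for g0, g1 in gaps):
            return "rejected_missing_at_saccade", None
        if any(g0 < last_c and onset < g1 for g0, g1 in gaps):
            return "rejected_gap", None
    if wrong:
        return "rejected_wrong_direction", None
    x = last_c - onset
    if x < params.anticipatory_ms:
        return "rejected_anticipatory", None
    if params.age_mode == "toddler24":
        span = [l for t, l in win if onset <= t <= last_c]
        frac = (sum(l == "C" for l in span) / len(span)) if span else 0.0
        if frac < params.min_fixation_fraction:
            return "rejected_insufficient_fixation", None
    return "scorable_saccade", x


def random_trial(rng, age_mode):
    """Random piecewise gaze trajectory over positions and dropouts."""
    dt = 40.0 if age_mode == "infant8" else 10.0 / 3.0
    positions = [CENTER, RIGHT, LEFT, OFF, None]
    n_seg = rng.integers(1, 7)
    cuts = np.sort(rng.uniform(0.0, 2000.0, size=n_seg - 1))
    bounds = [0.0, *cuts, 2000.0 + dt]
    segments = []
    for i in range(n_seg):
        pos = positions[rng.integers(len(positions))]
        segments.append((bounds[i], bounds[i + 1], pos))
    side = "right" if rng.random() < 0.5 else "left"
    return make_trial(segments, side=side, dt=dt)


def _compare_with_oracle(trial, aois, params):
    if params.age_mode == "toddler24":
        trial, _ = interpolate_gaps(trial, params.max_gap_ms)
    else:
        trial = frame_quantize(trial, params.frame_ms)
    got = find_disengagement(trial, aois, params)
    want_status, want_x = oracle_walk(trial, aois, params)
    assert got.status == want_status, (got, want_status)
    if want_status == "scorable_saccade":
        assert got.latency_ms == pytest.approx(want_x, abs=1e-9)
    return got.status


class TestOracleAgreement:
    @pytest.mark.parametrize("age_mode", ["infant8", "toddler24"])
    def test_scorer_matches_bruteforce_on_random_trajectories(self, aois, age_mode):
        params = ScoringParams.for_age(age_mode)
        rng = np.random.default_rng(20240915 if age_mode == "infant8" else 77)
        statuses = [
            _compare_with_oracle(random_trial(rng, age_mode), aois, params)
            for _ in range(600)
        ]
        # the sweep reaches both scorable and several rejected branches
        assert len(set(statuses)) >= 4

    def test_scorer_matches_bruteforce_on_simulated_sessions(self, aois):
        from overlapgaze.gaze_io import segment_trials
        from overlapgaze.simulate import AGE_MODE, SimParams, simulate_cohort

        cohort = simulate_cohort(SimParams(n_waking=8, n_nonwaking=8, seed=99))
        n = 0
        counts = {}
        for (pid, age), sess in sorted(cohort.sessions.items()):
            params = ScoringParams.for_age(AGE_MODE[age])
            for trial in segment_trials(sess.gaze, sess.events):
                status = _compare_with_oracle(trial, aois, params)
                counts[status] = counts.get(status, 0) + 1
                n += 1
        assert n >= 500
        assert counts.get("scorable_saccade", 0) > 200


class TestFixtures:
    def test_clean_saccade_latency_500(self, aois):
        trial = make_trial([(0.0, 1500.0, CENTER), (1500.0, 2001.0, RIGHT)])
        got = find_disengagement(trial, aois, P24)
        assert got.status == "scorable_saccade"
        assert got.latency_ms == pytest.approx(500.0, abs=10.0 / 3.0)
        assert got.index == pytest.approx((got.latency_ms - 160.0) / 840.0)

    def test_full_window_fixation_is_timeout_with_index_1(self, aois):
        trial = make_trial([(0.0, 2001.0, CENTER)])
        got = find_disengagement(trial, aois, P24)
        assert got.status == "scorable_timeout"
        assert got.index == 1.0

    def test_anticipatory_rejected_infant8(self, aois):
        trial = make_trial([(0.0, 1120.0, CENTER), (1120.0, 2001.0, RIGHT)], dt=40.0)
        got = find_disengagement(trial, aois, P8)
        assert got.status == "rejected_anticipatory"

    def test_wrong_direction_rejected(self, aois):
        trial = make_trial([(0.0, 1500.0, CENTER), (1500.0, 2001.0, LEFT)], side="right")
        got = find_disengagement(trial, aois, P24)
        assert got.status == "rejected_wrong_direction"

    def test_departure_without_landing_is_wrong_direction(self, aois):
        # a 300-ms off-screen excursion never reaches the distractor
        trial = make_trial(
            [
                (0.0, 1300.0, CENTER),
                (1300.0, 1600.0, OFF),
                (1600.0, 1900.0, CENTER),
                (1900.0, 2001.0, RIGHT),
            ]
        )
        assert find_disengagement(trial, aois, P24).status == "rejected_wrong_direction"

    def test_fixation_fraction_below_70_rejected(self, aois):
        # repeated brief wobbles off the face (each returning within the
        # landing window) push pre-saccade central fixation to ~65%
        segs = [(0.0, 1000.0, CENTER)]
        t = 1000.0
        for _ in range(4):
            segs += [(t, t + 120.0, CENTER), (t + 120.0, t + 200.0, OFF)]
            t += 200.0
        segs += [(t, 2001.0, RIGHT)]
        trial = make_trial(segs)
        got = find_disengagement(trial, aois, P24)
        assert got.status == "rejected_insufficient_fixation"

    def test_wobble_with_good_fixation_still_scorable(self, aois):
        # one brief wobble, fixation stays >= 70%
        trial = make_trial(
            [
                (0.0, 1400.0, CENTER),
                (1400.0, 1480.0, OFF),
                (1480.0, 1700.0, CENTER),
                (1700.0, 2001.0, RIGHT),
            ]
        )
        got = find_disengagement(trial, aois, P24)
        assert got.status == "scorable_saccade"
        # latency measured to the last on-face sample before the saccade
        assert got.latency_ms == pytest.approx(700.0, abs=10.0 / 3.0)

    def test_no_initial_fixation_rejected(self, aois):
        trial = make_trial([(0.0, 1100.0, OFF), (1100.0, 2001.0, CENTER)])
        assert find_disengagement(trial, aois, P24).status == "rejected_no_initial_fixation"

    def test_empty_trial_rejected(self, aois):
        trial = make_trial([(0.0, 2001.0, None)])
        assert find_disengagement(trial, aois, P24).status == "rejected_no_initial_fixation"

    def test_excess_movement_infant8(self, aois):
        # three departures from the face during the solo period
        segs = []
        t = 0.0
        for _ in range(3):
            segs += [(t, t + 120.0, CENTER), (t + 120.0, t + 240.0, OFF)]
            t += 240.0
        segs += [(t, 1500.0, CENTER), (1500.0, 2001.0, RIGHT)]
        trial = make_trial(segs, dt=40.0)
        assert find_disengagement(trial, aois, P8).status == "rejected_excess_movement"

    def test_saccade_inside_gap_rejected_toddler24(self, aois):
        trial = make_trial(
            [(0.0, 1400.0, CENTER), (1400.0, 1650.0, None), (1650.0, 2001.0, RIGHT)]
        )
        trial, report = interpolate_gaps(trial, P24.max_gap_ms)
        assert any(not g["filled"] for g in report)
        assert find_disengagement(trial, aois, P24).status == "rejected_missing_at_saccade"


class TestGapInterpolation:
    def test_short_gap_filled_and_reported(self, aois):
        trial = make_trial(
            [(0.0, 1200.0, CENTER), (1200.0, 1300.0, None), (1300.0, 2001.0, CENTER)]
        )
        out, report = interpolate_gaps(trial, 200.0)
        assert len(report) == 1 and report[0]["filled"]
        assert report[0]["extent_ms"] == pytest.approx(103.3, abs=1.0)
        assert out.samples["valid"].all()
        # interpolation is linear between the flanking positions (both at
        # center, so filled samples sit at the center too)
        assert np.allclose(out.samples["x_deg"], 0.0)

    def test_long_gap_left_unfilled(self):
        trial = make_trial(
            [(0.0, 1200.0, CENTER), (1200.0, 1450.0, None), (1450.0, 2001.0, CENTER)]
        )
        out, report = interpolate_gaps(trial, 200.0)
        assert len(report) == 1 and not report[0]["filled"]
        assert report[0]["extent_ms"] >= 200.0
        assert not out.samples["valid"].all()
        assert len(out.gaps) == 1

    def test_no_invalid_samples_identity(self):
        trial = make_trial([(0.0, 2001.0, CENTER)])
        out, report = interpolate_gaps(trial, 200.0)
        assert report == []
        pd.testing.assert_frame_equal(out.samples, trial.samples)

    def test_all_invalid_reported_untouched(self):
        trial = make_trial([(0.0, 2001.0, None)])
        out, report = interpolate_gaps(trial, 200.0)
        assert len(report) == 1 and not report[0]["filled"]
        assert not out.samples["valid"].any()


class TestFrameQuantize:
    def test_floor_to_frame_grid(self):
        trial = make_trial([(0.0, 2001.0, CENTER)], dt=10.0 / 3.0)
        # inject an off-grid sample time
        trial.samples.loc[1, "t_ms"] = 515.0 + 1000.0  # +515 ms after onset
        trial.samples.sort_values("t_ms", inplace=True)
        out = frame_quantize(trial, 40.0)
        rel = out.samples["t_ms"].to_numpy() - 1000.0
        assert np.all(np.isclose(rel % 40.0, 0.0) | np.isclose(rel % 40.0, 40.0))

    def test_idempotent(self):
        trial = make_trial([(0.0, 2001.0, CENTER)], dt=40.0)
        once = frame_quantize(trial, 40.0)
        twice = frame_quantize(once, 40.0)
        pd.testing.assert_frame_equal(once.samples, twice.samples)

    def test_quantized_latency_within_one_frame(self, aois):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.uniform(200.0, 950.0)
            trial = make_trial(
                [(0.0, 1000.0 + x + 1.0, CENTER), (1000.0 + x + 1.0, 2001.0, RIGHT)],
                dt=10.0 / 3.0,
            )
            fine = find_disengagement(trial, aois, P8)
            coarse = find_disengagement(frame_quantize(trial, 40.0), aois, P8)
            if fine.status == coarse.status == "scorable_saccade":
                assert abs(fine.latency_ms - coarse.latency_ms) < 40.0


class TestIndex:
    def test_endpoints(self):
        assert trial_index_value(160.0, P8) == 0.0
        assert trial_index_value(math.nan, P8, timeout=True) == 1.0
        assert trial_index_value(580.0, P8) == 0.5

    def test_toddler_150ms_clamps_to_zero(self):
        assert trial_index_value(155.0, P24) == 0.0

    @given(st.floats(min_value=160.0, max_value=1000.0))
    @settings(max_examples=200, deadline=None)
    def test_affine_identity_with_printed_formula(self, x):
        lhs = 1.0 - (1000.0 - x) / 840.0
        assert trial_index_value(x, P8) == pytest.approx(lhs, abs=1e-12)

    @given(
        st.lists(st.floats(min_value=100.0, max_value=1100.0), min_size=2, max_size=20)
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_bounded(self, xs):
        vals = [trial_index_value(x, P24) for x in sorted(xs)]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_rejected_status_has_no_index(self):
        sc = TrialScore(status="rejected_anticipatory")
        with pytest.raises(ValueError):
            trial_index(sc, P8)


class TestConditionDwell:
    def mk(self, status, latency=math.nan, cond="happy"):
        idx = math.nan
        if status == "scorable_timeout":
            idx = 1.0
        elif status == "scorable_saccade":
            idx = (latency - 160.0) / 840.0
        return TrialScore(status=status, latency_ms=latency, index=idx, condition=cond)

    def test_mean_of_indices(self):
        scores = [self.mk("scorable_saccade", 160.0), self.mk("scorable_timeout")]
        cs = condition_dwell(scores, "happy", P8)
        assert cs.n_scorable == 2
        assert cs.dwell_index == pytest.approx(0.5)

    def test_all_timeouts(self):
        cs = condition_dwell([self.mk("scorable_timeout")] * 6, "happy", P8)
        assert cs.n_scorable == 6 and cs.dwell_index == 1.0

    def test_rejected_excluded_from_n(self):
        scores = [self.mk("rejected_anticipatory")] * 3 + [
            self.mk("scorable_saccade", 580.0),
            self.mk("scorable_saccade", 1000.0),
        ]
        cs = condition_dwell(scores, "happy", P8)
        assert cs.n_scorable == 2

    def test_empty_condition_undefined(self):
        cs = condition_dwell([], "happy", P8)
        assert cs.n_scorable == 0 and math.isnan(cs.dwell_index)


class TestParticipantInclusion:
    def _session(self, aois, drop_condition=None, n_keep=1):
        trials = []
        conditions = ("happy", "fearful", "neutral_open", "neutral_closed")
        idx = 0
        for c in conditions:
            for j in range(6):
                if c == drop_condition and j >= n_keep:
                    segs = [(0.0, 1100.0, OFF), (1100.0, 2001.0, CENTER)]  # invalid
                else:
                    segs = [(0.0, 1500.0, CENTER), (1500.0, 2001.0, RIGHT)]
                tr = make_trial(segs, condition=c)
                tr.event["trial_index"] = idx
                idx += 1
                trials.append(tr)
        return trials

    def test_all_scorable_included(self, aois):
        ps = score_participant("p1", self._session(aois), aois, P24)
        assert ps.included
        assert all(cs.n_scorable == 6 for cs in ps.conditions.values())

    def test_single_scorable_condition_excluded(self, aois):
        ps = score_participant("p1", self._session(aois, drop_condition="happy"), aois, P24)
        assert not ps.included
        assert ps.conditions["happy"].n_scorable == 1

    def test_two_scorable_in_every_condition_suffices(self, aois):
        ps = score_participant(
            "p1", self._session(aois, drop_condition="happy", n_keep=2), aois, P24
        )
        assert ps.included


class TestOrderIndependence:
    def test_scoring_is_order_independent(self, aois):
        rng = np.random.default_rng(5)
        trials = [random_trial(rng, "toddler24") for _ in range(12)]
        for i, tr in enumerate(trials):
            tr.event["trial_index"] = i
            tr.event["condition"] = ["happy", "fearful"][i % 2]
        a = score_participant("p", trials, aois, P24)
        b = score_participant("p", trials[::-1], aois, P24)
        for c in ("happy", "fearful"):
            assert a.conditions[c].n_scorable == b.conditions[c].n_scorable
            if a.conditions[c].n_scorable:
                assert a.conditions[c].dwell_index == pytest.approx(
                    b.conditions[c].dwell_index
                )
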
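"""Synthetic cohort generator for the night-awakening Overlap-task study.

Emulates the structure of a two-group infant cohort: a waking group (>=3
parent-reported signaled night awakenings per night at 8 months) and a
nonwaking group (<=1), each child contributing a 24-trial Overlap session at
8 months (25 Hz video-frame resolution) and — with 83% retention — at 24
months (300 Hz eye tracking), plus a 42-item BITSEA questionnaire at 24
months and a demographics table.

The per-trial generative model is a censored latent dwell index: for child j
in group g, condition c,

    s = m[g, c] + u_j + e,   u_j ~ N(0, sigma_subject^2),  e ~ N(0, sigma_trial^2)

with the location m calibrated (:func:`calibrate_censored_mean`) so that
E[clamp(s, 0, 1)] equals the target condition mean after censoring: s >= 1
is emitted as a no-saccade (timeout) trial, s < 0 as a saccade at the 160-ms
normalization floor, and otherwise as a saccade at x = 160 + 840 s ms
(snapped to the session's sample grid so the scoring pipeline can recover
the ground truth exactly).  Unscorable trials are injected at rate
``p_invalid`` by violating one validity rule chosen uniformly.

BITSEA items are discretized from per-domain latent traits (unit variance; a
shared child factor with loading 0.3, a group shift per effect size, and for
competence a correlation with the child's 8-month happy-condition latent).
Response thresholds and item-noise levels were calibrated once against the
published domain means/SDs and internal consistencies, and are frozen as
defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import bitsea as bitsea_mod
from .gaze_io import EVENT_COLUMNS, write_event_log, write_gaze_log
from .protocol import CONDITIONS, ProtocolSpec, build_aois, generate_schedule

GROUPS = ("waking", "nonwaking")
AGES = (8, 24)
AGE_MODE = {8: "infant8", 24: "toddler24"}

#: Condition-mean dwell indices per group (constant over age); the group x
#: emotion pattern of the study's results.
DEFAULT_MU: dict[tuple[str, str], float] = {
    ("waking", "fearful"): 0.611,
    ("waking", "happy"): 0.550,
    ("waking", "neutral_open"): 0.541,
    ("waking", "neutral_closed"): 0.505,
    ("nonwaking", "fearful"): 0.646,
    ("nonwaking", "happy"): 0.602,
    ("nonwaking", "neutral_open"): 0.510,
    ("nonwaking", "neutral_closed"): 0.551,
}

#: Standardized group shifts on the BITSEA domain scores (waking - nonwaking).
DEFAULT_BITSEA_EFFECTS: dict[str, float] = {
    "dysregulation": 0.72,
    "competence": -0.48,
    "internalizing": 0.38,
    "externalizing": 0.19,
}

#: Per-group covariate frequencies (demographics table of the study).
DEFAULT_COVARIATE_FREQS: dict[str, dict[str, object]] = {
    "waking": {
        "p_boy": 43 / 76,
        "p_breastfeeding": (43 / 73, 16 / 73, 14 / 73),  # breast / mixed / formula
        "p_co_sleeping": 29 / 65,
        "p_falls_asleep_alone": 23 / 72,
        "p_prevention_center": 43 / 77,
    },
    "nonwaking": {
        "p_boy": 35 / 69,
        "p_breastfeeding": (20 / 60, 11 / 60, 29 / 60),
        "p_co_sleeping": 4 / 54,
        "p_falls_asleep_alone": 41 / 61,
        "p_prevention_center": 28 / 69,
    },
}


class CalibrationError(ValueError):
    """Target mean unreachable under the censoring model."""


# ---------------------------------------------------------------------------
# censored-mean calibration


def censored_normal_mean(m: float, sigma: float) -> float:
    """E[clamp(X, 0, 1)] for X ~ Normal(m, sigma^2) (closed form)."""
    if sigma == 0:
        return min(1.0, max(0.0, m))
    a = (0.0 - m) / sigma
    b = (1.0 - m) / sigma
    Phi_a, Phi_b = stats.norm.cdf(a), stats.norm.cdf(b)
    phi_a, phi_b = stats.norm.pdf(a), stats.norm.pdf(b)
    return float((1.0 - Phi_b) + m * (Phi_b - Phi_a) - sigma * (phi_b - phi_a))


def calibrate_censored_mean(target_mean: float, sigma: float, tol: float = 1e-9) -> float:
    """Location m such that the censored mean equals ``target_mean``.

    Monotone root-finding; with sigma = 0 the identity m = target_mean.
    """
    if not (0 < target_mean < 1):
        raise CalibrationError(f"target mean {target_mean} outside (0, 1)")
    if sigma < 0:
        raise CalibrationError("sigma must be nonnegative")
    if sigma == 0:
        return float(target_mean)
    lo, hi = -10 * sigma - 1.0, 10 * sigma + 2.0
    f = lambda m: censored_normal_mean(m, sigma) - target_mean
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(f"no root for target {target_mean}, sigma {sigma}")
    return float(optimize.brentq(f, lo, hi, xtol=tol))


# ---------------------------------------------------------------------------
# BITSEA item model


@dataclass(frozen=True)
class ItemModel:
    """Graded-threshold discretization of a unit-variance latent trait:
    Y = 0/1/2 as T + sigma_item * e crosses tau1, tau2."""

    tau1: float
    tau2: float
    sigma_item: float


# Frozen calibration against the published domain means/SDs and alphas
# (Gauss-Hermite moment matching; see docs/methods.md).
DOMAIN_ITEM_MODELS: dict[str, ItemModel] = {
    "internalizing": ItemModel(tau1=2.0847, tau2=10.0847, sigma_item=1.8816),
    "externalizing": ItemModel(tau1=0.1059, tau2=2.7929, sigma_item=1.4680),
    "competence": ItemModel(tau1=-4.8733, tau2=-1.0881, sigma_item=1.7970),
    "dysregulation": ItemModel(tau1=0.6943, tau2=5.0461, sigma_item=1.4765),
    "other_problem": ItemModel(tau1=1.6816, tau2=5.2101, sigma_item=1.6910),
}
#: sleep items (dysregulation) have much higher endorsement than the rest
SLEEP_ITEM_MODEL = ItemModel(tau1=0.4744, tau2=1.3329, sigma_item=1.4765)

#: loading of the single shared child factor on every domain latent
CHILD_FACTOR_LOADING = 0.3

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(61)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _item_cond_moments(T: np.ndarray, model: ItemModel) -> tuple[np.ndarray, np.ndarray]:
    """E[Y|T], E[Y^2|T] for the graded item given latent values T."""
    q1 = stats.norm.cdf((T - model.tau1) / model.sigma_item)
    q2 = stats.norm.cdf((T - model.tau2) / model.sigma_item)
    return q1 + q2, q1 + 3 * q2


def domain_sum_moments(shift: float, models: list[ItemModel]) -> tuple[float, float, float]:
    """(mean, variance, alpha) of the domain item-sum when the latent is
    N(shift, 1); items conditionally independent given the latent."""
    T = shift + _GH_NODES
    ES = np.zeros_like(T)
    VS = np.zeros_like(T)
    item_vars = []
    for m in models:
        ey, ey2 = _item_cond_moments(T, m)
        ES += ey
        VS += ey2 - ey**2
        mu_item = float(_GH_WEIGHTS @ ey)
        item_vars.append(float(_GH_WEIGHTS @ ey2) - mu_item**2)
    mean = float(_GH_WEIGHTS @ ES)
    var = float(_GH_WEIGHTS @ (VS + ES**2)) - mean**2
    k = len(models)
    alpha = k / (k - 1) * (1 - sum(item_vars) / var) if k > 1 else math.nan
    return mean, var, alpha


def domain_models(domain: str) -> list[ItemModel]:
    base = DOMAIN_ITEM_MODELS[domain]
    k = bitsea_mod.DOMAIN_SIZES[domain]
    if domain == "dysregulation":
        return [base] * (k - 2) + [SLEEP_ITEM_MODEL] * 2
    return [base] * k


def solve_latent_shift(d: float, domain: str) -> float:
    """Latent group shift delta whose expected domain-sum effect size
    (mean difference over pooled SD) equals d."""
    if d == 0:
        return 0.0
    models = domain_models(domain)

    def f(delta: float) -> float:
        m1, v1, _ = domain_sum_moments(+delta / 2, models)
        m0, v0, _ = domain_sum_moments(-delta / 2, models)
        return (m1 - m0) / math.sqrt((v1 + v0) / 2) - d

    return float(optimize.brentq(f, -4.0, 4.0))


# ---------------------------------------------------------------------------
# simulation parameters


@dataclass(frozen=True)
class SimParams:
    """Generative parameters; defaults are the study's conditions."""

    n_waking: int = 77
    n_nonwaking: int = 69
    retention_24m: float = 0.83
    awakening_mean: dict[str, float] = field(
        default_factory=lambda: {"waking": 3.8, "nonwaking": 0.9}
    )
    mu: dict[tuple[str, str], float] = field(default_factory=lambda: dict(DEFAULT_MU))
    age_trend: float = 0.0  # optional additive shift of mu at 24 months
    sigma_subject: float = 0.10
    sigma_trial: float = 0.25
    p_invalid: float = 0.10
    p_gap: float = 0.03  # extra >200-ms gap rate at 24 months
    bitsea_domain_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BITSEA_EFFECTS)
    )
    rho_happy_competence: float = 0.337
    covariate_freqs: dict[str, dict[str, object]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_COVARIATE_FREQS.items()}
    )
    sampling_hz_24m: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.retention_24m, self.p_invalid, self.p_gap):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        for key, m in self.mu.items():
            if not (0 < m < 1):
                raise ValueError(f"mu{key} must lie in (0, 1)")
        if self.sigma_subject < 0 or self.sigma_trial < 0:
            raise ValueError("SDs must be nonnegative")
        rho = self.rho_happy_competence
        if rho**2 + CHILD_FACTOR_LOADING**2 > 1:
            raise ValueError("rho_happy_competence too large for the factor model")


@dataclass
class Session:
    age: int
    gaze: pd.DataFrame
    events: pd.DataFrame
    sampling_rate_hz: float


@dataclass
class SyntheticCohort:
    """Everything the pipeline consumes plus the generating ground truth."""

    params: SimParams
    demographics: pd.DataFrame  # one row per child
    sessions: dict[tuple[str, int], Session]  # (participant_id, age) -> session
    responses: pd.DataFrame | None  # BITSEA item responses (retained children)
    ground_truth_trials: pd.DataFrame
    ground_truth_children: pd.DataFrame

    def write(self, outdir: str | Path) -> list[Path]:
        """Emit the cohort as the package's text formats; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gaze_dir = outdir / "gaze"
        gaze_dir.mkdir(exist_ok=True)
        paths = []
        for (pid, age), sess in sorted(self.sessions.items()):
            g = gaze_dir / f"{pid}_{age}m_gaze.tsv"
            e = gaze_dir / f"{pid}_{age}m_events.tsv"
            write_gaze_log(sess.gaze, g)
            write_event_log(sess.events, e)
            paths += [g, e]
        for name, df in [
            ("demographics.tsv", self.demographics),
            ("bitsea_responses.tsv", self.responses),
            ("ground_truth_trials.tsv", self.ground_truth_trials),
            ("ground_truth_children.tsv", self.ground_truth_children),
        ]:
            if df is None:
                continue
            p = outdir / name
            df.to_csv(p, sep="\t", index=(name == "bitsea_responses.tsv"),
                      index_label="participant_id" if name == "bitsea_responses.tsv" else None)
            paths.append(p)
        return paths


# ---------------------------------------------------------------------------
# gaze-stream emission


def _session_grids(age: int, params: SimParams) -> tuple[float, int]:
    """(trial span ms, steps) of the per-trial sample grid."""
    span = 2000.0  # 1000 ms central solo + 1000 ms analysis window
    if age == 8:
        return span, 50  # 40-ms video frames
    n = int(round(span * params.sampling_hz_24m / 1000.0))
    return span, n


def _emit_trial_samples(
    rel_grid: np.ndarray,
    onset_rel: float,
    x_ms: float | None,
    violation: str,
    gap_start_rel: float | None,
    aoi_centers: dict[str, tuple[float, float]],
    side: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positions and validity for one trial on the relative time grid.

    ``x_ms`` is the grid-snapped disengagement latency (None = timeout);
    ``violation`` in {"none", "late_fixation", "wrong_direction",
    "anticipatory", "long_gap"}; anticipatory trials carry their (short)
    latency in x_ms.
    """
    n = len(rel_grid)
    jitter = rng.normal(0.0, 0.6, size=(n, 2)).clip(-1.8, 1.8)
    cx, cy = aoi_centers["central"]
    x = np.full(n, cx) + jitter[:, 0]
    y = np.full(n, cy) + jitter[:, 1]
    valid = np.ones(n, dtype=bool)
    target = aoi_centers[side] if violation != "wrong_direction" else (
        aoi_centers["left" if side == "right" else "right"]
    )
    if x_ms is not None:
        after = rel_grid > onset_rel + x_ms
        x[after] = target[0] + jitter[after, 0]
        y[after] = target[1] + jitter[after, 1]
    if violation == "late_fixation":
        pre = rel_grid <= onset_rel + 80.0
        x[pre] = 0.0 + jitter[pre, 0]
        y[pre] = -22.0 + jitter[pre, 1]
    if violation == "long_gap" and gap_start_rel is not None:
        gap = (rel_grid > gap_start_rel) & (rel_grid < gap_start_rel + 260.0)
        valid[gap] = False
    return x, y, valid


def _simulate_session(
    pid: str,
    age: int,
    group: str,
    u_j: float,
    params: SimParams,
    rng: np.random.Generator,
    schedule_seed: int,
    aoi_centers: dict[str, tuple[float, float]],
    locations: dict[tuple[str, int, str], float],
    emit_gaze: bool,
) -> tuple[Session | None, list[dict]]:
    spec = ProtocolSpec()
    schedule = generate_schedule(spec, schedule_seed)
    span, steps = _session_grids(age, params)
    rel_grid = np.linspace(0.0, span, steps + 1)
    onset_rel = 1000.0
    iti = span + 3000.0
    anticip = {"infant8": 160.0, "toddler24": 150.0}[AGE_MODE[age]]
    truth_rows = []
    all_t, all_x, all_y, all_v = [], [], [], []
    events = []
    for plan in schedule:
        cond = plan.condition
        m = locations[(group, age, cond)]
        s = m + u_j + (rng.normal(0.0, params.sigma_trial) if params.sigma_trial > 0 else 0.0)
        # censoring
        if s >= 1.0:
            x_true: float | None = None  # timeout
        elif s < 0.0:
            x_true = 160.0
        else:
            x_true = 160.0 + 840.0 * s
        # snap to the session sample grid
        if x_true is not None:
            j = int(round((onset_rel + x_true) / (span / steps)))
            j = min(max(j, 0), steps)
            x_true = float(rel_grid[j] - onset_rel)
        violation = "none"
        gap_start = None
        if rng.random() < params.p_invalid:
            choices = ["late_fixation", "wrong_direction", "anticipatory"]
            if age == 24:
                choices.append("long_gap")
            violation = choices[rng.integers(len(choices))]
        elif age == 24 and rng.random() < params.p_gap:
            violation = "long_gap"
        x_emit = x_true
        if violation == "anticipatory":
            j = int(round((onset_rel + rng.uniform(40.0, anticip - 41.0)) / (span / steps)))
            x_emit = float(rel_grid[j] - onset_rel)
        if violation == "long_gap":
            if x_true is None:
                gap_start = onset_rel + rng.uniform(100.0, 700.0)
            else:
                gap_start = onset_rel + max(x_true - rng.uniform(150.0, 230.0), 10.0)
        if violation == "wrong_direction":
            x_emit = 500.0  # a saccade must exist (and land) to go the wrong way
        central_onset = 500.0 + plan.index * iti
        events.append(
            (plan.index, cond, central_onset, central_onset + onset_rel, plan.distractor_side)
        )
        truth_rows.append(
            dict(
                participant_id=pid,
                group=group,
                age=age,
                trial_index=plan.index,
                condition=cond,
                latent=s,
                true_latency_ms=(math.nan if x_true is None else x_true),
                true_index=float(min(1.0, max(0.0, s))),
                injected=violation,
            )
        )
        if emit_gaze:
            tx, ty, tv = _emit_trial_samples(
                rel_grid, onset_rel, x_emit, violation, gap_start,
                aoi_centers, plan.distractor_side, rng,
            )
            all_t.append(central_onset + rel_grid)
            all_x.append(tx)
            all_y.append(ty)
            all_v.append(tv)
    session = None
    if emit_gaze:
        gaze = pd.DataFrame(
            {
                "t_ms": np.concatenate(all_t),
                "x_deg": np.concatenate(all_x),
                "y_deg": np.concatenate(all_y),
                "valid": np.concatenate(all_v),
            }
        )
        ev = pd.DataFrame(events, columns=EVENT_COLUMNS)
        rate = 25.0 if age == 8 else params.sampling_hz_24m
        session = Session(age=age, gaze=gaze, events=ev, sampling_rate_hz=rate)
    return session, truth_rows


def _truncated_poisson(rng: np.random.Generator, mean: float, group: str) -> int:
    for _ in range(10_000):
        k = int(rng.poisson(mean))
        if group == "waking" and k >= 3:
            return k
        if group == "nonwaking" and k <= 1:
            return k
    raise RuntimeError("truncated Poisson sampling failed")


def simulate_cohort(params: SimParams, emit_gaze: bool = True) -> SyntheticCohort:
    """Generate a full synthetic cohort (bit-identical under a fixed seed).

    With ``emit_gaze=False`` only demographics, ground truth and BITSEA
    responses are produced (fast path for large-n statistical checks).
    """
    root = np.random.SeedSequence(params.seed)
    child_seeds = root.spawn(params.n_waking + params.n_nonwaking)
    aois = build_aois(ProtocolSpec())
    centers = {
        "central": aois.central.center,
        "left": aois.distractor_left.center,
        "right": aois.distractor_right.center,
    }
    shifts = {
        d: solve_latent_shift(params.bitsea_domain_effects.get(d, 0.0), d)
        for d in bitsea_mod.DOMAIN_SIZES
    }
    sigma_tot = math.hypot(params.sigma_subject, params.sigma_trial)
    locations = {
        (g, age, c): (
            calibrate_censored_mean(
                params.mu[(g, c)] + (params.age_trend if age == 24 else 0.0), sigma_tot
            )
            if sigma_tot > 0
            else params.mu[(g, c)] + (params.age_trend if age == 24 else 0.0)
        )
        for g in GROUPS
        for age in AGES
        for c in CONDITIONS
    }
    instrument = bitsea_mod.default_instrument()
    demo_rows, truth_trials, truth_children = [], [], []
    sessions: dict[tuple[str, int], Session] = {}
    resp_rows: dict[str, dict[str, int]] = {}
    groups = ["waking"] * params.n_waking + ["nonwaking"] * params.n_nonwaking
    for i, (group, seed_i) in enumerate(zip(groups, child_seeds)):
        pid = f"P{i + 1:04d}"
        rng = np.random.default_rng(seed_i)
        freqs = params.covariate_freqs[group]
        awaken = _truncated_poisson(rng, params.awakening_mean[group], group)
        u_j = rng.normal(0.0, params.sigma_subject) if params.sigma_subject > 0 else 0.0
        retained = bool(rng.random() < params.retention_24m)
        demo_rows.append(
            dict(
                participant_id=pid,
                group=group,
                awakenings=awaken,
                sex=("boy" if rng.random() < freqs["p_boy"] else "girl"),
                breastfeeding=["breast", "mixed", "formula"][
                    int(rng.choice(3, p=np.asarray(freqs["p_breastfeeding"])
                                   / np.sum(freqs["p_breastfeeding"])))
                ],
                co_sleeping=int(rng.random() < freqs["p_co_sleeping"]),
                falls_asleep_alone=int(rng.random() < freqs["p_falls_asleep_alone"]),
                healthcare_center=(
                    "prevention" if rng.random() < freqs["p_prevention_center"] else "control"
                ),
                cesd=round(max(0.0, rng.normal(10.0, 7.0)), 1),
                stai=round(max(20.0, rng.normal(35.0, 9.0)), 1),
                retained_24m=int(retained),
            )
        )
        schedule_seeds = rng.integers(0, 2**31 - 1, size=2)
        for age, sched_seed in zip(AGES, schedule_seeds):
            if age == 24 and not retained:
                continue
            sess, rows = _simulate_session(
                pid, age, group, u_j, params, rng, int(sched_seed), centers,
                locations, emit_gaze,
            )
            truth_trials.extend(rows)
            if sess is not None:
                sessions[(pid, age)] = sess
        # --- BITSEA latents (24 months) ---
        F = rng.normal()
        H = (u_j / params.sigma_subject) if params.sigma_subject > 0 else rng.normal()
        sign = +0.5 if group == "waking" else -0.5
        rho = params.rho_happy_competence
        lam = CHILD_FACTOR_LOADING
        latents = {}
        for domain in bitsea_mod.DOMAIN_SIZES:
            if domain == "competence":
                resid = math.sqrt(max(0.0, 1.0 - rho**2 - lam**2))
                T = shifts[domain] * sign + rho * H + lam * F + resid * rng.normal()
            else:
                resid = math.sqrt(1.0 - lam**2)
                T = shifts[domain] * sign + lam * F + resid * rng.normal()
            latents[domain] = T
        truth_children.append(
            dict(
                participant_id=pid,
                group=group,
                u=u_j,
                happy_latent=H,
                child_factor=F,
                retained_24m=int(retained),
                **{f"T_{d}": latents[d] for d in bitsea_mod.DOMAIN_SIZES},
            )
        )
        if retained:
            resp = {}
            for it in instrument.items:
                model = SLEEP_ITEM_MODEL if it.is_sleep_item else DOMAIN_ITEM_MODELS[it.domain]
                xi = latents[it.domain] + model.sigma_item * rng.normal()
                resp[it.item_id] = int(xi >= model.tau1) + int(xi >= model.tau2)
            resp_rows[pid] = resp
    demographics = pd.DataFrame(demo_rows)
    responses = (
        pd.DataFrame.from_dict(resp_rows, orient="index")[instrument.all_ids]
        if resp_rows
        else None
    )
    return SyntheticCohort(
        params=params,
        demographics=demographics,
        sessions=sessions,
        responses=responses,
        ground_truth_trials=pd.DataFrame(truth_trials),
        ground_truth_children=pd.DataFrame(truth_children),
    )


__all__ = [
    "GROUPS",
    "AGES",
    "AGE_MODE",
    "DEFAULT_MU",
    "DEFAULT_BITSEA_EFFECTS",
    "DEFAULT_COVARIATE_FREQS",
    "DOMAIN_ITEM_MODELS",
    "SLEEP_ITEM_MODEL",
    "CHILD_FACTOR_LOADING",
    "ItemModel",
    "SimParams",
    "Session",
    "SyntheticCohort",
    "CalibrationError",
    "censored_normal_mean",
    "calibrate_censored_mean",
    "domain_sum_moments",
    "domain_models",
    "solve_latent_shift",
    "simulate_cohort",
]
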
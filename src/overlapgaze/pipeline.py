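"""End-to-end orchestration: simulate -> score gaze -> score BITSEA -> analyze.

These functions operate on in-memory objects and are shared by the CLI and by
reproduction scripts; the CLI adds file I/O and manifests around them.
"""

from __future__ import annotations


import pandas as pd

from . import bitsea as bitsea_mod
from . import stats as stats_mod
from .gaze_io import segment_trials
from .protocol import CONDITIONS, ProtocolSpec, build_aois
from .scoring import (
    ScoringParams,
    participant_score_table,
    score_participant,
    trial_score_table,
)
from .simulate import AGE_MODE, SimParams, SyntheticCohort, simulate_cohort


def score_cohort_gaze(
    cohort: SyntheticCohort, spec: ProtocolSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full gaze-scoring pipeline over every session of a cohort.

    Returns (per-trial score table, per-participant wide table).  The wide
    table carries group, age, per-condition dwell indices and n, and the
    >=2-scorable-per-condition inclusion flag.
    """
    spec = spec or ProtocolSpec()
    aois = build_aois(spec)
    group_of = dict(
        zip(cohort.demographics["participant_id"], cohort.demographics["group"])
    )
    scored = []
    for (pid, age), sess in sorted(cohort.sessions.items()):
        params = ScoringParams.for_age(AGE_MODE[age])
        trials = segment_trials(
            sess.gaze, sess.events, window_end_ms=spec.window_end_ms,
            sampling_rate_hz=sess.sampling_rate_hz,
        )
        ps = score_participant(pid, trials, aois, params, conditions=spec.conditions)
        scored.append((pid, age, ps))
    trial_table = trial_score_table(scored)
    wide = participant_score_table(scored)
    wide.insert(1, "group", wide["participant_id"].map(group_of))
    return trial_table, wide


def long_dwell_table(wide: pd.DataFrame, conditions=CONDITIONS) -> pd.DataFrame:
    """Included participants only, one row per participant x age x condition."""
    rows = []
    for r in wide.itertuples():
        if not r.included:
            continue
        for c in conditions:
            rows.append(
                dict(
                    participant_id=r.participant_id,
                    group=r.group,
                    age=int(r.age),
                    condition=c,
                    dwell_index=getattr(r, f"dwell_{c}"),
                )
            )
    df = pd.DataFrame(rows)
    return df.dropna(subset=["dwell_index"]) if len(df) else df


def dwell_wide_by_age(long_table: pd.DataFrame) -> pd.DataFrame:
    """Participant-level wide table with dwell_{condition}_{age}m columns."""
    piv = long_table.pivot_table(
        index=["participant_id", "group"],
        columns=["condition", "age"],
        values="dwell_index",
        aggfunc="first",
        observed=True,
    )
    piv.columns = [f"dwell_{c}_{a}m" for c, a in piv.columns]
    return piv.reset_index()


def analyze_cohort(
    long_table: pd.DataFrame,
    domain_scores: pd.DataFrame,
    demographics: pd.DataFrame,
    covariates: list[str] | None = None,
) -> dict[str, object]:
    """Group-level analysis mirroring the study's statistical plan.

    Returns a dict with the mixed-model result, BITSEA t-tests (including
    the sleep-items-removed dysregulation row), the dwell x domain Pearson
    correlation table, and the demographics chi-square table.
    """
    lmm = stats_mod.fit_dwell_lmm(long_table, covariates=covariates)

    group_of = dict(zip(demographics["participant_id"], demographics["group"]))
    dom = domain_scores.copy()
    dom["group"] = [group_of.get(pid) for pid in dom.index]
    t_rows = []
    for domain in list(bitsea_mod.SCORED_DOMAINS) + ["dysregulation_no_sleep"]:
        a = dom.loc[dom["group"] == "waking", domain].to_numpy(dtype=float)
        b = dom.loc[dom["group"] == "nonwaking", domain].to_numpy(dtype=float)
        res = stats_mod.ttest_independent(a, b, variant="auto")
        t_rows.append(
            dict(domain=domain, t=res.t, df=res.df, p=res.p, d=res.d,
                 variant=res.variant, m_waking=res.m1, sd_waking=res.sd1,
                 n_waking=res.n1, m_nonwaking=res.m2, sd_nonwaking=res.sd2,
                 n_nonwaking=res.n2)
        )
    bitsea_tests = pd.DataFrame(t_rows)

    wide = dwell_wide_by_age(long_table)
    merged = wide.merge(
        dom.drop(columns=["group"]), left_on="participant_id", right_index=True,
        how="inner",
    )
    dwell_cols = [c for c in merged.columns if c.startswith("dwell_")]
    domain_cols = ["internalizing", "externalizing", "dysregulation_no_sleep", "competence"]
    correlations = stats_mod.pearson_correlations(merged, dwell_cols, domain_cols)

    chi_rows = []
    for var in ("co_sleeping", "falls_asleep_alone"):
        if var not in demographics.columns:
            continue
        tab = pd.crosstab(demographics["group"], demographics[var])
        if tab.shape == (2, 2):
            x2, dfree, p = stats_mod.chi_square_2x2(tab.to_numpy())
            chi_rows.append(dict(variable=var, chi2=x2, df=dfree, p=p,
                                 n=int(tab.to_numpy().sum())))
    chi_table = pd.DataFrame(chi_rows)

    return dict(lmm=lmm, bitsea_tests=bitsea_tests, correlations=correlations,
                chi_square=chi_table)


def run_pipeline(params: SimParams) -> dict[str, object]:
    """Simulate a cohort and push it through scoring and analysis."""
    cohort = simulate_cohort(params)
    trial_table, wide = score_cohort_gaze(cohort)
    long_table = long_dwell_table(wide)
    domains = bitsea_mod.score_domains(cohort.responses)
    results = analyze_cohort(long_table, domains, cohort.demographics)
    results.update(cohort=cohort, trial_table=trial_table, wide=wide,
                   long_table=long_table, domain_scores=domains)
    return results


__all__ = [
    "score_cohort_gaze",
    "long_dwell_table",
    "dwell_wide_by_age",
    "analyze_cohort",
    "run_pipeline",
]
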
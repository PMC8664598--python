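"""Group-level inference: mixed model for dwell indices, t-tests, chi-square,
Pearson correlations.

The longitudinal dwell data (two ages within child, four emotion conditions,
two awakening groups between children) are analyzed with a linear mixed model
with a child-level random intercept.  The screening fixed-effect structure is
group + age + emotion + group:emotion + group:age + group:age:emotion; the
random-effect ("covariance") structure is selected by AIC over a small
candidate set.  Significant factors are followed up with Bonferroni-corrected
pairwise comparisons reported with Cohen's d.

BITSEA domain differences use independent-samples t-tests (pooled by
default; Welch is auto-selected when a Levene pretest rejects variance
homogeneity at .05).  Demographic 2x2 tables use the Pearson chi-square
without continuity correction — the convention pinned by reproducing the
published co-sleeping and falling-asleep-alone statistics exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.formula.api as smf
from patsy import dmatrix

CONDITION_ORDER = ("happy", "fearful", "neutral_open", "neutral_closed")


class DegenerateFitError(ValueError):
    """Response has no usable variation for the requested model."""


# ---------------------------------------------------------------------------
# t-tests


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    d: float
    variant: str  # "pooled" | "welch"
    m1: float
    sd1: float
    n1: int
    m2: float
    sd2: float
    n2: int


def ttest_from_summaries(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> TTestResult:
    """Independent-samples t-test from group summaries.

    Pooled: t = (m1-m2)/(s_p sqrt(1/n1+1/n2)) with df = n1+n2-2 and Cohen's
    d = (m1-m2)/s_p.  Welch: Satterthwaite df; d keeps the pooled-SD
    denominator.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    s_p = math.sqrt(sp2)
    d = (m1 - m2) / s_p
    if variant == "pooled":
        df = n1 + n2 - 2
        t = (m1 - m2) / (s_p * math.sqrt(1 / n1 + 1 / n2))
    elif variant == "welch":
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        t = (m1 - m2) / math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p), d=float(d),
                       variant=variant, m1=m1, sd1=sd1, n1=n1, m2=m2, sd2=sd2, n2=n2)


def ttest_independent(
    a: np.ndarray, b: np.ndarray, variant: str = "auto"
) -> TTestResult:
    """t-test on raw vectors; ``variant='auto'`` picks Welch when a Levene
    pretest rejects homogeneity of variance at .05."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if variant == "auto":
        _, p_lev = sps.levene(a, b)
        variant = "welch" if p_lev < 0.05 else "pooled"
    return ttest_from_summaries(
        float(a.mean()), float(a.std(ddof=1)), len(a),
        float(b.mean()), float(b.std(ddof=1)), len(b),
        variant=variant,
    )


# ---------------------------------------------------------------------------
# chi-square


def chi_square_2x2(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square for a 2x2 table, no continuity correction:
    X^2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (2, 2) or (c < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    a, b = c[0]
    cc, d = c[1]
    n = c.sum()
    margins = [(a + b), (cc + d), (a + cc), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("zero margin in 2x2 table")
    x2 = n * (a * d - b * cc) ** 2 / np.prod(margins)
    p = sps.chi2.sf(x2, df=1)
    return float(x2), 1, float(p)


# ---------------------------------------------------------------------------
# Bonferroni post hocs


def bonferroni_pairwise(comparisons: pd.DataFrame, family_size: int | None = None) -> pd.DataFrame:
    """Adjust a table of pairwise comparisons: p_adj = min(1, m * p_raw).

    ``family_size`` defaults to the number of rows (the family).
    """
    if len(comparisons) == 0:
        raise ValueError("empty comparison family")
    m = family_size if family_size is not None else len(comparisons)
    out = comparisons.copy()
    out["p_adj"] = np.minimum(1.0, m * out["p_raw"])
    return out


# ---------------------------------------------------------------------------
# linear mixed model


@dataclass
class LMMResult:
    fixed_effects: pd.DataFrame  # effect, F, df_num, df_den, p
    emmeans: pd.DataFrame  # group/age/emotion margins and cells: estimate, se
    pairwise: pd.DataFrame  # Bonferroni-adjusted emotion contrasts
    covariance_structure: str
    aic: float
    candidate_aics: dict[str, float]
    var_subject: float
    var_resid: float
    covariate_tests: pd.DataFrame | None = None
    model_result: object = field(default=None, repr=False)


_FIXED_TERMS = [
    "C(group)",
    "C(age)",
    "C(emotion)",
    "C(group):C(age)",
    "C(group):C(emotion)",
    "C(group):C(age):C(emotion)",
]

_CANDIDATES = {
    # random intercept only == compound-symmetric within-child covariance
    "compound_symmetry": dict(re_formula="1", vc_formula=None),
    # child intercept + random age effect: per-age covariance over ages
    "random_age": dict(re_formula="1 + C(age)", vc_formula=None),
    # heterogeneous-by-emotion child effects
    "emotion_components": dict(re_formula="1", vc_formula={"emo": "0 + C(emotion)"}),
}


def _formula(covariates: list[str] | None) -> str:
    rhs = " + ".join(_FIXED_TERMS + list(covariates or []))
    return f"dwell_index ~ {rhs}"


def _wald_F(result, names: list[str], term: str, df_den: float) -> tuple[float, float, float]:
    """Joint Wald test of all fixed-effect coefficients belonging to a term."""
    sel = [
        i for i, nm in enumerate(names)
        if _term_of(nm) == term
    ]
    if not sel:
        return math.nan, 0.0, math.nan
    params = np.asarray(result.fe_params)
    cov = np.asarray(result.cov_params())[: len(params), : len(params)]
    est = params[sel]
    if np.allclose(est, 0.0):
        return 0.0, float(len(sel)), 1.0
    V = cov[np.ix_(sel, sel)]
    W = float(est @ np.linalg.solve(V, est))
    q = len(sel)
    F = W / q
    p = sps.f.sf(F, q, df_den)
    return F, float(q), float(p)


def _term_of(coef_name: str) -> str:
    """Map a patsy coefficient name to its model term."""
    parts = coef_name.split(":")
    factors = []
    for p in parts:
        factors.append(p.split("[")[0])
    return ":".join(factors)


def fit_dwell_lmm(
    table: pd.DataFrame,
    covariates: list[str] | None = None,
    structure: str | None = None,
) -> LMMResult:
    """Fit the longitudinal dwell-index mixed model.

    ``table`` is long: participant_id, group, age, condition, dwell_index
    (included participants only; incomplete longitudinal data allowed).  Each
    candidate random-effect structure is fitted by ML and the AIC winner
    reported, unless ``structure`` names one candidate to force.  When
    ``covariates`` are given, each is screened with its own Wald test (the
    model retains them).
    """
    df = table.rename(columns={"condition": "emotion"}).copy()
    required = {"participant_id", "group", "age", "emotion", "dwell_index"}
    if not required.issubset(df.columns):
        raise ValueError(f"missing columns {sorted(required - set(df.columns))}")
    if df["group"].nunique() < 2:
        raise ValueError("need at least two groups")
    y = df["dwell_index"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise DegenerateFitError("all dwell indices identical")
    cells = df.groupby(["group", "age", "emotion"], observed=True).size()
    expected = df["group"].nunique() * df["age"].nunique() * df["emotion"].nunique()
    if len(cells) < expected:
        raise ValueError("unestimable empty cell in group x age x emotion design")
    df["emotion"] = pd.Categorical(
        df["emotion"],
        categories=[c for c in CONDITION_ORDER if c in set(df["emotion"])],
        ordered=True,
    )
    formula = _formula(covariates)

    candidates = _CANDIDATES
    if structure is not None:
        if structure not in _CANDIDATES:
            raise ValueError(f"unknown covariance structure {structure!r}")
        candidates = {structure: _CANDIDATES[structure]}
    fits: dict[str, object] = {}
    aics: dict[str, float] = {}
    for name, spec in candidates.items():
        fit = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                model = smf.mixedlm(
                    formula,
                    df,
                    groups=df["participant_id"],
                    re_formula=spec["re_formula"],
                    vc_formula=spec["vc_formula"],
                )
                fit = model.fit(reml=False, method=method, maxiter=500)
                if np.isfinite(fit.llf) and np.all(np.isfinite(np.asarray(fit.fe_params))):
                    break
                fit = None
            except (np.linalg.LinAlgError, ValueError):
                fit = None
        if fit is None:
            continue
        fits[name] = fit
        aics[name] = float(-2 * fit.llf + 2 * (fit.df_modelwc))
    if not fits:
        raise DegenerateFitError("no candidate covariance structure could be fitted")
    best = min(aics, key=aics.get)
    result = fits[best]

    names = list(result.fe_params.index)
    n_obs = len(df)
    df_den = float(n_obs - len(names))
    rows = []
    for term in _FIXED_TERMS:
        F, q, p = _wald_F(result, names, term, df_den)
        rows.append(dict(effect=term.replace("C(", "").replace(")", ""),
                         F=F, df_num=q, df_den=df_den, p=p))
    fixed = pd.DataFrame(rows)

    cov_tests = None
    if covariates:
        cov_rows = []
        for cov in covariates:
            F, q, p = _wald_F(result, names, cov, df_den)
            if math.isnan(F):  # categorical covariate coefficient names
                F, q, p = _wald_F(result, names, f"C({cov})", df_den)
            cov_rows.append(dict(covariate=cov, F=F, df_num=q, df_den=df_den, p=p))
        cov_tests = pd.DataFrame(cov_rows)

    var_subject = float(np.asarray(result.cov_re)[0, 0]) if result.cov_re.size else 0.0
    var_resid = float(result.scale)

    emmeans = _estimated_marginal_means(result, df, formula, covariates)
    pairwise = _emotion_posthocs(result, df, formula, covariates, var_subject, var_resid, df_den)

    return LMMResult(
        fixed_effects=fixed,
        emmeans=emmeans,
        pairwise=pairwise,
        covariance_structure=best,
        aic=aics[best],
        candidate_aics=aics,
        var_subject=var_subject,
        var_resid=var_resid,
        covariate_tests=cov_tests,
        model_result=result,
    )


def _design_row(
    result, df: pd.DataFrame, formula: str, covariates, fill: dict
) -> np.ndarray:
    """Fixed-effect design row for one cell: factors not fixed in ``fill``
    are averaged over their levels, covariates held at their means."""
    design_info = result.model.data.design_info
    groups = sorted(df["group"].unique())
    ages = sorted(df["age"].unique())
    emotions = list(df["emotion"].cat.categories)
    grid = dict(fill)
    for cov in covariates or []:
        grid[cov] = float(df[cov].mean())
    free = [k for k in ("group", "age", "emotion") if k not in fill]
    levels = {"group": groups, "age": ages, "emotion": emotions}
    combos = list(itertools.product(*[levels[k] for k in free])) or [()]
    mats = []
    for combo in combos:
        row = dict(grid)
        row.update(dict(zip(free, combo)))
        data = pd.DataFrame([row])
        data["emotion"] = pd.Categorical(data["emotion"], categories=emotions)
        X = dmatrix(design_info, data, return_type="dataframe")
        mats.append(X.to_numpy()[0])
    return np.mean(mats, axis=0)


def _cell_estimate(result, row: np.ndarray) -> tuple[float, float]:
    params = np.asarray(result.fe_params)
    cov = np.asarray(result.cov_params())[: len(params), : len(params)]
    est = float(row @ params)
    se = float(np.sqrt(row @ cov @ row))
    return est, se


def _estimated_marginal_means(result, df, formula, covariates) -> pd.DataFrame:
    groups = sorted(df["group"].unique())
    ages = sorted(df["age"].unique())
    emotions = list(df["emotion"].cat.categories)
    rows = []
    # emotion margins (averaged over group and age), the headline cells
    for emo in emotions:
        r = _design_row(result, df, formula, covariates, {"emotion": emo})
        est, se = _cell_estimate(result, r)
        rows.append(dict(margin="emotion", group="", age="", emotion=emo,
                         estimate=est, se=se))
    for g in groups:
        for emo in emotions:
            r = _design_row(result, df, formula, covariates, {"group": g, "emotion": emo})
            est, se = _cell_estimate(result, r)
            rows.append(dict(margin="group_x_emotion", group=g, age="", emotion=emo,
                             estimate=est, se=se))
    for g in groups:
        for a in ages:
            for emo in emotions:
                r = _design_row(result, df, formula, covariates,
                                {"group": g, "age": a, "emotion": emo})
                est, se = _cell_estimate(result, r)
                rows.append(dict(margin="cell", group=g, age=str(a), emotion=emo,
                                 estimate=est, se=se))
    return pd.DataFrame(rows)


def _emotion_posthocs(result, df, formula, covariates, var_subject, var_resid, df_den) -> pd.DataFrame:
    """Within-group emotion pairwise contrasts, Bonferroni over the 6 pairs
    per group; d = contrast / sqrt(var_subject + var_resid)."""
    groups = sorted(df["group"].unique())
    emotions = list(df["emotion"].cat.categories)
    sd_tot = math.sqrt(var_subject + var_resid)
    rows = []
    for g in groups:
        for e1, e2 in itertools.combinations(emotions, 2):
            r1 = _design_row(result, df, formula, covariates, {"group": g, "emotion": e1})
            r2 = _design_row(result, df, formula, covariates, {"group": g, "emotion": e2})
            est, se = _cell_estimate(result, r1 - r2)
            t = est / se if se > 0 else 0.0
            p_raw = 2 * sps.t.sf(abs(t), df_den) if se > 0 else 1.0
            rows.append(dict(group=g, emotion_1=e1, emotion_2=e2, estimate=est,
                             se=se, t=t, p_raw=p_raw,
                             d=(est / sd_tot if sd_tot > 0 else math.nan)))
    out = pd.DataFrame(rows)
    m = len(list(itertools.combinations(emotions, 2)))
    return pd.concat(
        [bonferroni_pairwise(out[out["group"] == g], family_size=m) for g in groups],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# correlations


def pearson_correlations(
    table: pd.DataFrame,
    dwell_columns: list[str],
    domain_columns: list[str],
    min_n: int = 3,
) -> pd.DataFrame:
    """Pairwise-complete Pearson r with unadjusted two-sided p for every
    (dwell column) x (domain column) pair."""
    rows = []
    for dc in dwell_columns:
        for bc in domain_columns:
            pair = table[[dc, bc]].dropna()
            n = len(pair)
            if n < min_n:
                rows.append(dict(dwell=dc, domain=bc, r=math.nan, n=n, p=math.nan))
                continue
            x, y = pair[dc].to_numpy(), pair[bc].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append(dict(dwell=dc, domain=bc, r=math.nan, n=n, p=math.nan))
                continue
            r, p = sps.pearsonr(x, y)
            rows.append(dict(dwell=dc, domain=bc, r=float(r), n=n, p=float(p)))
    return pd.DataFrame(rows)


__all__ = [
    "CONDITION_ORDER",
    "DegenerateFitError",
    "TTestResult",
    "LMMResult",
    "ttest_from_summaries",
    "ttest_independent",
    "chi_square_2x2",
    "bonferroni_pairwise",
    "fit_dwell_lmm",
    "pearson_correlations",
]
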
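"""Construct-validity battery for the continuous mental-health score.

Reimplements the validation workflow used on the 2014 Canadian HBSC sample:
complete-case restriction with an attrition comparison, survey-weighted
descriptives (mean, SD, skewness), weighted approximate-quartile binning of
continuous covariates, school-clustered mixed-effects group comparisons
adjusted for age band and sex (with ordinal trend tests), intraclass
correlation from the random-intercept variance components, Cohen's d effect
sizes, and the normal-approximation minimal detectable difference.

Conventions fixed here for reproducibility:

* Cohen's d pools the two group SDs **unweighted**, ``sqrt((s1^2+s2^2)/2)``;
  this is the form that reproduces the published effect sizes from the
  published group means/SDs (an n-weighted pooled SD does not).
* d is computed from the raw survey-weighted group means/SDs, not from
  model-adjusted means; positive d means the comparison group scores lower
  than the reference group.
* Weighted SD and skewness normalize by the weight total (population-moment
  definitions, no small-sample correction).
* Mixed models are fit by REML via statsmodels MixedLM, which does not
  support analytic weights, so the adjusted p-values are unweighted while
  all descriptives are weighted.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AnalysisError",
    "BinningError",
    "AGE_BANDS",
    "age_band",
    "complete_case_filter",
    "bin_quartiles",
    "weighted_mean_sd",
    "weighted_quantile",
    "skewness",
    "cohens_d",
    "cohens_d_pooled_n",
    "VarianceComponents",
    "icc",
    "fit_icc",
    "ClusteredComparison",
    "fit_clustered_comparison",
    "minimal_detectable_difference",
    "CovariateSpec",
    "default_covariates",
    "build_effect_table",
    "published_reference_table",
]


class AnalysisError(ValueError):
    """An analysis step received data it cannot operate on."""


class BinningError(AnalysisError):
    """Quartile binning on too few distinct values; treat as categorical."""


AGE_BANDS = ("<=11", "12", "13", "14", ">=15")


def age_band(age_years) -> pd.Series:
    """Band ages as <=11, 12, 13, 14, >=15 (the reporting granularity)."""
    a = pd.to_numeric(pd.Series(age_years), errors="coerce")
    lab = pd.cut(
        a, bins=[-np.inf, 11, 12, 13, 14, np.inf], labels=AGE_BANDS, right=True
    )
    return lab.astype(pd.CategoricalDtype(AGE_BANDS, ordered=True))


# ---------------------------------------------------------------------------
# complete cases & attrition
# ---------------------------------------------------------------------------

_DEFAULT_ATTRITION_VARS = ("age_years", "sex", "relative_affluence", "self_rated_health")


def complete_case_filter(
    panel: pd.DataFrame,
    analysis_vars: Sequence[str],
    attrition_vars: Sequence[str] = _DEFAULT_ATTRITION_VARS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows missing any analysis variable; report attrition.

    Returns ``(filtered, attrition)`` where the attrition report compares
    included vs excluded students on each ``attrition_vars`` entry: Welch
    t-test for numeric variables, chi-square for categoricals (computed on
    non-missing values of that variable within each side).
    """
    missing_cols = [c for c in analysis_vars if c not in panel.columns]
    if missing_cols:
        raise AnalysisError(f"analysis variables absent from panel: {missing_cols}")
    keep = panel[list(analysis_vars)].notna().all(axis=1)
    included, excluded = panel[keep], panel[~keep]
    if len(included) == 0:
        raise AnalysisError("complete-case filter removed every row")
    rows = []
    for var in attrition_vars:
        if var not in panel.columns:
            continue
        a = included[var].dropna()
        b = excluded[var].dropna()
        if len(b) == 0 or len(a) == 0:
            rows.append((var, "none", np.nan, np.nan, len(a), len(b)))
            continue
        if pd.api.types.is_numeric_dtype(panel[var]):
            stat, p = stats.ttest_ind(a, b, equal_var=False)
            test = "welch_t"
        else:
            tab = pd.crosstab(
                pd.concat([a, b]),
                np.r_[np.zeros(len(a)), np.ones(len(b))],
            )
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                rows.append((var, "chi2", np.nan, np.nan, len(a), len(b)))
                continue
            stat, p, _, _ = stats.chi2_contingency(tab)
            test = "chi2"
        rows.append((var, test, float(stat), float(p), len(a), len(b)))
    attrition = pd.DataFrame(
        rows,
        columns=["variable", "test", "statistic", "p_value", "n_included", "n_excluded"],
    )
    return included, attrition


# ---------------------------------------------------------------------------
# weighted descriptives
# ---------------------------------------------------------------------------

def _clean_wx(values, weights):
    x = np.asarray(values, dtype=float)
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape:
            raise AnalysisError("values and weights must have the same length")
    ok = ~np.isnan(x) & ~np.isnan(w)
    x, w = x[ok], w[ok]
    if x.size == 0:
        raise AnalysisError("no non-missing values")
    if (w <= 0).any():
        raise AnalysisError("weights must be positive")
    return x, w


def weighted_mean_sd(values, weights=None) -> tuple[float, float]:
    """Survey-weighted mean and SD (variance normalized by the weight sum)."""
    x, w = _clean_wx(values, weights)
    m = float(np.average(x, weights=w))
    var = float(np.average((x - m) ** 2, weights=w))
    return m, float(np.sqrt(var))


def weighted_quantile(values, q, weights=None) -> np.ndarray:
    """Inverse-CDF weighted quantile: smallest x with cumweight fraction >= q."""
    x, w = _clean_wx(values, weights)
    order = np.argsort(x, kind="mergesort")
    x, w = x[order], w[order]
    cdf = np.cumsum(w) / w.sum()
    qs = np.atleast_1d(np.asarray(q, dtype=float))
    idx = np.searchsorted(cdf, qs, side="left")
    idx = np.clip(idx, 0, x.size - 1)
    return x[idx]


def skewness(values, weights=None) -> float:
    """Weighted third standardized moment g1 = m3 / m2^{3/2}."""
    x, w = _clean_wx(values, weights)
    if x.size < 3:
        raise AnalysisError("skewness needs >=3 values")
    m = np.average(x, weights=w)
    m2 = np.average((x - m) ** 2, weights=w)
    if m2 <= 0:
        raise AnalysisError("zero variance: skewness undefined")
    m3 = np.average((x - m) ** 3, weights=w)
    return float(m3 / m2**1.5)


def bin_quartiles(
    values,
    weights=None,
    labels: tuple[str, str, str, str] = ("High", "Q2", "Q3", "Low"),
) -> pd.Categorical:
    """Approximate-quartile bins at the weighted 25/50/75th percentiles.

    ``labels`` runs from the top quartile downward ("High" = highest scores,
    i.e. most supportive / most prosocial). Ties at a cut point fall into the
    lower-score bin, so bins on discrete scales are approximate and may be
    unequal. Missing values yield missing bins.
    """
    x = np.asarray(values, dtype=float)
    distinct = np.unique(x[~np.isnan(x)])
    if distinct.size < 4:
        raise BinningError(
            f"only {distinct.size} distinct values; model this covariate as categorical"
        )
    q25, q50, q75 = weighted_quantile(values, [0.25, 0.50, 0.75], weights)
    out = np.full(x.shape, None, dtype=object)
    out[x <= q25] = labels[3]
    out[(x > q25) & (x <= q50)] = labels[2]
    out[(x > q50) & (x <= q75)] = labels[1]
    out[x > q75] = labels[0]
    out[np.isnan(x)] = None
    return pd.Categorical(out, categories=list(labels), ordered=True)


# ---------------------------------------------------------------------------
# effect sizes & power
# ---------------------------------------------------------------------------

def cohens_d(mean_ref: float, sd_ref: float, mean_cmp: float, sd_cmp: float) -> float:
    """Standardized mean difference with the unweighted pooled SD.

    ``d = (mean_ref - mean_cmp) / sqrt((sd_ref^2 + sd_cmp^2) / 2)``; positive
    d means the comparison group has the lower mental-health score. By
    convention d >= 0.8 is large and d >= 1.2 very large.
    """
    if not (sd_ref > 0 and sd_cmp > 0):
        raise AnalysisError("Cohen's d requires positive group SDs")
    return (mean_ref - mean_cmp) / np.sqrt((sd_ref**2 + sd_cmp**2) / 2.0)


def cohens_d_pooled_n(
    mean_ref: float, sd_ref: float, n_ref: float,
    mean_cmp: float, sd_cmp: float, n_cmp: float,
) -> float:
    """n-weighted pooled-SD variant (classical two-sample pooling).

    Provided for comparison only; the unweighted form is what reproduces the
    published effect sizes from the published group summaries.
    """
    if not (sd_ref > 0 and sd_cmp > 0):
        raise AnalysisError("Cohen's d requires positive group SDs")
    if n_ref < 2 or n_cmp < 2:
        raise AnalysisError("pooled-n Cohen's d requires n >= 2 per group")
    pooled = np.sqrt(
        ((n_ref - 1) * sd_ref**2 + (n_cmp - 1) * sd_cmp**2) / (n_ref + n_cmp - 2)
    )
    return (mean_ref - mean_cmp) / pooled


def minimal_detectable_difference(
    n1: int, n2: int, sd: float = 10.0, alpha: float = 0.05, power: float = 0.8
) -> float:
    """Two-sample normal-approximation MDD.

    ``(z_{1-alpha/2} + z_{power}) * sd * sqrt(1/n1 + 1/n2)``.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise AnalysisError("alpha and power must lie in (0, 1)")
    if n1 < 2 or n2 < 2:
        raise AnalysisError("need n >= 2 per group")
    if not sd > 0:
        raise AnalysisError("sd must be positive")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    return float(z * sd * np.sqrt(1.0 / n1 + 1.0 / n2))


# ---------------------------------------------------------------------------
# clustered adjusted comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceComponents:
    """Random-intercept variance decomposition of a school-clustered model."""

    sigma2_school: float
    sigma2_residual: float
    note: str = ""

    @property
    def icc(self) -> float:
        return icc(self.sigma2_school, self.sigma2_residual)


def icc(sigma2_school: float, sigma2_residual: float) -> float:
    """Intraclass correlation: school variance / total variance."""
    if sigma2_school < 0 or sigma2_residual <= 0:
        raise AnalysisError("variances must be nonnegative (residual positive)")
    return float(sigma2_school / (sigma2_school + sigma2_residual))


def _fit_mixed(formula: str, data: pd.DataFrame, groups: pd.Series):
    # the default optimizer is robust near the variance boundary where
    # lbfgs tends to collapse the random-intercept variance to zero
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=groups)
        return model.fit(reml=True)


def fit_icc(outcome, school) -> VarianceComponents:
    """Null random-intercept model (outcome ~ 1 + (1 | school))."""
    df = pd.DataFrame({"y": np.asarray(outcome, float), "school": np.asarray(school)})
    df = df.dropna()
    if df["school"].nunique() < 2:
        raise AnalysisError("need >=2 schools for a clustered model")
    try:
        res = _fit_mixed("y ~ 1", df, df["school"])
        s2_school = float(np.asarray(res.cov_re)[0, 0])
        s2_resid = float(res.scale)
        note = ""
        if s2_school <= 0 or not np.isfinite(s2_school):
            s2_school, note = 0.0, "school variance at boundary; icc set to 0"
    except Exception as exc:  # singular fits degrade, never crash
        mvar = float(np.nanvar(df["y"], ddof=1))
        return VarianceComponents(0.0, mvar, f"mixed fit failed ({exc}); icc set to 0")
    return VarianceComponents(s2_school, s2_resid, note)


@dataclass
class ClusteredComparison:
    """Adjusted group contrasts from one school-clustered mixed model."""

    reference: str
    p_by_group: dict[str, float]
    p_trend: float | None
    components: VarianceComponents
    n_used: int


def fit_clustered_comparison(
    data: pd.DataFrame,
    group: str,
    outcome: str = "mh_score",
    school: str = "school_id",
    age: str | None = "age_band",
    sex: str | None = "sex",
    levels: Sequence[str] | None = None,
    trend: bool = True,
) -> ClusteredComparison:
    """Mixed-effects comparison of group means, adjusted and clustered.

    Fits ``outcome ~ C(group) + C(age_band) + C(sex)`` with a random school
    intercept; the first of ``levels`` is the reference. Adjusters identical
    to the tested covariate are dropped (the sex contrast is age-adjusted
    only, and vice versa). ``p_trend`` refits with the group coded 1..k as a
    numeric linear term. Wald z p-values are reported per non-reference
    group. A singular/failed fit yields icc = 0 with a note rather than an
    exception.
    """
    cols = {outcome: "y", group: "g", school: "school"}
    df = pd.DataFrame({v: data[k] for k, v in cols.items()})
    for adj, name in ((age, "age"), (sex, "sex")):
        if adj is not None and adj != group:
            df[name] = data[adj].astype(str)
    df["g"] = df["g"].astype(str).replace("nan", np.nan) if df["g"].dtype == object else df["g"]
    df = df.dropna()
    if df["school"].nunique() < 2:
        raise AnalysisError("need >=2 schools")
    if levels is None:
        levels = list(pd.unique(df["g"].astype(str)))
    else:
        levels = [str(l) for l in levels]
    df["g"] = df["g"].astype(str)
    df = df[df["g"].isin(levels)]
    observed = [l for l in levels if (df["g"] == l).any()]
    if len(observed) < 2:
        raise AnalysisError("need >=2 non-empty groups to compare")
    reference = observed[0]
    adjusters = [c for c in ("age", "sex") if c in df.columns]
    adj_terms = "".join(f" + C({c})" for c in adjusters)

    formula = f"y ~ C(g, Treatment(reference='{reference}')){adj_terms}"
    try:
        res = _fit_mixed(formula, df, df["school"])
        s2_school = float(np.asarray(res.cov_re)[0, 0])
        s2_resid = float(res.scale)
        note = ""
        if s2_school <= 0 or not np.isfinite(s2_school):
            s2_school, note = 0.0, "school variance at boundary; icc set to 0"
        comps = VarianceComponents(s2_school, s2_resid, note)
        p_by_group = {}
        for lev in observed[1:]:
            key = f"C(g, Treatment(reference='{reference}'))[T.{lev}]"
            p_by_group[lev] = float(res.pvalues[key])
    except Exception as exc:
        comps = VarianceComponents(
            0.0, float(np.nanvar(df["y"], ddof=1)), f"mixed fit failed ({exc})"
        )
        p_by_group = {lev: np.nan for lev in observed[1:]}

    p_trend = None
    if trend and len(observed) > 2:
        scores = {lev: i + 1 for i, lev in enumerate(observed)}
        df["g_score"] = df["g"].map(scores).astype(float)
        try:
            res_t = _fit_mixed(f"y ~ g_score{adj_terms}", df, df["school"])
            p_trend = float(res_t.pvalues["g_score"])
        except Exception:
            p_trend = np.nan
    return ClusteredComparison(reference, p_by_group, p_trend, comps, len(df))


# ---------------------------------------------------------------------------
# the descriptive/effect table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateSpec:
    """How one covariate enters the validity table.

    ``kind`` is ``"categorical"`` (ordered ``levels``, reference first) or
    ``"quartile"`` (weighted approximate quartiles of a continuous scale,
    labelled High/Q2/Q3/Low with High as reference).
    """

    name: str
    column: str
    kind: str = "categorical"
    levels: tuple[str, ...] | None = None
    trend: bool = True


def default_covariates() -> tuple[CovariateSpec, ...]:
    """The validation battery: demographics, support scales, functioning."""
    return (
        CovariateSpec("Sex", "sex", levels=("Male", "Female"), trend=False),
        CovariateSpec("Age", "age_band", levels=AGE_BANDS),
        CovariateSpec(
            "Relative family affluence",
            "relative_affluence",
            levels=("Well-off", "Average", "Not well-off"),
        ),
        CovariateSpec("Family support", "family_support", kind="quartile"),
        CovariateSpec("Peer support", "peer_support", kind="quartile"),
        CovariateSpec("Student support", "student_support", kind="quartile"),
        CovariateSpec("Teacher support", "teacher_support", kind="quartile"),
        CovariateSpec(
            "Academic performance",
            "academic_performance",
            levels=("5", "4", "3", "2", "1"),
        ),
        CovariateSpec(
            "Self-rated health status",
            "self_rated_health",
            levels=("Excellent", "Good", "Fair/poor"),
        ),
        CovariateSpec(
            "Feelings of hopelessness", "hopelessness", levels=("No", "Yes"),
            trend=False,
        ),
        CovariateSpec("Prosocial behavior", "prosocial", kind="quartile"),
    )


def _level_str(v) -> object:
    """Group label as text; integral floats print without the decimal."""
    if pd.isna(v):
        return np.nan
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return str(v)


def build_effect_table(
    panel: pd.DataFrame,
    covariates: Sequence[CovariateSpec] | None = None,
    weights_col: str = "weight",
    outcome: str = "mh_score",
    subgroup: pd.Series | None = None,
    fit_models: bool = True,
) -> pd.DataFrame:
    """Per-covariate weighted descriptives, adjusted p-values, and Cohen's d.

    One row per covariate group: weighted n, %, weighted mean and SD of the
    outcome, adjusted p vs reference (school-clustered mixed model), p-trend
    (ordinal covariates), and d vs reference from the weighted group
    summaries. ``subgroup`` restricts the table (e.g. to the Mentally
    Healthy category for the within-group analysis). Empty groups are
    skipped; a covariate with fewer than two non-empty groups raises
    :class:`AnalysisError`.
    """
    if covariates is None:
        covariates = default_covariates()
    df = panel.copy()
    if subgroup is not None:
        df = df[np.asarray(subgroup, bool)]
    if len(df) == 0:
        raise AnalysisError("no rows to analyze (empty subgroup?)")
    if "age_band" not in df.columns and "age_years" in df.columns:
        df["age_band"] = age_band(df["age_years"])
    w_all = df[weights_col] if weights_col in df.columns else pd.Series(1.0, index=df.index)

    rows = []
    for spec in covariates:
        if spec.column not in df.columns:
            raise AnalysisError(f"covariate column {spec.column!r} absent")
        if spec.kind == "quartile":
            gcol = bin_quartiles(df[spec.column], w_all)
            levels = ("High", "Q2", "Q3", "Low")
            gseries = pd.Series(gcol.astype(object), index=df.index)
        else:
            levels = spec.levels or tuple(
                str(v) for v in pd.unique(df[spec.column].dropna())
            )
            gseries = df[spec.column].astype(object).map(_level_str)
        mask = gseries.notna() & df[outcome].notna() & w_all.notna()
        sub = df[mask]
        g = gseries[mask].astype(str)
        w = w_all[mask]
        observed = [l for l in levels if (g == l).any()]
        if len(observed) < 2:
            raise AnalysisError(
                f"covariate {spec.name!r} has <2 non-empty groups; no contrast"
            )
        stats_by_group = {}
        total_w = float(w.sum())
        for lev in observed:
            m = g == lev
            mean, sd = weighted_mean_sd(sub.loc[m, outcome], w[m])
            stats_by_group[lev] = {
                "n_weighted": float(w[m].sum()),
                "pct": 100.0 * float(w[m].sum()) / total_w,
                "mean": mean,
                "sd": sd,
                "n_raw": int(m.sum()),
            }
        comparison = None
        if fit_models:
            fit_df = sub.assign(_g=g)
            comparison = fit_clustered_comparison(
                fit_df,
                group="_g",
                outcome=outcome,
                school="school_id",
                age=None if spec.column == "age_band" else "age_band",
                sex=None if spec.column == "sex" else "sex",
                levels=observed,
                trend=spec.trend,
            )
        ref = observed[0]
        ref_stats = stats_by_group[ref]
        for i, lev in enumerate(observed):
            s = stats_by_group[lev]
            is_ref = lev == ref
            # d undefined for near-empty/degenerate groups (e.g. a rare
            # category inside a restricted subgroup)
            degenerate = (
                s["n_raw"] < 2 or s["sd"] <= 0
                or ref_stats["n_raw"] < 2 or ref_stats["sd"] <= 0
            )
            d = (
                np.nan
                if is_ref or degenerate
                else cohens_d(ref_stats["mean"], ref_stats["sd"], s["mean"], s["sd"])
            )
            p_adj = np.nan
            if not is_ref and comparison is not None:
                p_adj = comparison.p_by_group.get(lev, np.nan)
            rows.append(
                {
                    "covariate": spec.name,
                    "group": lev,
                    "reference": is_ref,
                    "n_weighted": s["n_weighted"],
                    "pct": s["pct"],
                    "mean": s["mean"],
                    "sd": s["sd"],
                    "p_adjusted": p_adj,
                    "p_trend": (
                        comparison.p_trend
                        if (i == 0 and comparison is not None and comparison.p_trend is not None)
                        else np.nan
                    ),
                    "cohens_d": d,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# published reference summaries (2014 Canadian HBSC validation tables)
# ---------------------------------------------------------------------------

_REFERENCE_CSV = """\
table,covariate,group,n_weighted,pct,mean,sd,cohens_d
full,Sex,Male,8774,46.5,51.6,8.8,
full,Sex,Female,10093,53.5,48.7,10.5,0.30
full,Age,<=11,1645,8.7,54.8,7.6,
full,Age,12,3102,16.4,53.4,8.5,0.17
full,Age,13,3550,18.8,51.6,9.2,0.38
full,Age,14,4303,22.8,49.3,9.7,0.63
full,Age,>=15,6266,33.2,46.8,10.2,0.89
full,Relative family affluence,Well-off,10701,56.7,52.4,9.0,
full,Relative family affluence,Average,6484,34.4,48.0,9.2,0.48
full,Relative family affluence,Not well-off,1682,8.9,43.5,12.1,0.83
full,Family support,High,5242,27.8,56.0,7.6,
full,Family support,Q2,5744,30.4,52.2,7.4,0.51
full,Family support,Q3,3977,21.1,47.6,8.5,1.04
full,Family support,Low,3904,20.7,41.5,10.0,1.63
full,Peer support,High,4830,25.6,53.0,9.6,
full,Peer support,Q2,3190,16.9,51.2,9.5,0.19
full,Peer support,Q3,6112,32.4,49.8,9.2,0.34
full,Peer support,Low,4734,25.1,46.6,10.0,0.65
full,Student support,High,4762,25.2,54.8,8.1,
full,Student support,Q2,4708,25.0,51.9,8.2,0.36
full,Student support,Q3,5007,26.5,49.0,9.2,0.67
full,Student support,Low,4389,23.3,44.1,10.4,1.15
full,Teacher support,High,4761,25.2,55.9,7.3,
full,Teacher support,Q2,4893,25.9,52.0,7.8,0.52
full,Teacher support,Q3,4537,24.1,48.7,8.8,0.89
full,Teacher support,Low,4675,24.8,43.4,10.7,1.36
full,Academic performance,5,6036,32.0,52.4,8.1,
full,Academic performance,4,9156,48.5,50.2,10.0,0.24
full,Academic performance,3,2994,15.9,46.7,11.0,0.59
full,Academic performance,2,556,3.0,43.4,10.2,0.98
full,Academic performance,1,124,0.7,38.7,10.4,1.47
full,Self-rated health status,Excellent,5626,29.8,54.9,8.0,
full,Self-rated health status,Good,10160,53.9,49.8,8.9,0.60
full,Self-rated health status,Fair/poor,3081,16.3,42.2,10.3,1.38
full,Feelings of hopelessness,No,13889,73.6,53.4,7.4,
full,Feelings of hopelessness,Yes,4978,26.4,40.9,9.9,1.43
full,Prosocial behavior,High,4979,26.4,52.1,10.2,
full,Prosocial behavior,Q2,4530,24.0,50.6,9.5,0.15
full,Prosocial behavior,Q3,5353,28.4,49.3,9.5,0.28
full,Prosocial behavior,Low,4005,21.2,47.8,9.6,0.43
healthy,Family support,High,4993,33.7,58.0,5.5,
healthy,Family support,Q2,5173,34.9,54.7,5.2,0.62
healthy,Family support,Q3,2903,19.6,52.2,5.3,1.07
healthy,Family support,Low,1744,11.8,50.2,5.8,1.38
healthy,Peer support,High,4196,28.3,56.8,6.3,
healthy,Peer support,Q2,2575,17.3,55.6,5.7,0.20
healthy,Peer support,Q3,4948,33.3,53.9,5.7,0.48
healthy,Peer support,Low,3128,21.1,53.0,5.8,0.63
healthy,Student support,High,4363,29.5,57.6,5.5,
healthy,Student support,Q2,4024,27.2,55.0,5.6,0.47
healthy,Student support,Q3,3830,25.9,53.5,5.6,0.75
healthy,Student support,Low,2554,17.3,51.7,6.2,1.01
healthy,Teacher support,High,4532,31.4,57.9,5.2,
healthy,Teacher support,Q2,4175,28.9,54.9,5.4,0.53
healthy,Teacher support,Q3,3323,23.0,52.8,5.7,0.93
healthy,Teacher support,Low,2404,16.7,51.4,6.3,1.13
healthy,Academic performance,5,5245,35.6,55.4,5.6,
healthy,Academic performance,4,7157,48.6,54.9,6.1,0.09
healthy,Academic performance,3,2014,13.7,53.4,6.6,0.33
healthy,Academic performance,2,277,1.9,52.9,6.2,0.42
healthy,Academic performance,1,42,0.3,51.0,5.0,0.83
healthy,Self-rated health status,Excellent,5210,35.0,57.4,5.6,
healthy,Self-rated health status,Good,8155,54.8,53.9,5.8,0.61
healthy,Self-rated health status,Fair/poor,1507,10.1,50.8,5.5,1.19
"""


def published_reference_table() -> pd.DataFrame:
    """Published group summaries of the 2014 HBSC validation analysis.

    Weighted n, %, mean, SD, and Cohen's d per covariate group, for the full
    sample (``table == "full"``) and for the subgroup categorized as
    Mentally Healthy by the four-group measure (``table == "healthy"``).
    The reference row of each covariate has a missing ``cohens_d``.
    """
    return pd.read_csv(io.StringIO(_REFERENCE_CSV))
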
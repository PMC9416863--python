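"""Synthetic HBSC-like cohort generator with known ground truth.

Generates item-level questionnaire cohorts that emulate the statistical
structure of the 2014 Canadian HBSC validation sample: ~400 schools with a
small school-level variance fraction (ICC ~ 0.038), ordinal items with
realistic reliabilities (alpha 0.75-0.92 via their inter-item correlations),
survey weights developed by grade-within-region strata, and covariates whose
standardized group differences (Cohen's d) match configured targets. Every
cohort carries its ground truth so pipeline estimates can be checked against
the generating parameters.

Generative model
----------------
Latent well-being ``W`` and psychopathology ``P`` are unit-variance factors
with correlation ``cor_swb_pth`` (default -0.5), each decomposed into a
school effect and a student residual with the same correlation structure, so
*every* linear combination of (W, P) has school-variance fraction ``f``.
Ordinal items load on W or P and are discretized at equal-probability normal
cuts (an optional tilt reproduces the left skew of real mental-health
scores). Because discretization and item noise attenuate the measured
score's school fraction to ``f * R^2`` (``R^2`` = share of measured-score
variance explained by the latents), the generator estimates ``R^2`` on an
internal pilot draw and inflates the latent fraction to ``icc_school / R^2``
so the *measured* score's ICC matches the configured value.

Covariate groups are assigned by thresholding latents correlated with the
realized (measured) mental-health score, with the correlation chosen in
closed form from truncated-normal slice moments so that the realized Cohen's
d between the reference and bottom groups equals the configured target —
i.e. targets are calibrated on the scale the analysis actually sees, not on
the error-free latent scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .scales import (
    EXTERNALIZED_ITEMS,
    FREQUENCY_5,
    LIKERT_AGREE_5,
    PROSOCIAL_6,
    RISK_FREQUENCY_3,
)

__all__ = [
    "ConfigError",
    "null_rejection_rate",
    "CategoricalTarget",
    "ScaleTarget",
    "CohortConfig",
    "GroundTruth",
    "spearman_brown",
    "invert_spearman_brown",
    "discretization_attenuation",
    "ItemCalibration",
    "calibrate_items",
    "rho_for_target_d",
    "assign_weights_and_strata",
    "generate_cohort",
]


class ConfigError(ValueError):
    """Infeasible or inconsistent cohort configuration."""


# ---------------------------------------------------------------------------
# reliability / attenuation arithmetic
# ---------------------------------------------------------------------------

def spearman_brown(r_bar: float, k: int) -> float:
    """Alpha of k exchangeable items with mean inter-item correlation r_bar."""
    return k * r_bar / (1.0 + (k - 1) * r_bar)


def invert_spearman_brown(alpha: float, k: int) -> float:
    """Mean inter-item correlation implied by alpha for k exchangeable items."""
    return alpha / (k - alpha * (k - 1))


def _category_probs(levels: int, tilt: float = 1.0, direction: int = +1) -> np.ndarray:
    """Category probabilities: uniform at tilt=1, geometric otherwise.

    ``direction=+1`` piles mass on high codes (ceiling, e.g. well-being
    items in a left-skewed cohort); ``-1`` piles mass on low codes (floor,
    e.g. symptom items).
    """
    if tilt <= 0:
        raise ConfigError("tilt must be positive")
    j = np.arange(levels, dtype=float)
    p = tilt ** (j if direction > 0 else -j)
    return p / p.sum()


def discretization_attenuation(levels: int, probs=None) -> float:
    """Correlation between a standard normal and its discretized category code.

    Categories are the slices between normal quantile cuts at the cumulative
    ``probs`` (equal-probability by default), scored 0..levels-1.
    """
    if probs is None:
        probs = np.full(levels, 1.0 / levels)
    probs = np.asarray(probs, dtype=float)
    if probs.size != levels or not np.isclose(probs.sum(), 1.0):
        raise ConfigError("probs must be a length-`levels` probability vector")
    edges = np.r_[0.0, np.cumsum(probs)]
    edges[-1] = 1.0
    z = norm.ppf(edges)
    pdf = np.where(np.isfinite(z), norm.pdf(z), 0.0)
    scores = np.arange(levels, dtype=float)
    # E[s * Z] = sum_j s_j * (phi(a_j) - phi(b_j))
    cov = float(np.sum(scores * (pdf[:-1] - pdf[1:])))
    mean_s = float(np.sum(probs * scores))
    var_s = float(np.sum(probs * scores**2) - mean_s**2)
    return cov / np.sqrt(var_s)


@dataclass(frozen=True)
class ItemCalibration:
    """Loadings/noise for k exchangeable ordinal items targeting r_bar.

    ``loading`` is the continuous-scale factor loading (``sqrt(r_bar)``), so
    the pre-discretization inter-item correlation equals ``r_bar`` and the
    continuous-scale alpha is the Spearman-Brown value. Discretizing to
    ``levels`` categories attenuates each item by ``attenuation``, so the
    realized inter-item correlation is ~``r_discrete`` and the realized
    alpha ~``alpha_discrete`` (slightly below the continuous target).
    ``score_factor_cor`` is the implied correlation between the summed
    discrete score and the common factor.
    """

    k: int
    levels: int
    r_bar: float
    loading: float
    attenuation: float
    alpha_continuous: float
    r_discrete: float
    alpha_discrete: float
    score_factor_cor: float


def calibrate_items(r_bar: float, k: int, levels: int, probs=None) -> ItemCalibration:
    """Solve item loadings for a target mean inter-item correlation."""
    if not 0.0 <= r_bar < 1.0:
        raise ConfigError("r_bar must lie in [0, 1)")
    if k < 1:
        raise ConfigError("k must be >= 1")
    a = discretization_attenuation(levels, probs)
    loading = float(np.sqrt(r_bar))
    r_disc = r_bar * a * a
    alpha_cont = spearman_brown(r_bar, k) if k > 1 else np.nan
    alpha_disc = spearman_brown(r_disc, k) if k > 1 else np.nan
    # cor(sum of discrete items, factor): k*lam*a / sqrt(k + k(k-1) r_disc)
    denom = np.sqrt(k * (1.0 + (k - 1) * r_disc))
    score_cor = k * loading * a / denom if r_bar > 0 else 0.0
    if k == 1:
        score_cor = loading * a
    return ItemCalibration(
        k, levels, r_bar, loading, a, alpha_cont, r_disc, alpha_disc, float(score_cor)
    )


# ---------------------------------------------------------------------------
# target-d calibration from truncated-normal slice moments
# ---------------------------------------------------------------------------

def _slice_moments(lo_q: float, hi_q: float) -> tuple[float, float]:
    """Mean and variance of a standard normal within quantile slice (lo, hi]."""
    p = hi_q - lo_q
    a, b = norm.ppf(lo_q), norm.ppf(hi_q)
    fa = norm.pdf(a) if np.isfinite(a) else 0.0
    fb = norm.pdf(b) if np.isfinite(b) else 0.0
    afa = a * fa if np.isfinite(a) else 0.0
    bfb = b * fb if np.isfinite(b) else 0.0
    m = (fa - fb) / p
    v = 1.0 + (afa - bfb) / p - m * m
    return m, v


def rho_for_target_d(
    d: float, prevalences, cmp_tail: float | None = None
) -> float:
    """Correlation between a grouping latent and the outcome that yields d.

    Groups occupy quantile slices of the latent ``C``, ordered from the top
    (reference = best mental health) down. For outcome ``Y`` with
    ``cor(C, Y) = rho`` (bivariate normal), Cohen's d between the reference
    slice and the bottom slice (of mass ``cmp_tail``, default the last
    prevalence) is::

        d = rho * (m_ref - m_cmp) / sqrt(rho^2 * (v_ref + v_cmp)/2 + 1 - rho^2)

    with (m, v) the slice moments of a standard normal. This inverts that
    relation.
    """
    prev = np.asarray(prevalences, dtype=float)
    if (prev <= 0).any() or not np.isclose(prev.sum(), 1.0, atol=1e-6):
        raise ConfigError("prevalences must be positive and sum to 1")
    prev = prev / prev.sum()
    if d == 0:
        return 0.0
    if d < 0:
        raise ConfigError("target d must be nonnegative (reference scores highest)")
    tail = prev[-1] if cmp_tail is None else float(cmp_tail)
    m_ref, v_ref = _slice_moments(1.0 - prev[0], 1.0)
    m_cmp, v_cmp = _slice_moments(0.0, tail)
    A = m_ref - m_cmp
    B = 0.5 * (v_ref + v_cmp)
    rho2 = d * d / (A * A + d * d * (1.0 - B))
    rho = float(np.sqrt(rho2))
    if rho > 0.995:
        raise ConfigError(f"target d={d} infeasible for these group prevalences")
    return rho


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoricalTarget:
    """A directly observed categorical covariate.

    ``labels``/``prevalences`` run from the reference group (best mental
    health) downward; ``d`` is the target effect size of the reference vs
    the bottom group. ``cmp_tail`` merges the bottom ``cmp_tail`` mass into
    the comparison slice when the analysis collapses trailing categories
    (used for self-rated health, where Fair and Poor are analyzed jointly).
    """

    labels: tuple[str, ...]
    prevalences: tuple[float, ...]
    d: float
    cmp_tail: float | None = None


@dataclass(frozen=True)
class ScaleTarget:
    """A multi-item covariate scale binned into quartiles by the analysis."""

    d: float
    r_bar: float
    k: int
    levels: int


def _default_categorical_targets() -> dict[str, CategoricalTarget]:
    return {
        "sex": CategoricalTarget(("Male", "Female"), (0.465, 0.535), 0.30),
        "age_band": CategoricalTarget(
            ("<=11", "12", "13", "14", ">=15"),
            (0.087, 0.164, 0.188, 0.228, 0.333),
            0.89,
        ),
        "affluence": CategoricalTarget(
            ("Well-off", "Average", "Not well-off"), (0.567, 0.344, 0.089), 0.83
        ),
        "academic_marks": CategoricalTarget(
            (
                "Mostly As",
                "Mostly As and Bs",
                "Mostly Bs and Cs",
                "Mostly Cs",
                "Mostly letter grades below C",
            ),
            (0.320, 0.485, 0.159, 0.029, 0.007),
            1.47,
        ),
        "srh": CategoricalTarget(
            ("Excellent", "Good", "Fair", "Poor"),
            (0.298, 0.539, 0.120, 0.043),
            1.38,
            cmp_tail=0.163,
        ),
        "hopeless": CategoricalTarget(("No", "Yes"), (0.736, 0.264), 1.43),
    }


def _default_scale_targets() -> dict[str, ScaleTarget]:
    # r_bar inverted from the instruments' published alphas
    return {
        "family_support": ScaleTarget(1.63, invert_spearman_brown(0.91, 4), 4, 5),
        "peer_support": ScaleTarget(0.65, invert_spearman_brown(0.92, 4), 4, 5),
        "student_support": ScaleTarget(1.15, invert_spearman_brown(0.80, 3), 3, 5),
        "teacher_support": ScaleTarget(1.36, invert_spearman_brown(0.90, 9), 9, 5),
        "prosocial": ScaleTarget(0.43, invert_spearman_brown(0.87, 5), 5, 6),
    }


def _default_mh_reliability() -> dict[str, float]:
    # internalized/externalized r_bar inverted from published alphas
    # (0.79 over 4 items, 0.75 over 7); single-item reliabilities chosen as
    # plausible values for a Cantril ladder and a single affect item.
    return {
        "life_satisfaction": 0.81,
        "positive_affect": 0.64,
        "negative_affect": 0.50,
        "internalized": invert_spearman_brown(0.79, 4),
        "externalized": invert_spearman_brown(0.75, 7),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults emulate the 2014 HBSC study design."""

    n_students: int = 20_000
    n_schools: int = 400
    icc_school: float = 0.038
    cor_swb_pth: float = -0.5
    mh_reliability: Mapping[str, float] = field(default_factory=_default_mh_reliability)
    categorical_targets: Mapping[str, CategoricalTarget] = field(
        default_factory=_default_categorical_targets
    )
    scale_targets: Mapping[str, ScaleTarget] = field(default_factory=_default_scale_targets)
    weight_dispersion: float = 0.3
    missing_rate: float = 0.004
    skew_strength: float = 1.0
    seed: int = 2014

    def __post_init__(self) -> None:
        if not self.n_students >= self.n_schools >= 2:
            raise ConfigError("need n_students >= n_schools >= 2")
        if not 0.0 <= self.icc_school < 1.0:
            raise ConfigError("icc_school must lie in [0, 1)")
        if not -1.0 < self.cor_swb_pth <= 0.0:
            raise ConfigError("cor_swb_pth must lie in (-1, 0]")
        if self.weight_dispersion < 0:
            raise ConfigError("weight_dispersion must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.skew_strength <= 0:
            raise ConfigError("skew_strength must be positive")
        for name, tgt in self.categorical_targets.items():
            if len(tgt.labels) != len(tgt.prevalences):
                raise ConfigError(f"{name}: labels/prevalences length mismatch")
            rho_for_target_d(tgt.d, tgt.prevalences, tgt.cmp_tail)  # feasibility
        for name, tgt in self.scale_targets.items():
            if not 0.0 <= tgt.r_bar < 1.0:
                raise ConfigError(f"{name}: r_bar must lie in [0, 1)")

    def with_skew(self, strength: float = 1.6) -> "CohortConfig":
        """Copy with tilted item cuts reproducing a left-skewed score."""
        return replace(self, skew_strength=strength)


@dataclass
class GroundTruth:
    """Generating values stored alongside a cohort for recovery tests."""

    per_student: pd.DataFrame
    info: dict


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------

#: (scale, columns, levels, factor, direction) for the measure's own items;
#: direction +1 = higher code is better mental health
_MH_ITEM_PLAN = (
    ("life_satisfaction", ("ls_cantril",), 11, "W", +1),
    ("positive_affect", ("pa_energy",), 5, "W", +1),
    ("negative_affect", ("na_lonely", "na_helpless"), 5, "-W", -1),
    ("internalized", ("int_low", "int_irritable", "int_nervous", "int_sleep"), 5, "P", -1),
    ("externalized", EXTERNALIZED_ITEMS, 3, "P", -1),
)

_SCALE_ITEM_COLUMNS = {
    "family_support": tuple(f"fam_{i}" for i in range(1, 5)),
    "peer_support": tuple(f"peer_{i}" for i in range(1, 5)),
    "student_support": tuple(f"stud_{i}" for i in range(1, 4)),
    "teacher_support": tuple(f"teach_{i}" for i in range(1, 10)),
    "prosocial": tuple(f"prosoc_{i}" for i in range(1, 6)),
}

def _column_labels() -> dict[str, tuple[str, ...] | None]:
    """Response-label set per emitted item column (None = numeric)."""
    labels: dict[str, tuple[str, ...] | None] = {"ls_cantril": None, "pa_energy": LIKERT_AGREE_5}
    for col in ("na_lonely", "na_helpless"):
        labels[col] = LIKERT_AGREE_5
    for col in _MH_ITEM_PLAN[3][1]:
        labels[col] = FREQUENCY_5
    for col in EXTERNALIZED_ITEMS:
        labels[col] = RISK_FREQUENCY_3
    for name, cols in _SCALE_ITEM_COLUMNS.items():
        lab = PROSOCIAL_6 if name == "prosocial" else LIKERT_AGREE_5
        for col in cols:
            labels[col] = lab
    return labels


def _discretize(x: np.ndarray, levels: int, probs: np.ndarray) -> np.ndarray:
    cuts = norm.ppf(np.cumsum(probs)[:-1])
    return np.searchsorted(cuts, x, side="left").astype(np.int64)


def _emit_mh_item_codes(
    W: np.ndarray, P: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Ordinal item codes for the measure's own subscales."""
    codes: dict[str, np.ndarray] = {}
    n = W.size
    for scale, cols, levels, factor, direction in _MH_ITEM_PLAN:
        r = float(config.mh_reliability[scale])
        lam = np.sqrt(r)
        base = W if factor == "W" else (-W if factor == "-W" else P)
        probs = _category_probs(levels, config.skew_strength, direction)
        for col in cols:
            cont = lam * base + np.sqrt(1.0 - r) * rng.standard_normal(n)
            codes[col] = _discretize(cont, levels, probs)
    return codes


def _mh_z_from_codes(codes: Mapping[str, np.ndarray]) -> np.ndarray:
    """The composite score arithmetic on complete integer codes, as z-scores."""

    def z(v):
        v = np.asarray(v, float)
        return (v - v.mean()) / v.std(ddof=1)

    ls = z(codes["ls_cantril"])
    pa = z(codes["pa_energy"])
    na = z(codes["na_lonely"] + codes["na_helpless"])
    internal = z(sum(codes[c] for c in _MH_ITEM_PLAN[3][1]))
    external = z(sum(codes[c] for c in EXTERNALIZED_ITEMS))
    swb = z(ls + pa - na)
    pth = z(internal + external)
    return z(swb - pth)


def _pilot_measurement_r2(config: CohortConfig, seed_seq: np.random.SeedSequence,
                          n_pilot: int = 6000) -> float:
    """Share of measured-score variance explained by (W, P), from a pilot draw."""
    rng = np.random.Generator(np.random.PCG64(seed_seq))
    c = config.cor_swb_pth
    cov = np.array([[1.0, c], [c, 1.0]])
    L = np.linalg.cholesky(cov)
    WP = rng.standard_normal((n_pilot, 2)) @ L.T
    W, P = WP[:, 0], WP[:, 1]
    zhat = _mh_z_from_codes(_emit_mh_item_codes(W, P, config, rng))
    X = np.column_stack([np.ones(n_pilot), W, P])
    beta, *_ = np.linalg.lstsq(X, zhat, rcond=None)
    resid = zhat - X @ beta
    return float(1.0 - resid.var() / zhat.var())


def assign_weights_and_strata(
    region: np.ndarray,
    grade: np.ndarray,
    dispersion: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Survey weights drawn per grade-within-region stratum, mean exactly 1.

    One lognormal weight per stratum (coefficient of variation =
    ``dispersion``), shared by the stratum's students and normalized so the
    emitted weights average 1. ``dispersion=0`` yields unit weights. Weights
    are independent of mental health by construction, so weighted and
    unweighted estimands coincide in expectation.
    """
    n = len(region)
    if dispersion == 0:
        return np.ones(n)
    sigma2 = np.log1p(dispersion**2)
    strata = pd.Series(zip(region, grade))
    cells = strata.unique()
    draws = np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=len(cells)))
    lookup = dict(zip(cells, draws))
    w = strata.map(lookup).to_numpy(dtype=float)
    return w / w.mean()


_REGIONS = ("ON", "QC", "BC", "AB", "MB", "SK", "NS", "NB", "NL", "PE")


def _realized_d(z: np.ndarray, group: np.ndarray, ref: int, cmp_groups) -> float:
    """Unweighted Cohen's d (unweighted pooled SD) between assigned groups."""
    a = z[group == ref]
    b = z[np.isin(group, cmp_groups)]
    return float((a.mean() - b.mean()) / np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0))


def _solve_rho(f, target: float, lo: float = 0.0, hi: float = 0.995) -> float:
    """Monotone 1-D root finding of realized-d(rho) = target."""
    from scipy.optimize import brentq

    if target == 0:
        return 0.0
    f_lo, f_hi = f(lo) - target, f(hi) - target
    if f_lo >= 0:
        return lo  # target below the assignment-noise floor
    if f_hi <= 0:
        raise ConfigError(f"target d={target} infeasible (max realized {f_hi + target:.2f})")
    return float(brentq(lambda r: f(r) - target, lo, hi, xtol=1e-4))


def _assign_groups_by_rank(C: np.ndarray, prevalences: np.ndarray) -> np.ndarray:
    """Slice students into groups by descending latent rank, exact counts."""
    n = C.size
    bounds = np.round(np.cumsum(prevalences) * n).astype(int)
    bounds[-1] = n
    order = np.argsort(-C, kind="mergesort")
    group = np.empty(n, dtype=np.int64)
    start = 0
    for g, stop in enumerate(bounds):
        group[order[start:stop]] = g
        start = stop
    return group


def null_rejection_rate(
    n_replicates: int = 1000,
    n_students: int = 500,
    n_schools: int = 20,
    icc_school: float = 0.038,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the clustered adjusted comparison under the null.

    Each replicate draws a school-clustered Gaussian outcome with the given
    ICC, a binary grouping factor independent of the outcome, and random
    age-band/sex adjusters, then fits the same mixed model the validity
    analysis uses and records whether the adjusted group p-value falls below
    ``alpha``. With a well-calibrated test the returned rate is ~``alpha``.
    """
    from .validity import fit_clustered_comparison

    rng = np.random.default_rng(seed)
    per_school = n_students // n_schools
    school = np.repeat(np.arange(n_schools), per_school)
    n = school.size
    tau = np.sqrt(icc_school / (1.0 - icc_school))
    rejections = 0
    for _ in range(n_replicates):
        y = rng.standard_normal(n) + tau * rng.standard_normal(n_schools)[school]
        d = pd.DataFrame(
            {
                "mh_score": y,
                "grp": rng.integers(0, 2, n).astype(str),
                "school_id": school,
                "age_band": rng.integers(0, 5, n).astype(str),
                "sex": rng.integers(0, 2, n).astype(str),
            }
        )
        cc = fit_clustered_comparison(d, group="grp", levels=["0", "1"], trend=False)
        rejections += bool(cc.p_by_group["1"] < alpha)
    return rejections / n_replicates


def generate_cohort(config: CohortConfig | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one item-level cohort and its ground truth.

    Deterministic for a fixed ``config.seed``. Returns ``(table, truth)``
    where ``table`` is the raw item-response table (labels for ordinal
    items, integers for the Cantril ladder) and ``truth`` holds per-student
    latents plus the calibration actually used.
    """
    config = config or CohortConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    r2 = _pilot_measurement_r2(config, seeds[0])
    f = config.icc_school / r2 if config.icc_school > 0 else 0.0
    if f >= 0.9:
        raise ConfigError(
            f"icc_school={config.icc_school} needs latent school fraction {f:.2f} "
            "after measurement attenuation; infeasible"
        )

    n, s = config.n_students, config.n_schools
    rng_lat = np.random.Generator(np.random.PCG64(seeds[1]))
    rng_items = np.random.Generator(np.random.PCG64(seeds[2]))
    rng_cov = np.random.Generator(np.random.PCG64(seeds[3]))
    rng_w = np.random.Generator(np.random.PCG64(seeds[4]))
    rng_miss = np.random.Generator(np.random.PCG64(seeds[5]))

    # latent W/P with a shared correlation structure at both levels
    c = config.cor_swb_pth
    L = np.linalg.cholesky(np.array([[1.0, c], [c, 1.0]]))
    school_of = np.repeat(np.arange(s), np.diff(np.linspace(0, n, s + 1).astype(int)))
    u = (rng_lat.standard_normal((s, 2)) @ L.T) * np.sqrt(f)
    e = (rng_lat.standard_normal((n, 2)) @ L.T) * np.sqrt(1.0 - f)
    W = u[school_of, 0] + e[:, 0]
    P = u[school_of, 1] + e[:, 1]

    codes = _emit_mh_item_codes(W, P, config, rng_items)
    zhat = _mh_z_from_codes(codes)

    # Covariate calibration: the analytic rho from truncated-normal moments
    # is refined by root-finding on the realized d in this very sample (all
    # noise draws fixed first), so the emitted cohort meets its target d on
    # the measured score rather than on an error-free latent.
    truth_cols: dict[str, np.ndarray] = {}
    cat_assign: dict[str, np.ndarray] = {}
    rho_used: dict[str, float] = {}
    for name, tgt in config.categorical_targets.items():
        prev = np.asarray(tgt.prevalences, float)
        prev = prev / prev.sum()
        eps = rng_cov.standard_normal(n)
        tail = prev[-1] if tgt.cmp_tail is None else float(tgt.cmp_tail)
        tail_from = np.cumsum(prev[::-1])[::-1]  # mass from group j downward
        cmp_groups = [j for j in range(len(prev)) if tail_from[j] <= tail + 1e-9]

        def d_real(rho, eps=eps, prev=prev, cmp_groups=cmp_groups):
            C = rho * zhat + np.sqrt(1.0 - rho * rho) * eps
            g = _assign_groups_by_rank(C, prev)
            return _realized_d(zhat, g, 0, cmp_groups)

        rho = _solve_rho(d_real, tgt.d)
        C = rho * zhat + np.sqrt(1.0 - rho * rho) * eps
        g = _assign_groups_by_rank(C, prev)
        cat_assign[name] = np.asarray(tgt.labels, dtype=object)[g]
        truth_cols[f"latent_{name}"] = C
        rho_used[name] = rho
    for name, tgt in config.scale_targets.items():
        calib = calibrate_items(tgt.r_bar, tgt.k, tgt.levels)
        eps = rng_cov.standard_normal(n)
        item_noise = rng_cov.standard_normal((n, tgt.k))
        probs = _category_probs(tgt.levels)  # covariate scales stay symmetric
        cuts = norm.ppf(np.cumsum(probs)[:-1])

        def score_of(rho, eps=eps, item_noise=item_noise, tgt=tgt, calib=calib, cuts=cuts):
            F = rho * zhat + np.sqrt(1.0 - rho * rho) * eps
            X = calib.loading * F[:, None] + np.sqrt(1.0 - tgt.r_bar) * item_noise
            return np.searchsorted(cuts, X, side="left").sum(axis=1), F

        def d_real(rho, score_of=score_of):
            S, _ = score_of(rho)
            q25, q75 = np.quantile(S, [0.25, 0.75], method="inverted_cdf")
            high, low = S > q75, S <= q25
            a, b = zhat[high], zhat[low]
            return float(
                (a.mean() - b.mean()) / np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
            )

        rho_f = _solve_rho(d_real, tgt.d)
        S, F = score_of(rho_f)
        X = calib.loading * F[:, None] + np.sqrt(1.0 - tgt.r_bar) * item_noise
        item_codes = np.searchsorted(cuts, X, side="left").astype(np.int64)
        for j, col in enumerate(_SCALE_ITEM_COLUMNS[name]):
            codes[col] = item_codes[:, j]
        truth_cols[f"latent_{name}"] = F
        rho_used[name] = rho_f

    # demographics derived from the assigned bands
    band = cat_assign["age_band"]
    age = np.select(
        [band == "<=11", band == "12", band == "13", band == "14"],
        [11, 12, 13, 14],
        default=0,
    ).astype(np.int64)
    age[band == ">=15"] = 15 + (rng_cov.random(int((band == ">=15").sum())) < 0.3)
    grade = np.clip(age - 5, 6, 10)
    region = np.asarray(_REGIONS, dtype=object)[rng_cov.integers(0, len(_REGIONS), n)]
    weight = assign_weights_and_strata(region, grade, config.weight_dispersion, rng_w)

    table = pd.DataFrame(
        {
            "student_id": [f"S{i:06d}" for i in range(1, n + 1)],
            "school_id": [f"SCH{j + 1:04d}" for j in school_of],
            "weight": weight,
            "age_years": age,
            "sex": cat_assign["sex"],
            "region": region,
            "grade": grade,
        }
    )
    label_map = _column_labels()
    for col, vals in codes.items():
        labels = label_map[col]
        if labels is None:
            table[col] = vals
        else:
            table[col] = np.asarray(labels, dtype=object)[vals]
    table["academic_marks"] = cat_assign["academic_marks"]
    table["hopeless"] = cat_assign["hopeless"]
    table["srh"] = cat_assign["srh"]
    table["affluence"] = cat_assign["affluence"]

    # missingness completely at random over questionnaire responses
    questionnaire = [
        c
        for c in table.columns
        if c not in ("student_id", "school_id", "weight", "age_years", "sex", "region", "grade")
    ]
    if config.missing_rate > 0:
        mask = rng_miss.random((n, len(questionnaire))) < config.missing_rate
        for j, col in enumerate(questionnaire):
            col_mask = mask[:, j]
            if col_mask.any():
                if table[col].dtype == np.int64:
                    table[col] = table[col].astype(float)
                table.loc[col_mask, col] = np.nan

    per_student = pd.DataFrame(
        {
            "student_id": table["student_id"],
            "school_id": table["school_id"],
            "school_effect_w": u[school_of, 0],
            "school_effect_p": u[school_of, 1],
            "W": W,
            "P": P,
            "latent_mh": (W - P) / np.sqrt(2.0 - 2.0 * c),
            "measured_mh_z": zhat,
            **truth_cols,
        }
    )
    info = {
        "seed": config.seed,
        "icc_target": config.icc_school,
        "latent_school_fraction": f,
        "measurement_r2": r2,
        "target_d": {
            **{k: v.d for k, v in config.categorical_targets.items()},
            **{k: v.d for k, v in config.scale_targets.items()},
        },
        "cor_swb_pth": c,
        "missing_rate": config.missing_rate,
        "skew_strength": config.skew_strength,
        "rho_used": rho_used,
    }
    return table, GroundTruth(per_student, info)
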
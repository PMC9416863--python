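"""Continuous dual-factor mental-health score.

The measure combines subjective well-being (SWB) and psychopathology (PTH)
into one continuum:

1. each subscale (life satisfaction LS, positive affect PA, negative affect
   NA, internalized INT, externalized EXT) is T-standardized to mean 50,
   SD 10 over the scoring sample;
2. SWB = LS_T + PA_T - NA_T and PTH = INT_T + EXT_T, each re-standardized;
3. the mental-health score is the T-standardized difference SWB_T - PTH_T,
   so higher scores mean better overall mental health.

Standardization moments are unweighted sample moments (SD with the n-1
denominator) over students with non-missing inputs at that stage; survey
weights enter only in downstream descriptive/validation analyses. Every
stage's (mean, sd) pair is recorded as a calibration so new data can be
scored against a frozen reference sample.

The classical four-group categorization (Mentally Healthy / Symptomatic yet
Content / Asymptomatic yet Discontent / Mentally Unhealthy) is provided as a
deterministic quadrant rule on (SWB_T, PTH_T) with configurable cutoffs;
ties count as "high" on both axes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .scales import ScaleDefinition, build_subscale_panel

__all__ = [
    "DegenerateInputError",
    "GROUP_LABELS",
    "standardize_t",
    "compute_swb",
    "compute_pth",
    "compute_mh_score",
    "classify_dual_factor",
    "score_pipeline",
    "ScoringResult",
    "save_calibration",
    "load_calibration",
]


class DegenerateInputError(ValueError):
    """Standardization requested on a constant or near-empty vector."""


GROUP_LABELS = (
    "Mentally Healthy",
    "Symptomatic yet Content",
    "Asymptomatic yet Discontent",
    "Mentally Unhealthy",
)

#: order in which standardization stages run (and appear in calibrations)
_STAGES = (
    "life_satisfaction",
    "positive_affect",
    "negative_affect",
    "internalized",
    "externalized",
    "swb",
    "pth",
    "mh",
)


def standardize_t(
    values,
    reference: tuple[float, float] | None = None,
    return_params: bool = False,
):
    """T-standardize: ``50 + 10 * (x - m) / s``.

    ``(m, s)`` are the unweighted mean and n-1 SD of the non-missing input
    values, unless a frozen ``reference`` pair is supplied (scoring new data
    against an existing calibration). Missing values pass through as ``nan``
    and do not enter the moments.
    """
    x = np.asarray(values, dtype=float)
    if reference is not None:
        m, s = float(reference[0]), float(reference[1])
        if not s > 0:
            raise DegenerateInputError("reference sd must be positive")
    else:
        ok = x[~np.isnan(x)]
        if ok.size < 2:
            raise DegenerateInputError("need >=2 non-missing values to standardize")
        m = float(ok.mean())
        s = float(ok.std(ddof=1))
        if not s > 0:
            raise DegenerateInputError("zero variance: T-scores undefined")
    t = 50.0 + 10.0 * (x - m) / s
    if isinstance(values, pd.Series):
        t = pd.Series(t, index=values.index, name=values.name)
    return (t, (m, s)) if return_params else t


def compute_swb(ls_t, pa_t, na_t):
    """Raw subjective well-being composite: LS_T + PA_T - NA_T.

    Missing in any component propagates to the output.
    """
    return np.asarray(ls_t, float) + np.asarray(pa_t, float) - np.asarray(na_t, float)


def compute_pth(int_t, ext_t):
    """Raw psychopathology composite: INT_T + EXT_T."""
    return np.asarray(int_t, float) + np.asarray(ext_t, float)


def compute_mh_score(swb_t, pth_t, reference: tuple[float, float] | None = None,
                     return_params: bool = False):
    """Final mental-health score: T-standardized ``swb_t - pth_t``."""
    diff = np.asarray(swb_t, float) - np.asarray(pth_t, float)
    return standardize_t(diff, reference=reference, return_params=return_params)


def classify_dual_factor(swb_t, pth_t, thresholds: tuple[float, float] = (50.0, 50.0)):
    """Quadrant assignment on (SWB_T, PTH_T).

    ``swb_t >= swb_cut`` counts as high well-being and ``pth_t >= pth_cut``
    as high psychopathology. Rows with a missing coordinate get a missing
    group. Note the conventional group-prevalence figures depend on cutoffs
    external to this measure; ``(50, 50)`` is only a default.
    """
    swb = np.asarray(swb_t, float)
    pth = np.asarray(pth_t, float)
    swb_cut, pth_cut = float(thresholds[0]), float(thresholds[1])
    high_wb = swb >= swb_cut
    high_p = pth >= pth_cut
    out = np.select(
        [
            high_wb & ~high_p,
            high_wb & high_p,
            ~high_wb & ~high_p,
            ~high_wb & high_p,
        ],
        GROUP_LABELS,
        default=None,
    ).astype(object)
    out[np.isnan(swb) | np.isnan(pth)] = None
    return pd.Categorical(out, categories=list(GROUP_LABELS))


@dataclass
class ScoringResult:
    """Output of :func:`score_pipeline`."""

    panel: pd.DataFrame
    calibration: dict[str, tuple[float, float]]
    log: dict[str, object] = field(default_factory=dict)


def score_pipeline(
    table: pd.DataFrame,
    scale_definitions: Mapping[str, ScaleDefinition] | None = None,
    thresholds: tuple[float, float] = (50.0, 50.0),
    calibration: Mapping[str, tuple[float, float]] | None = None,
) -> ScoringResult:
    """Run subscale scoring and all composite steps on a raw item table.

    Returns a panel with the subscale scores, the five subscale T-scores,
    raw and T-standardized SWB/PTH composites, the final ``mh_score``, and
    the four-group ``dual_factor_group``, plus the stage calibrations and a
    scoring log (rows scored / missing per stage).

    With ``calibration`` supplied, every stage uses the frozen (mean, sd)
    pairs instead of the input sample's own moments.
    """
    log: dict[str, object] = {"n_input": int(len(table))}
    calib_out: dict[str, tuple[float, float]] = {}
    if len(table) == 0:
        log["warning"] = "empty input table; nothing scored"
        empty = pd.DataFrame()
        for col in ("ls_t", "pa_t", "na_t", "int_t", "ext_t", "swb_raw",
                    "pth_raw", "swb_t", "pth_t", "mh_score"):
            empty[col] = pd.Series(dtype=float)
        empty["dual_factor_group"] = pd.Categorical(
            [], categories=list(GROUP_LABELS)
        )
        return ScoringResult(empty, calib_out, log)
    panel = build_subscale_panel(table, scale_definitions)

    def _ref(stage: str):
        if calibration is None:
            return None
        if stage not in calibration:
            raise KeyError(f"calibration missing stage {stage!r}")
        return calibration[stage]

    def _stage(stage: str, values: pd.Series) -> pd.Series:
        # a stage with (almost) no observed input yields missing T-scores
        # for everyone rather than failing the whole run; a *constant*
        # observed input is still a hard error (no silent all-50 output)
        if values.notna().sum() < 2 and _ref(stage) is None:
            calib_out[stage] = (np.nan, np.nan)
            log[f"n_missing_{stage}"] = int(values.isna().sum())
            log.setdefault("warnings", []).append(
                f"stage {stage!r}: <2 non-missing inputs; all T-scores missing"
            )
            return pd.Series(np.nan, index=values.index, name=values.name)
        try:
            t, params = standardize_t(values, reference=_ref(stage), return_params=True)
        except DegenerateInputError as exc:
            raise DegenerateInputError(f"stage {stage!r}: {exc}") from exc
        calib_out[stage] = params
        log[f"n_missing_{stage}"] = int(values.isna().sum())
        return t

    panel["ls_t"] = _stage("life_satisfaction", panel["life_satisfaction"])
    panel["pa_t"] = _stage("positive_affect", panel["positive_affect"])
    panel["na_t"] = _stage("negative_affect", panel["negative_affect"])
    panel["int_t"] = _stage("internalized", panel["internalized"])
    panel["ext_t"] = _stage("externalized", panel["externalized"])

    panel["swb_raw"] = compute_swb(panel["ls_t"], panel["pa_t"], panel["na_t"])
    panel["pth_raw"] = compute_pth(panel["int_t"], panel["ext_t"])
    panel["swb_t"] = _stage("swb", panel["swb_raw"])
    panel["pth_t"] = _stage("pth", panel["pth_raw"])
    panel["mh_score"] = _stage("mh", panel["swb_t"] - panel["pth_t"])
    panel["dual_factor_group"] = classify_dual_factor(
        panel["swb_t"], panel["pth_t"], thresholds
    )
    log["n_scored"] = int(panel["mh_score"].notna().sum())
    log["thresholds"] = tuple(thresholds)
    return ScoringResult(panel, calib_out, log)


def save_calibration(calibration: Mapping[str, tuple[float, float]], path) -> None:
    """Write stage (mean, sd) pairs as JSON, in stage order."""
    ordered = {k: list(map(float, calibration[k])) for k in _STAGES if k in calibration}
    extra = {k: list(map(float, v)) for k, v in calibration.items() if k not in ordered}
    with open(path, "w") as fh:
        json.dump({**ordered, **extra}, fh, indent=2, sort_keys=False)
        fh.write("\n")


def load_calibration(path) -> dict[str, tuple[float, float]]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: (float(v[0]), float(v[1])) for k, v in raw.items()}
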
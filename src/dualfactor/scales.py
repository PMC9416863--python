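"""Subscale scoring for ordinal adolescent health-questionnaire items.

Converts raw item responses (Likert labels, frequency labels, or integer
codes) into the summed subscale scores used by the dual-factor mental-health
measure and its validation battery:

* well-being side — Cantril-ladder life satisfaction (0-10), single-item
  positive affect (0-4), two-item negative affect (0-8);
* psychopathology side — four-item internalized (psychological) symptoms
  (0-16) and a seven-behavior overt risk-taking scale for externalized
  symptoms (0-14);
* validation covariates — family and peer support (MSPSS four-item scales,
  0-16), student support (0-12), teacher support (0-36), prosocial behavior
  (0-25), plus the single-item covariates (academic marks, hopelessness,
  self-rated health, relative family affluence).

Scoring is a plain oriented sum: each item is coded 0..(levels-1) in the
direction of the construct, and a scale score is missing whenever any of its
items is missing (no imputation; downstream analyses are complete-case).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CodingError",
    "SchemaError",
    "ItemDefinition",
    "ScaleDefinition",
    "code_ordinal_response",
    "score_scale",
    "score_externalized",
    "score_negative_affect",
    "cronbach_alpha",
    "default_scale_definitions",
    "load_scale_config",
    "build_subscale_panel",
    "LIKERT_AGREE_5",
    "FREQUENCY_5",
    "RISK_FREQUENCY_3",
    "PROSOCIAL_6",
    "EXTERNALIZED_ITEMS",
]


class CodingError(ValueError):
    """A response label is not among an item's declared labels."""


class SchemaError(KeyError):
    """A required item column is absent from the input table."""


# ---------------------------------------------------------------------------
# canonical response-label sets (lowest construct level first)
# ---------------------------------------------------------------------------

LIKERT_AGREE_5: tuple[str, ...] = (
    "Strongly Disagree",
    "Disagree",
    "Neither Agree nor Disagree",
    "Agree",
    "Strongly Agree",
)

#: symptom-frequency options, "Rarely or never" .. "About every day"
FREQUENCY_5: tuple[str, ...] = (
    "Rarely or never",
    "About every month",
    "About every week",
    "More than once a week",
    "About every day",
)

#: trichotomized engagement in a risk behavior
RISK_FREQUENCY_3: tuple[str, ...] = ("None", "Infrequent", "Frequent")

#: six-level frequency options used by the prosocial-behavior items
PROSOCIAL_6: tuple[str, ...] = (
    "Never",
    "Rarely",
    "Sometimes",
    "Often",
    "Very often",
    "Always",
)

#: the seven overt risk-taking behaviors of the externalized-symptoms scale
EXTERNALIZED_ITEMS: tuple[str, ...] = (
    "ext_alcohol",
    "ext_drunkenness",
    "ext_smoking",
    "ext_alt_tobacco",
    "ext_fighting",
    "ext_energy_drinks",
    "ext_no_helmet",
)


@dataclass(frozen=True)
class ItemDefinition:
    """One questionnaire item inside a scale.

    ``labels`` orders the response options from raw code 0 upward; ``None``
    means the column already holds integer codes (e.g. the Cantril ladder).
    ``reverse`` flips the raw order when the printed option order opposes the
    construct the scale measures (orientation is applied before summing, so a
    reversed item still contributes 0..levels-1 in construct direction).
    """

    column: str
    levels: int
    labels: tuple[str, ...] | None = None
    reverse: bool = False

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError(f"item {self.column!r} needs >=2 response levels")
        if self.labels is not None and len(self.labels) != self.levels:
            raise ValueError(
                f"item {self.column!r}: {len(self.labels)} labels for "
                f"{self.levels} levels"
            )


@dataclass(frozen=True)
class ScaleDefinition:
    """A named multi-item scale with its declared score range."""

    name: str
    items: tuple[ItemDefinition, ...]
    score_range: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError(f"scale {self.name!r} has no items")
        cols = [it.column for it in self.items]
        if len(set(cols)) != len(cols):
            raise ValueError(f"scale {self.name!r} has duplicate item columns")
        implied = (0, sum(it.levels - 1 for it in self.items))
        if self.score_range is None:
            object.__setattr__(self, "score_range", implied)
        elif tuple(self.score_range) != implied:
            raise ValueError(
                f"scale {self.name!r}: declared range {self.score_range} "
                f"inconsistent with items (implied {implied})"
            )

    @property
    def columns(self) -> list[str]:
        return [it.column for it in self.items]


def _normalize_label(label: object) -> str:
    return str(label).strip().casefold()


def code_ordinal_response(label: object, item: ItemDefinition) -> float:
    """Map one response to its oriented integer code in ``0..levels-1``.

    Missing responses (``None``/``NaN``/empty string) propagate as ``nan``.
    Unknown labels raise :class:`CodingError` naming the item and the label.
    """
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return np.nan
    if item.labels is None:
        try:
            code = float(label)
        except (TypeError, ValueError):
            raise CodingError(
                f"item {item.column!r}: non-numeric response {label!r}"
            ) from None
        if np.isnan(code):
            return np.nan
        if code != int(code) or not 0 <= code <= item.levels - 1:
            raise CodingError(
                f"item {item.column!r}: code {label!r} outside 0..{item.levels - 1}"
            )
        code = int(code)
    else:
        key = _normalize_label(label)
        if key == "":
            return np.nan
        lookup = {_normalize_label(lab): i for i, lab in enumerate(item.labels)}
        if key not in lookup:
            raise CodingError(f"item {item.column!r}: unknown label {label!r}")
        code = lookup[key]
    return float(item.levels - 1 - code) if item.reverse else float(code)


def _code_column(series: pd.Series, item: ItemDefinition) -> pd.Series:
    """Vectorized :func:`code_ordinal_response` over one column."""
    if item.labels is None:
        coded = pd.to_numeric(series, errors="coerce")
        bad = series.notna() & coded.isna()
        # non-numeric strings that are not blank are coding errors, not missing
        if item.labels is None and bad.any():
            stripped = series[bad].astype(str).str.strip()
            bad_real = stripped != ""
            if bad_real.any():
                raise CodingError(
                    f"item {item.column!r}: non-numeric response "
                    f"{series[bad][bad_real].iloc[0]!r}"
                )
        valid = coded.dropna()
        if ((valid < 0) | (valid > item.levels - 1) | (valid % 1 != 0)).any():
            offender = valid[(valid < 0) | (valid > item.levels - 1) | (valid % 1 != 0)]
            raise CodingError(
                f"item {item.column!r}: code {offender.iloc[0]!r} outside "
                f"0..{item.levels - 1}"
            )
        out = coded.astype(float)
    else:
        lookup = {_normalize_label(lab): float(i) for i, lab in enumerate(item.labels)}
        keys = series.astype("object").map(
            lambda v: np.nan
            if v is None or (isinstance(v, float) and np.isnan(v)) or _normalize_label(v) == ""
            else _normalize_label(v)
        )
        unknown = keys.dropna()[~keys.dropna().isin(lookup)]
        if len(unknown):
            raise CodingError(
                f"item {item.column!r}: unknown label {series[unknown.index[0]]!r}"
            )
        out = keys.map(lookup).astype(float)
    if item.reverse:
        out = (item.levels - 1) - out
    return out


def score_scale(rows: pd.DataFrame, definition: ScaleDefinition) -> pd.Series:
    """Sum the oriented item codes of one scale.

    Returns a float Series aligned to ``rows.index``; a student's score is
    ``nan`` if any constituent item is missing.
    """
    missing_cols = [c for c in definition.columns if c not in rows.columns]
    if missing_cols:
        raise SchemaError(
            f"scale {definition.name!r}: missing column(s) {missing_cols}"
        )
    coded = pd.DataFrame(
        {it.column: _code_column(rows[it.column], it) for it in definition.items}
    )
    score = coded.sum(axis=1, skipna=False)
    score.name = definition.name
    return score


def score_externalized(rows: pd.DataFrame) -> pd.Series:
    """Overt risk-taking score: seven behaviors, None/Infrequent/Frequent = 0/1/2."""
    definition = ScaleDefinition(
        "externalized",
        tuple(ItemDefinition(c, 3, RISK_FREQUENCY_3) for c in EXTERNALIZED_ITEMS),
    )
    return score_scale(rows, definition)


def score_negative_affect(rows: pd.DataFrame) -> pd.Series:
    """Two-item negative affect (loneliness, helplessness), agreement coded up."""
    definition = ScaleDefinition(
        "negative_affect",
        (
            ItemDefinition("na_lonely", 5, LIKERT_AGREE_5),
            ItemDefinition("na_helpless", 5, LIKERT_AGREE_5),
        ),
    )
    return score_scale(rows, definition)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha, ``k/(k-1) * (1 - sum(var_i) / var(total))``.

    Variances use the n-1 denominator. For exchangeable items this equals the
    Spearman-Brown form ``k*rbar / (1 + (k-1)*rbar)`` in expectation.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("cronbach_alpha needs a 2-D matrix with >=2 items")
    if X.shape[0] < 3:
        raise ValueError("cronbach_alpha needs >=3 observations")
    if np.isnan(X).any():
        raise ValueError("cronbach_alpha requires complete data")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha undefined")
    return k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var)


# ---------------------------------------------------------------------------
# default scale dictionary (2014 Canadian HBSC item set)
# ---------------------------------------------------------------------------

def default_scale_definitions() -> dict[str, ScaleDefinition]:
    """Scale dictionary matching the synthetic cohort's column layout."""
    agree = LIKERT_AGREE_5

    def likert(cols: Iterable[str]) -> tuple[ItemDefinition, ...]:
        return tuple(ItemDefinition(c, 5, agree) for c in cols)

    return {
        "life_satisfaction": ScaleDefinition(
            "life_satisfaction", (ItemDefinition("ls_cantril", 11),)
        ),
        "positive_affect": ScaleDefinition(
            "positive_affect", (ItemDefinition("pa_energy", 5, agree),)
        ),
        "negative_affect": ScaleDefinition(
            "negative_affect", likert(["na_lonely", "na_helpless"])
        ),
        "internalized": ScaleDefinition(
            "internalized",
            tuple(
                ItemDefinition(c, 5, FREQUENCY_5)
                for c in ("int_low", "int_irritable", "int_nervous", "int_sleep")
            ),
        ),
        "externalized": ScaleDefinition(
            "externalized",
            tuple(ItemDefinition(c, 3, RISK_FREQUENCY_3) for c in EXTERNALIZED_ITEMS),
        ),
        "family_support": ScaleDefinition(
            "family_support", likert([f"fam_{i}" for i in range(1, 5)])
        ),
        "peer_support": ScaleDefinition(
            "peer_support", likert([f"peer_{i}" for i in range(1, 5)])
        ),
        "student_support": ScaleDefinition(
            "student_support", likert([f"stud_{i}" for i in range(1, 4)])
        ),
        "teacher_support": ScaleDefinition(
            "teacher_support", likert([f"teach_{i}" for i in range(1, 10)])
        ),
        "prosocial": ScaleDefinition(
            "prosocial",
            tuple(
                ItemDefinition(f"prosoc_{i}", 6, PROSOCIAL_6) for i in range(1, 6)
            ),
        ),
    }


def load_scale_config(path) -> dict[str, ScaleDefinition]:
    """Read a scale dictionary from a YAML file.

    Expected layout::

        family_support:
          items: [fam_1, fam_2, fam_3, fam_4]
          levels: 5
          labels: [Strongly Disagree, ..., Strongly Agree]   # optional
          reverse: [false, false, false, false]              # optional

    ``levels``/``labels``/``reverse`` may be scalars (applied to every item)
    or per-item lists.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"scale config {path!r} must be a mapping")
    out: dict[str, ScaleDefinition] = {}
    for name, entry in raw.items():
        cols: Sequence[str] = entry["items"]
        n = len(cols)

        def per_item(key, default):
            val = entry.get(key, default)
            if isinstance(val, (list, tuple)) and (
                key != "labels" or (len(val) and isinstance(val[0], (list, tuple)))
            ):
                if len(val) != n:
                    raise ValueError(f"{name}: {key} length != number of items")
                return list(val)
            return [val] * n

        levels = per_item("levels", 5)
        labels = per_item("labels", None)
        reverse = per_item("reverse", False)
        out[name] = ScaleDefinition(
            name,
            tuple(
                ItemDefinition(
                    c,
                    int(levels[i]),
                    tuple(labels[i]) if labels[i] is not None else None,
                    bool(reverse[i]),
                )
                for i, c in enumerate(cols)
            ),
        )
    return out


# single-item covariate codings -------------------------------------------

_ACADEMIC_LABELS = {
    "mostly letter grades below c": 1,
    "mostly cs": 2,
    "mostly bs and cs": 3,
    "mostly as and bs": 4,
    "mostly as": 5,
}

_SRH_COLLAPSE = {
    "excellent": "Excellent",
    "good": "Good",
    "fair": "Fair/poor",
    "poor": "Fair/poor",
    "fair/poor": "Fair/poor",
}


def _map_categorical(series: pd.Series, mapping: Mapping[str, object], what: str) -> pd.Series:
    keys = series.astype("object").map(
        lambda v: np.nan
        if v is None or (isinstance(v, float) and np.isnan(v)) or _normalize_label(v) == ""
        else _normalize_label(v)
    )
    unknown = keys.dropna()[~keys.dropna().isin(mapping)]
    if len(unknown):
        raise CodingError(f"{what}: unknown label {series[unknown.index[0]]!r}")
    return keys.map(dict(mapping))


def build_subscale_panel(
    table: pd.DataFrame,
    scale_definitions: Mapping[str, ScaleDefinition] | None = None,
) -> pd.DataFrame:
    """Score every scale and carry through the single-item covariates.

    Returns one row per student with identifier/weight/demographics, each
    scale score (float, ``nan`` = missing), and the normalized categorical
    covariates (``academic_performance`` as ordinal 1-5, ``hopelessness``
    Yes/No, ``self_rated_health`` collapsed to Excellent/Good/Fair-poor,
    ``relative_affluence``).
    """
    defs = dict(scale_definitions or default_scale_definitions())
    panel = pd.DataFrame(index=table.index)
    for col in ("student_id", "school_id", "weight", "age_years", "sex"):
        if col in table.columns:
            panel[col] = table[col]
    for name, definition in defs.items():
        panel[name] = score_scale(table, definition)
    if "academic_marks" in table.columns:
        panel["academic_performance"] = _map_categorical(
            table["academic_marks"], _ACADEMIC_LABELS, "academic_marks"
        )
    if "hopeless" in table.columns:
        panel["hopelessness"] = _map_categorical(
            table["hopeless"], {"yes": "Yes", "no": "No"}, "hopeless"
        )
    if "srh" in table.columns:
        panel["self_rated_health"] = _map_categorical(
            table["srh"], _SRH_COLLAPSE, "srh"
        )
    if "affluence" in table.columns:
        panel["relative_affluence"] = _map_categorical(
            table["affluence"],
            {
                "well-off": "Well-off",
                "average": "Average",
                "not well-off": "Not well-off",
            },
            "affluence",
        )
    return panel
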
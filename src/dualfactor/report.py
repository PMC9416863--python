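"""End-to-end orchestration and publication-style outputs.

``run_full_analysis`` wires the whole method together: score a raw item
table (or a freshly simulated cohort), restrict to complete cases with an
attrition report, and produce the descriptive/effect tables for the full
sample and for the Mentally Healthy subgroup, together with weighted
summary statistics (mean, SD, range, skewness) and the school-level ICC.
All outputs are plain CSV/text with a deterministic header recording the
seed and a hash of the configuration, so identical configs yield identical
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import composite, validity
from .scales import ScaleDefinition, default_scale_definitions
from .simulate import CohortConfig, generate_cohort

__all__ = ["RunConfig", "run_full_analysis", "render_table", "write_with_header"]

logger = logging.getLogger("dualfactor")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
logger.setLevel(logging.INFO)


@dataclass
class RunConfig:
    """Inputs and knobs of one full analysis run."""

    input_csv: str | None = None  # None -> simulate a default cohort
    output_dir: str = "dualfactor_out"
    scale_definitions: dict[str, ScaleDefinition] | None = None
    thresholds: tuple[float, float] = (50.0, 50.0)
    seed: int = 2014
    weights_col: str = "weight"
    subgroup: str | None = None  # dual-factor group label for the restricted table
    fit_models: bool = True
    cohort: CohortConfig | None = None

    def digest(self) -> str:
        payload = {
            "input_csv": self.input_csv,
            "thresholds": list(self.thresholds),
            "seed": self.seed,
            "weights_col": self.weights_col,
            "subgroup": self.subgroup,
            "fit_models": self.fit_models,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def write_with_header(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    """CSV with a comment header carrying seed + config hash (UTF-8, '.')."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# dualfactor seed={config.seed} config={config.digest()}\n")
        df.to_csv(fh, index=False, float_format="%.6g", lineterminator="\n")


def render_table(effect_table: pd.DataFrame, title: str = "") -> str:
    """Fixed-column text rendering of an effect table.

    Means/SDs at 1 dp, Cohen's d at 2 dp, reference rows marked ``ref``.
    """
    if len(effect_table) == 0:
        raise validity.AnalysisError("cannot render an empty effect table")
    lines = []
    if title:
        lines.append(title)
    header = (
        f"{'':28s}{'n (wtd)':>10s}{'(%)':>8s}{'Mean':>8s}{'(SD)':>8s}"
        f"{'p':>10s}{'p-trend':>10s}{'d':>8s}"
    )
    lines.append(header)
    lines.append("-" * len(header))
    for cov, block in effect_table.groupby("covariate", sort=False):
        lines.append(f"{cov}")
        for _, row in block.iterrows():
            if row["reference"]:
                p_txt, d_txt = "ref", "ref"
            else:
                p_txt = (
                    "<0.001"
                    if row["p_adjusted"] < 0.001
                    else f"{row['p_adjusted']:.3f}"
                ) if pd.notna(row["p_adjusted"]) else ""
                d_txt = f"{row['cohens_d']:.2f}"
            pt = row["p_trend"]
            pt_txt = (
                ("<0.001" if pt < 0.001 else f"{pt:.3f}") if pd.notna(pt) else ""
            )
            lines.append(
                f"  {str(row['group']):26s}{row['n_weighted']:>10,.0f}"
                f"{row['pct']:>7.1f}%{row['mean']:>8.1f}{row['sd']:>8.1f}"
                f"{p_txt:>10s}{pt_txt:>10s}{d_txt:>8s}"
            )
    return "\n".join(lines) + "\n"


def run_full_analysis(config: RunConfig) -> dict[str, object]:
    """Score, filter, describe, and test; write the artifact bundle.

    Returns the in-memory artifacts (scored panel, effect tables, summary,
    attrition report) and writes them under ``config.output_dir``. Raises
    with the failing stage's name on any stage error.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        if config.input_csv is not None:
            table = pd.read_csv(config.input_csv, comment="#")
            logger.info("loaded %d rows from %s", len(table), config.input_csv)
        else:
            cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
            table, truth = generate_cohort(cohort_cfg)
            logger.info(
                "simulated %d students in %d schools (seed=%d)",
                len(table), cohort_cfg.n_schools, cohort_cfg.seed,
            )

        stage = "score"
        defs = config.scale_definitions or default_scale_definitions()
        result = composite.score_pipeline(table, defs, thresholds=config.thresholds)
        panel = result.panel
        logger.info("scored %s of %s students", result.log.get("n_scored"), len(panel))

        stage = "complete_cases"
        analysis_vars = [
            "mh_score", "age_years", "sex",
            "relative_affluence", "family_support", "peer_support",
            "student_support", "teacher_support", "academic_performance",
            "self_rated_health", "hopelessness", "prosocial",
        ]
        analysis_vars = [v for v in analysis_vars if v in panel.columns]
        filtered, attrition = validity.complete_case_filter(panel, analysis_vars)

        stage = "describe"
        w = filtered[config.weights_col]
        mean, sd = validity.weighted_mean_sd(filtered["mh_score"], w)
        skew = validity.skewness(filtered["mh_score"], w)
        comps = validity.fit_icc(panel["mh_score"], panel["school_id"])
        summary = {
            "n_scored": int(panel["mh_score"].notna().sum()),
            "n_complete": int(len(filtered)),
            "weighted_mean": mean,
            "weighted_sd": sd,
            "min": float(filtered["mh_score"].min()),
            "max": float(filtered["mh_score"].max()),
            "skewness": skew,
            "icc_school": comps.icc,
            "sigma2_school": comps.sigma2_school,
            "sigma2_residual": comps.sigma2_residual,
        }

        stage = "effect_table_full"
        effects_full = validity.build_effect_table(
            filtered, weights_col=config.weights_col, fit_models=config.fit_models
        )

        stage = "effect_table_subgroup"
        subgroup_label = config.subgroup or "Mentally Healthy"
        mask = filtered["dual_factor_group"].astype(object) == subgroup_label
        if mask.sum() == 0:
            raise validity.AnalysisError(
                f"subgroup {subgroup_label!r} is empty; nothing to analyze"
            )
        subgroup_covs = tuple(
            c for c in validity.default_covariates()
            if c.column not in ("sex", "age_band", "relative_affluence", "hopelessness")
        )
        effects_sub = validity.build_effect_table(
            filtered,
            covariates=subgroup_covs,
            weights_col=config.weights_col,
            subgroup=mask,
            fit_models=config.fit_models,
        )

        stage = "write"
        write_with_header(panel, out / "composite_panel.csv", config)
        write_with_header(attrition, out / "attrition.csv", config)
        write_with_header(effects_full, out / "effects_full.csv", config)
        write_with_header(effects_sub, out / "effects_mentally_healthy.csv", config)
        composite.save_calibration(result.calibration, out / "calibration.json")
        with open(out / "summary.json", "w") as fh:
            json.dump({"seed": config.seed, "config": config.digest(), **summary}, fh, indent=2)
            fh.write("\n")
        with open(out / "tables.txt", "w", encoding="utf-8") as fh:
            fh.write(f"# dualfactor seed={config.seed} config={config.digest()}\n")
            fh.write(render_table(effects_full, "Full sample by average mental health score"))
            fh.write("\n")
            fh.write(render_table(effects_sub, f"{subgroup_label} subgroup"))
        logger.info("artifacts written to %s", out)
    except Exception:
        logger.error("run failed at stage %r", stage)
        raise

    return {
        "panel": panel,
        "filtered": filtered,
        "attrition": attrition,
        "summary": summary,
        "effects_full": effects_full,
        "effects_subgroup": effects_sub,
        "calibration": result.calibration,
    }
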
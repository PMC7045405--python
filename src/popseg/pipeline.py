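"""End-to-end orchestration: generate -> segment -> score -> evaluate.

``run_pipeline`` produces, in the output directory: the survey and outcome
tables (generate mode), the segmented cohort table, one summary table per
report figure/table analogue (``fig1_eq5d``, ``fig2_mortality``,
``fig3_admissions``, ``fig4_ed``, ``fig5_soc``, ``table3_chisq``), a
``table2_segments`` composition table, per-table column-dictionary schema
files, and a run manifest (config + package version + seed).  Identical
config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .cohort import Cohort, load_cohort, validate_cohort, write_cohort, write_segmented_cohort
from .conditions import ConditionMap, default_condition_map
from .eq5d import ValueSet, default_value_set
from .exceptions import PopsegError, ValidationError
from .segmentation import SCHEMES, assign_all
from .stats import build_validity_report
from .synthetic import GeneratorParams, default_generator_params, generate_cohort

logger = logging.getLogger(__name__)

_TABLE_FILES = {
    "eq5d": "fig1_eq5d.csv",
    "mortality": "fig2_mortality.csv",
    "admissions": "fig3_admissions.csv",
    "ed": "fig4_ed.csv",
    "soc": "fig5_soc.csv",
    "chisq": "table3_chisq.csv",
}

_COLUMN_DOC = {
    "scheme": "segmentation scheme name",
    "segment_id": "canonical segment id (blank = all-subjects reference row)",
    "segment_label": "segment label",
    "n": "subjects in segment",
    "n_scored": "subjects with complete EQ-5D responses",
    "mean_eq5d": "mean EQ-5D index among scored subjects",
    "share_pct": "percent of cohort in segment (half-up, 1 decimal)",
    "mean": "mean outcome (probability for mortality, visits/person otherwise)",
    "se": "standard error (see se_method)",
    "ci_low": "lower confidence bound",
    "ci_high": "upper confidence bound",
    "se_method": "standard-error family: binomial/poisson/normal",
    "outcome": "dichotomized outcome tested",
    "statistic": "Pearson chi-squared statistic",
    "df": "degrees of freedom (#non-empty segments - 1)",
    "p_value": "p-value from the chi-squared distribution",
    "stars": "significance: * p<0.05, ** p<0.01, *** p<0.001",
    "n_low_expected": "cells with expected count < 5 (flagged, not corrected)",
    "degenerate": "True if the table was unsuitable for the test",
    "note": "degeneracy reason, if any",
    "mean_age": "mean age in years",
    "pct_male": "percent male",
    "difficulty_expenses_pct": "percent reporting difficulty meeting expenses",
}


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    out_dir: str
    survey_path: Optional[str] = None      # segment/evaluate an existing cohort ...
    outcomes_path: Optional[str] = None
    generate: bool = False                 # ... or generate one
    n: Optional[int] = None
    seed: int = 0
    schemes: Sequence[str] = tuple(SCHEMES)
    value_set_path: Optional[str] = None
    condition_map_path: Optional[str] = None
    generator_params_path: Optional[str] = None
    ci_level: float = 0.95
    strict: bool = False
    plots: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schemes"] = list(self.schemes)
        return d


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)
    schema = {col: _COLUMN_DOC.get(col, "") for col in df.columns}
    path.with_suffix(".schema.json").write_text(
        json.dumps(schema, indent=2) + "\n", encoding="utf-8"
    )


def _table2(cohort: Cohort, assignments, value_set: ValueSet) -> pd.DataFrame:
    from .stats import segment_share

    subjects = {s.subject_id: s for s in cohort.subjects}
    rows = []
    for scheme in sorted({a.scheme for a in assignments}):
        groups: dict = {}
        labels: dict = {}
        for a in assignments:
            if a.scheme != scheme:
                continue
            groups.setdefault(a.segment_id, []).append(subjects[a.subject_id])
            labels[a.segment_id] = a.segment_label
        total = len(cohort.subjects)
        for seg_id in sorted(groups):
            members = groups[seg_id]
            scored = [value_set.score(s.eq5d_responses) for s in members
                      if s.eq5d_responses is not None]
            expenses = [s.difficulty_meeting_expenses for s in members
                        if s.difficulty_meeting_expenses is not None]
            rows.append({
                "scheme": scheme,
                "segment_id": seg_id,
                "segment_label": labels[seg_id],
                "n": len(members),
                "share_pct": segment_share(len(members), total),
                "mean_age": round(sum(s.age for s in members) / len(members), 1),
                "pct_male": segment_share(sum(s.sex == "male" for s in members), len(members)),
                "mean_eq5d": round(sum(scored) / len(scored), 3) if scored else None,
                "difficulty_expenses_pct": (
                    segment_share(sum(expenses), len(expenses)) if expenses else None
                ),
            })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns {table name: output path}.

    Raises a :class:`PopsegError` subclass on any failure; nothing is left
    half-written because all tables are assembled before the first write.
    """
    out_dir = Path(config.out_dir)

    if config.generate:
        params = (GeneratorParams.from_yaml(config.generator_params_path)
                  if config.generator_params_path else default_generator_params())
        cohort = generate_cohort(params, seed=config.seed, n=config.n)
        logger.info("generated cohort of %d subjects (seed=%d)", len(cohort), config.seed)
    else:
        if config.survey_path is None:
            raise PopsegError("config must either set generate=True or name a survey file")
        cohort = load_cohort(config.survey_path, config.outcomes_path, strict=config.strict)
        logger.info("loaded cohort of %d subjects from %s", len(cohort), config.survey_path)

    findings = validate_cohort(cohort)
    if findings:
        message = "; ".join(
            f"{f.subject_id}/{f.field}: {f.rule}" for f in findings[:5]
        ) + ("..." if len(findings) > 5 else "")
        if config.strict:
            raise ValidationError(f"{len(findings)} validation finding(s): {message}")
        logger.warning("%d validation finding(s): %s", len(findings), message)

    cmap = (ConditionMap.from_yaml(config.condition_map_path)
            if config.condition_map_path else default_condition_map())
    value_set = (ValueSet.from_yaml(config.value_set_path)
                 if config.value_set_path else default_value_set())

    assignments = assign_all(cohort, schemes=config.schemes, condition_map=cmap)

    artifacts: dict = {}
    tables: dict = {"table2_segments": _table2(cohort, assignments, value_set)}
    if cohort.outcomes:
        report = build_validity_report(cohort, assignments, schemes=config.schemes,
                                       value_set=value_set, level=config.ci_level)
        tables.update(report)
    else:
        from .eq5d import summarize_utility
        tables["eq5d"] = summarize_utility(cohort, assignments, value_set)

    out_dir.mkdir(parents=True, exist_ok=True)
    if config.generate:
        write_cohort(cohort, out_dir / "survey.csv", out_dir / "outcomes.csv")
        artifacts["survey"] = str(out_dir / "survey.csv")
        artifacts["outcomes"] = str(out_dir / "outcomes.csv")
    write_segmented_cohort(cohort, assignments, out_dir / "segmented.csv")
    artifacts["segmented"] = str(out_dir / "segmented.csv")
    for name, df in tables.items():
        filename = _TABLE_FILES.get(name, f"{name}.csv")
        _write_table(df, out_dir / filename)
        artifacts[name] = str(out_dir / filename)

    if config.plots:
        from .plots import save_report_plots

        for path in save_report_plots(tables, out_dir):
            artifacts[Path(path).stem + "_png"] = path

    manifest = {
        "popseg_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_subjects": len(cohort),
        "n_assignments": len(assignments),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    artifacts["manifest"] = str(out_dir / "manifest.json")
    return artifacts
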
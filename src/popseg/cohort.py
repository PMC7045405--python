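"""Survey / outcome data model with delimited-text readers and writers.

A cohort is a list of :class:`SubjectRecord` (one per survey respondent,
eligibility age 60+) optionally joined one-to-one to a list of
:class:`OutcomeRecord` carrying the 180-day follow-up outcomes (death flag
and hospital-admission / emergency-department / specialist-outpatient-clinic
visit counts).

Tables are delimited text (comma default, tab accepted), UTF-8, one header
row; booleans are encoded 0/1 and missing values as empty cells.  The column
dictionary ships as ``data/survey_schema.yaml``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .exceptions import CompletenessError, FormatError, IntegrityError, ValidationError

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
MENTAL_HEALTH_LEVELS = ("none", "mild", "severe")

#: survey boolean columns that feed segmentation and must be resolved
#: (missing -> False in non-strict mode, fatal in strict mode)
SEGMENTATION_FLAGS = (
    "any_symptomatic_condition",
    "cancer",
    "acute_event_recent",
    "organ_failure_condition",
    "progressive_decline_condition",
    "end_of_life",
    "adl_deficit",
    "skilled_nursing_need",
    "iadl_deficit",
    "social_support_deficit",
    "activation_deficit",
    "disruptive_behaviour",
)

EQ5D_COLUMNS = (
    "eq5d_mobility",
    "eq5d_self_care",
    "eq5d_usual_activities",
    "eq5d_pain_discomfort",
    "eq5d_anxiety_depression",
)

SURVEY_COLUMNS = (
    ("subject_id", "age", "sex", "proxy_respondent", "chronic_conditions", "mental_health")
    + SEGMENTATION_FLAGS
    + EQ5D_COLUMNS
    + ("difficulty_meeting_expenses",)
)

OUTCOME_COLUMNS = (
    "subject_id",
    "died_180d",
    "n_admissions_180d",
    "n_ed_visits_180d",
    "n_soc_visits_180d",
)


@dataclass
class SubjectRecord:
    """One respondent's baseline survey variables."""

    subject_id: str
    age: int
    sex: str
    proxy_respondent: bool = False
    chronic_conditions: frozenset = frozenset()
    any_symptomatic_condition: bool = False
    mental_health: str = "none"
    cancer: bool = False
    acute_event_recent: bool = False
    organ_failure_condition: bool = False
    progressive_decline_condition: bool = False
    end_of_life: bool = False  # carried in the model; never set by this survey
    adl_deficit: bool = False
    skilled_nursing_need: bool = False
    iadl_deficit: bool = False
    social_support_deficit: bool = False
    activation_deficit: bool = False
    disruptive_behaviour: bool = False
    eq5d_responses: Optional[tuple] = None  # (mobility, self-care, usual, pain, anxiety)
    difficulty_meeting_expenses: Optional[bool] = None


@dataclass
class OutcomeRecord:
    """One respondent's 180-day outcomes."""

    subject_id: str
    died_180d: bool
    n_admissions_180d: int
    n_ed_visits_180d: int
    n_soc_visits_180d: int


@dataclass
class Cohort:
    subjects: list = field(default_factory=list)
    outcomes: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subjects)

    def outcomes_by_id(self) -> dict:
        return {o.subject_id: o for o in self.outcomes}

    def subject_ids(self) -> list:
        return [s.subject_id for s in self.subjects]


@dataclass(frozen=True)
class Finding:
    """A single validation finding (never an exception)."""

    subject_id: str
    field: str
    rule: str
    message: str


# ---------------------------------------------------------------------------
# parsing helpers

_TRUE = {"1", "true", "True"}
_FALSE = {"0", "false", "False"}


def _parse_bool(cell, row: int, column: str) -> Optional[bool]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return None
    text = str(cell).strip()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise FormatError(f"row {row}, column {column!r}: cannot parse boolean {cell!r}")


def _parse_int(cell, row: int, column: str) -> Optional[int]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return None
    try:
        return int(str(cell).strip())
    except ValueError:
        raise FormatError(f"row {row}, column {column!r}: cannot parse integer {cell!r}") from None


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _subject_from_row(row: Mapping, idx: int, strict: bool) -> SubjectRecord:
    sid = str(row["subject_id"]).strip()
    age = _parse_int(row["age"], idx, "age")
    if age is None:
        raise ValidationError(f"row {idx}: missing required field 'age'")
    sex = str(row["sex"]).strip()
    if sex not in SEXES:
        raise FormatError(f"row {idx}, column 'sex': expected male/female, got {row['sex']!r}")
    mh = str(row.get("mental_health", "") or "none").strip() or "none"
    if mh not in MENTAL_HEALTH_LEVELS:
        raise FormatError(f"row {idx}, column 'mental_health': invalid level {mh!r}")
    conditions = frozenset(
        c.strip() for c in str(row.get("chronic_conditions", "") or "").split(";") if c.strip()
    )

    flags = {}
    for name in SEGMENTATION_FLAGS:
        value = _parse_bool(row.get(name, ""), idx, name)
        if value is None:
            if strict:
                raise ValidationError(
                    f"row {idx}, column {name!r}: missing segmentation input for "
                    f"subject {sid!r} (strict mode)"
                )
            logger.warning(
                "subject %s row %d: missing flag %s recorded as absent (non-strict)",
                sid, idx, name,
            )
            value = False
        flags[name] = value

    levels = [_parse_int(row.get(c, ""), idx, c) for c in EQ5D_COLUMNS]
    eq5d = tuple(levels) if all(v is not None for v in levels) else None
    proxy = _parse_bool(row.get("proxy_respondent", ""), idx, "proxy_respondent") or False
    expenses = _parse_bool(row.get("difficulty_meeting_expenses", ""), idx, "difficulty_meeting_expenses")

    return SubjectRecord(
        subject_id=sid,
        age=age,
        sex=sex,
        proxy_respondent=proxy,
        chronic_conditions=conditions,
        mental_health=mh,
        eq5d_responses=eq5d,
        difficulty_meeting_expenses=expenses,
        **flags,
    )


def load_cohort(
    survey_path: str | Path,
    outcomes_path: str | Path | None = None,
    strict: bool = False,
) -> Cohort:
    """Read a survey table (and optional outcomes table) into a validated Cohort.

    Non-strict mode records missing segmentation flags as absent (False) with
    a logged warning; strict mode raises :class:`ValidationError` naming the
    row and column.  Row order is preserved.
    """
    df = _read_table(survey_path, required=("subject_id", "age", "sex"))
    subjects = [_subject_from_row(row, idx, strict) for idx, row in df.iterrows()]

    seen, duplicates = set(), []
    for s in subjects:
        if s.subject_id in seen:
            duplicates.append(s.subject_id)
        seen.add(s.subject_id)
    if duplicates:
        raise IntegrityError(f"duplicate subject_id(s): {sorted(set(duplicates))}")

    outcomes: list = []
    if outcomes_path is not None:
        odf = _read_table(outcomes_path, required=OUTCOME_COLUMNS)
        for idx, row in odf.iterrows():
            counts = {}
            for name in OUTCOME_COLUMNS[2:]:
                value = _parse_int(row[name], idx, name)
                if value is None or value < 0:
                    raise FormatError(
                        f"row {idx}, column {name!r}: expected non-negative count"
                    )
                counts[name] = value
            died = _parse_bool(row["died_180d"], idx, "died_180d")
            if died is None:
                raise FormatError(f"row {idx}: missing died_180d")
            outcomes.append(OutcomeRecord(str(row["subject_id"]).strip(), died, **counts))
        orphans = sorted({o.subject_id for o in outcomes} - seen)
        if orphans:
            raise IntegrityError(f"outcome rows without matching subject: {orphans}")
        dupes = [o for o in pd.Series([o.subject_id for o in outcomes]).value_counts().items() if o[1] > 1]
        if dupes:
            raise IntegrityError(f"duplicate outcome rows for subject(s): {[d[0] for d in dupes]}")

    return Cohort(
        subjects=subjects,
        outcomes=outcomes,
        provenance={"source": str(survey_path), "outcomes_source": str(outcomes_path) if outcomes_path else None},
    )


# ---------------------------------------------------------------------------
# validation


def validate_cohort(cohort: Cohort) -> list:
    """Check every type invariant; returns findings, never raises."""
    findings: list = []
    seen = set()
    for s in cohort.subjects:
        if s.subject_id in seen:
            findings.append(Finding(s.subject_id, "subject_id", "unique_subject_id",
                                    f"subject_id {s.subject_id!r} occurs more than once"))
        seen.add(s.subject_id)
        if s.age < 60:
            findings.append(Finding(s.subject_id, "age", "age_ge_60",
                                    f"age {s.age} below study eligibility (60+)"))
        if s.sex not in SEXES:
            findings.append(Finding(s.subject_id, "sex", "sex_domain", f"invalid sex {s.sex!r}"))
        if s.mental_health not in MENTAL_HEALTH_LEVELS:
            findings.append(Finding(s.subject_id, "mental_health", "mental_health_domain",
                                    f"invalid level {s.mental_health!r}"))
        if s.any_symptomatic_condition and len(s.chronic_conditions) == 0:
            findings.append(Finding(s.subject_id, "any_symptomatic_condition",
                                    "symptomatic_implies_condition",
                                    "symptomatic flag set with empty chronic-condition set"))
        if s.eq5d_responses is not None:
            if len(s.eq5d_responses) != 5 or any(
                not isinstance(v, int) or v < 1 for v in s.eq5d_responses
            ):
                findings.append(Finding(s.subject_id, "eq5d_responses", "eq5d_levels",
                                        f"invalid EQ-5D levels {s.eq5d_responses!r}"))
    outcome_ids = set()
    for o in cohort.outcomes:
        outcome_ids.add(o.subject_id)
        if o.subject_id not in seen:
            findings.append(Finding(o.subject_id, "subject_id", "outcome_join_total",
                                    "outcome row has no matching subject"))
        for name in ("n_admissions_180d", "n_ed_visits_180d", "n_soc_visits_180d"):
            if getattr(o, name) < 0:
                findings.append(Finding(o.subject_id, name, "count_nonnegative",
                                        f"{name} is negative"))
    if cohort.outcomes:
        for sid in seen - outcome_ids:
            findings.append(Finding(sid, "subject_id", "outcome_join_total",
                                    "subject has no outcome row"))
    return findings


# ---------------------------------------------------------------------------
# writing


def _format_bool(value: Optional[bool]) -> str:
    return "" if value is None else str(int(value))


def survey_frame(subjects: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Serialize subjects to the survey table layout (strings, 0/1 booleans)."""
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "age": str(s.age),
            "sex": s.sex,
            "proxy_respondent": _format_bool(s.proxy_respondent),
            "chronic_conditions": ";".join(sorted(s.chronic_conditions)),
            "mental_health": s.mental_health,
        }
        for name in SEGMENTATION_FLAGS:
            row[name] = _format_bool(getattr(s, name))
        for i, col in enumerate(EQ5D_COLUMNS):
            row[col] = "" if s.eq5d_responses is None else str(s.eq5d_responses[i])
        row["difficulty_meeting_expenses"] = _format_bool(s.difficulty_meeting_expenses)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(SURVEY_COLUMNS), dtype=str)


def outcome_frame(outcomes: Iterable[OutcomeRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": o.subject_id,
            "died_180d": str(int(o.died_180d)),
            "n_admissions_180d": str(o.n_admissions_180d),
            "n_ed_visits_180d": str(o.n_ed_visits_180d),
            "n_soc_visits_180d": str(o.n_soc_visits_180d),
        }
        for o in outcomes
    ]
    return pd.DataFrame(rows, columns=list(OUTCOME_COLUMNS), dtype=str)


def write_cohort(cohort: Cohort, survey_path: str | Path,
                 outcomes_path: str | Path | None = None) -> None:
    """Write the survey (and optionally outcomes) tables; round-trips exactly."""
    survey_frame(cohort.subjects).to_csv(survey_path, index=False)
    if outcomes_path is not None:
        outcome_frame(cohort.outcomes).to_csv(outcomes_path, index=False)


def write_segmented_cohort(cohort: Cohort, assignments: Sequence, path: str | Path) -> None:
    """Write the survey table with one ``segment_<scheme>`` column per scheme.

    ``assignments`` is a flat list of SegmentAssignment covering every subject
    for every scheme present in the list; any gap raises CompletenessError.
    """
    by_scheme: dict = {}
    for a in assignments:
        by_scheme.setdefault(a.scheme, {})[a.subject_id] = a
    df = survey_frame(cohort.subjects)
    for scheme in sorted(by_scheme):
        table = by_scheme[scheme]
        missing = [s.subject_id for s in cohort.subjects if s.subject_id not in table]
        if missing:
            raise CompletenessError(
                f"scheme {scheme!r}: no assignment for subject(s) {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        df[f"segment_{scheme}"] = [str(table[s.subject_id].segment_id) for s in cohort.subjects]
    df.to_csv(path, index=False)
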
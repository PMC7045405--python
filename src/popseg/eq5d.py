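"""EQ-5D health-utility scoring with pluggable value-set tariffs.

The EQ-5D index collapses five self-reported dimensions (mobility,
self-care, usual activities, pain/discomfort, anxiety/depression) into a
single utility anchored at 1.0 = full health.  Scoring is table-driven by a
:class:`ValueSet`: the shipped default is the published UK time-trade-off
tariff for the 3-level instrument (additive decrements, floor −0.594), and
any user tariff in the same file format can be swapped in.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import EQ5D_COLUMNS, Cohort
from .exceptions import DomainError

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)


@dataclass(frozen=True)
class EQ5DProfile:
    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def levels(self) -> tuple:
        return (
            self.mobility,
            self.self_care,
            self.usual_activities,
            self.pain_discomfort,
            self.anxiety_depression,
        )


def _as_levels(profile) -> tuple:
    if isinstance(profile, EQ5DProfile):
        return profile.levels()
    levels = tuple(int(v) for v in profile)
    if len(levels) != 5:
        raise DomainError(f"an EQ-5D profile has 5 dimensions, got {len(levels)}")
    return levels


@dataclass
class ValueSet:
    """An additive EQ-5D tariff.

    index = full_health_value
            − constant_any_problem · 1{any level > 1}
            − Σ_d decrements[d][level_d]
            − any_level3_term · 1{any level == levels_per_dimension}
    """

    name: str
    levels_per_dimension: int
    decrements: Mapping[str, Mapping[int, float]]
    constant_any_problem: float = 0.0
    any_level3_term: float = 0.0
    full_health_value: float = 1.0

    def __post_init__(self) -> None:
        if self.full_health_value != 1.0:
            raise DomainError("full_health_value must equal 1.0")
        for dim in DIMENSIONS:
            if dim not in self.decrements:
                raise DomainError(f"tariff {self.name!r} lacks decrements for {dim!r}")

    @property
    def floor_value(self) -> float:
        """Utility of the all-worst profile."""
        worst = (self.levels_per_dimension,) * 5
        return self.score(worst)

    def score(self, profile) -> float:
        levels = _as_levels(profile)
        for dim, level in zip(DIMENSIONS, levels):
            if not 1 <= level <= self.levels_per_dimension:
                raise DomainError(
                    f"dimension {dim!r}: level {level} outside 1..{self.levels_per_dimension}"
                )
        utility = self.full_health_value
        if any(level > 1 for level in levels):
            utility -= self.constant_any_problem
        for dim, level in zip(DIMENSIONS, levels):
            if level > 1:
                utility -= float(self.decrements[dim][level])
        if any(level == self.levels_per_dimension for level in levels):
            utility -= self.any_level3_term
        return utility

    def all_profiles(self) -> Iterable[tuple]:
        return itertools.product(range(1, self.levels_per_dimension + 1), repeat=5)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ValueSet":
        with open(path, encoding="utf-8") as fh:
            return cls._from_dict(yaml.safe_load(fh))

    @classmethod
    def _from_dict(cls, raw: Mapping) -> "ValueSet":
        return cls(
            name=raw["name"],
            levels_per_dimension=int(raw["levels_per_dimension"]),
            decrements={d: {int(k): float(v) for k, v in m.items()}
                        for d, m in raw["decrements"].items()},
            constant_any_problem=float(raw.get("constant_any_problem", 0.0)),
            any_level3_term=float(raw.get("any_level3_term", 0.0)),
            full_health_value=float(raw.get("full_health_value", 1.0)),
        )


def default_value_set() -> ValueSet:
    """The UK TTO 3-level tariff shipped with the package."""
    ref = resources.files("popseg.data").joinpath("uk_tto_3l.yaml")
    return ValueSet._from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


def score_index(profile, value_set: Optional[ValueSet] = None) -> float:
    """Score one profile; deterministic table lookup."""
    return (value_set or default_value_set()).score(profile)


class EQ5DScorer(BaseEstimator, TransformerMixin):
    """Transformer scoring the EQ-5D index over a survey-layout DataFrame.

    Expects the five ``eq5d_*`` level columns; ``transform`` returns a float
    array of utilities with NaN where any dimension response is missing.
    """

    def __init__(self, value_set: Optional[ValueSet] = None):
        self.value_set = value_set

    def fit(self, X=None, y=None):
        self.value_set_ = self.value_set or default_value_set()
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "value_set_"):
            self.fit()
        missing = [c for c in EQ5D_COLUMNS if c not in X.columns]
        if missing:
            raise DomainError(f"input lacks EQ-5D column(s) {missing}")
        out = np.full(len(X), np.nan)
        levels = X[list(EQ5D_COLUMNS)].to_numpy()
        for i, row in enumerate(levels):
            try:
                parsed = tuple(int(v) for v in row)
            except (TypeError, ValueError):
                continue
            out[i] = self.value_set_.score(parsed)
        return out


def summarize_utility(
    cohort: Cohort,
    assignments: Sequence,
    value_set: Optional[ValueSet] = None,
) -> pd.DataFrame:
    """Mean EQ-5D index by scheme and segment, plus an all-subjects row.

    Subjects with missing dimension responses are excluded from ``n_scored``
    (they still belong to their segments).
    """
    vs = value_set or default_value_set()
    utility = {
        s.subject_id: (vs.score(s.eq5d_responses) if s.eq5d_responses is not None else None)
        for s in cohort.subjects
    }
    rows = []
    schemes = sorted({a.scheme for a in assignments})
    for scheme in schemes:
        per_segment: dict = {}
        labels: dict = {}
        for a in assignments:
            if a.scheme != scheme:
                continue
            per_segment.setdefault(a.segment_id, []).append(utility[a.subject_id])
            labels[a.segment_id] = a.segment_label
        for seg_id in sorted(per_segment):
            scored = [u for u in per_segment[seg_id] if u is not None]
            rows.append({
                "scheme": scheme,
                "segment_id": seg_id,
                "segment_label": labels[seg_id],
                "n": len(per_segment[seg_id]),
                "n_scored": len(scored),
                "mean_eq5d": float(np.mean(scored)) if scored else np.nan,
            })
        scored_all = [u for u in utility.values() if u is not None]
        rows.append({
            "scheme": scheme,
            "segment_id": pd.NA,
            "segment_label": "(all subjects)",
            "n": len(cohort.subjects),
            "n_scored": len(scored_all),
            "mean_eq5d": float(np.mean(scored_all)) if scored_all else np.nan,
        })
    return pd.DataFrame(
        rows, columns=["scheme", "segment_id", "segment_label", "n", "n_scored", "mean_eq5d"]
    )
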
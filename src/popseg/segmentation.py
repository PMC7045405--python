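"""Rule-cascade segment assignment for the four segmentation schemes.

Every subject receives exactly one segment per scheme.  Cascade schemes
(Delaware, Lombardy, North-West London) evaluate config-defined entry
criteria in highest-to-lowest-need order and stop at the first match; the
Singapore Simple Segmentation Tool (SST) instead crosses a 6-level Global
Impression of medical need with a 3-level Risk-and-Actionability (RA)
summary of complicating factors, yielding a canonical 18-cell grid with
``segment_id = 3 * (GI - 1) + RA``.

The engine is exposed both as per-record functions and as the
:class:`SegmentAssigner` scikit-learn estimator operating on survey-layout
DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from .cohort import Cohort, SubjectRecord, _subject_from_row
from .conditions import ConditionMap, default_condition_map
from .exceptions import DomainError
from .exceptions import MappingError  # noqa: F401  (raised via ConditionMap.resolve)

SCHEMES = ("singapore", "delaware", "lombardy", "nwlondon")

GI_LABELS = {
    1: "Healthy",
    2: "Asymptomatic Chronic Condition",
    3: "Symptomatic Chronic Condition",
    4: "Long Course of Decline",
    5: "Limited Reserve with Serious Exacerbations",
    6: "End of Life",
}
RA_LABELS = {1: "Low RA", 2: "Moderate RA", 3: "High RA"}


@dataclass(frozen=True)
class SegmentAssignment:
    scheme: str
    subject_id: str
    segment_id: int
    segment_label: str
    components: Optional[tuple] = None  # (GI, RA) for the Singapore scheme
    note: str = ""


# ---------------------------------------------------------------------------
# feature derivation

def subject_features(subject: SubjectRecord, condition_map: ConditionMap) -> dict:
    """Resolve a record into the features scheme predicates consume.

    Condition-class flags are the union of the survey's direct flags and the
    classes of the reported condition codes, so either source can establish
    class membership.
    """
    classes = condition_map.classes_of(subject.chronic_conditions)
    mh_order = ("none", "mild", "severe")
    mental = max(subject.mental_health, classes["mental_health"], key=mh_order.index)
    return {
        "age": subject.age,
        "chronic_count": classes["chronic_count"],
        "mental_health": mental,
        "cancer": subject.cancer or classes["cancer"],
        "organ_failure": subject.organ_failure_condition or classes["organ_failure"],
        "progressive_decline": subject.progressive_decline_condition
        or classes["progressive_decline"],
        "early_stage": classes["early_stage"],
        "end_of_life": subject.end_of_life,
        "any_symptomatic_condition": subject.any_symptomatic_condition,
        "acute_event_recent": subject.acute_event_recent,
        "adl_deficit": subject.adl_deficit,
        "skilled_nursing_need": subject.skilled_nursing_need,
        "iadl_deficit": subject.iadl_deficit,
        "social_support_deficit": subject.social_support_deficit,
        "activation_deficit": subject.activation_deficit,
        "disruptive_behaviour": subject.disruptive_behaviour,
    }


# ---------------------------------------------------------------------------
# predicate mini-language

_MH_ORDER = {"none": 0, "mild": 1, "severe": 2}


def compile_predicate(node: Mapping) -> Callable[[dict], bool]:
    if len(node) != 1:
        raise DomainError(f"predicate must have exactly one key: {node!r}")
    (op, arg), = node.items()
    if op == "always":
        return lambda f: True
    if op == "age_ge":
        return lambda f, v=int(arg): f["age"] >= v
    if op == "age_lt":
        return lambda f, v=int(arg): f["age"] < v
    if op == "flag":
        if arg not in ("acute_event_recent", "adl_deficit", "skilled_nursing_need",
                       "iadl_deficit", "social_support_deficit", "activation_deficit",
                       "disruptive_behaviour", "end_of_life", "any_symptomatic_condition"):
            raise DomainError(f"unknown flag {arg!r} in scheme predicate")
        return lambda f, k=arg: bool(f[k])
    if op == "mental_health_is":
        return lambda f, v=arg: f["mental_health"] == v
    if op == "mental_health_ge":
        return lambda f, v=_MH_ORDER[arg]: _MH_ORDER[f["mental_health"]] >= v
    if op == "chronic_count_ge":
        return lambda f, v=int(arg): f["chronic_count"] >= v
    if op == "class_present":
        if arg not in ("cancer", "early_stage", "organ_failure", "progressive_decline"):
            raise DomainError(f"unknown condition class {arg!r}")
        return lambda f, k=arg: bool(f[k])
    if op == "all_of":
        parts = [compile_predicate(p) for p in arg]
        return lambda f: all(p(f) for p in parts)
    if op == "any_of":
        parts = [compile_predicate(p) for p in arg]
        return lambda f: any(p(f) for p in parts)
    if op == "negate":
        inner = compile_predicate(arg)
        return lambda f: not inner(f)
    raise DomainError(f"unknown predicate operator {op!r}")


@dataclass
class SchemeDefinition:
    """An ordered rule cascade (or the SST grid) for one scheme."""

    name: str
    kind: str  # "cascade" | "grid"
    segments: list = field(default_factory=list)  # (id, label, predicate) in need order
    placeholders: list = field(default_factory=list)
    gi_labels: Mapping[int, str] = field(default_factory=lambda: GI_LABELS)
    ra_labels: Mapping[int, str] = field(default_factory=lambda: RA_LABELS)
    not_evaluable: tuple = ()

    def assign(self, subject: SubjectRecord, features: dict) -> SegmentAssignment:
        if self.kind == "grid":
            return _assign_grid(self, subject, features)
        for seg_id, label, predicate in self.segments:
            if predicate(features):
                return SegmentAssignment(self.name, subject.subject_id, seg_id, label)
        raise DomainError(  # unreachable when the config ends in a catch-all
            f"scheme {self.name!r}: no entry criterion matched subject "
            f"{subject.subject_id!r}; the cascade lacks a catch-all"
        )


def load_scheme_definitions(path: str | Path | None = None) -> dict:
    """Load scheme configs; defaults to the packaged ``schemes.yaml``."""
    if path is None:
        ref = resources.files("popseg.data").joinpath("schemes.yaml")
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    else:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    defs = {}
    for name, cfg in raw["schemes"].items():
        kind = cfg.get("kind", "cascade")
        if kind == "grid":
            defs[name] = SchemeDefinition(
                name=name,
                kind="grid",
                gi_labels={int(k): v for k, v in cfg["gi_labels"].items()},
                ra_labels={int(k): v for k, v in cfg["ra_labels"].items()},
                not_evaluable=tuple(cfg.get("not_evaluable", ())),
            )
        else:
            segments = [
                (int(seg["id"]), seg["label"], compile_predicate(seg["when"]))
                for seg in cfg["segments"]
            ]
            last = cfg["segments"][-1]["when"]
            if "always" not in last:
                raise DomainError(f"scheme {name!r}: final criterion must be a catch-all")
            defs[name] = SchemeDefinition(
                name=name, kind="cascade", segments=segments,
                placeholders=list(cfg.get("placeholders", ())),
            )
    return defs


# ---------------------------------------------------------------------------
# SST components

def compute_ra_level(subject: SubjectRecord) -> int:
    """Risk-and-Actionability level from the complicating-factor flags.

    3 — any ADL deficit or skilled-nursing task need;
    2 — otherwise, any of IADL / social-support / activation deficit or
        disruptive behaviour;
    1 — all others.
    """
    if subject.adl_deficit or subject.skilled_nursing_need:
        return 3
    if (subject.iadl_deficit or subject.social_support_deficit
            or subject.activation_deficit or subject.disruptive_behaviour):
        return 2
    return 1


#: Global Impression cascade, highest to lowest need: (category, feature test)
_GI_CASCADE = (
    (6, lambda f: f["end_of_life"]),
    (5, lambda f: f["organ_failure"]),
    (4, lambda f: f["progressive_decline"]),
    (3, lambda f: f["any_symptomatic_condition"]),
    (2, lambda f: f["chronic_count"] >= 1),
    (1, lambda f: True),
)


def compute_global_impression(
    subject: SubjectRecord, condition_map: Optional[ConditionMap] = None
) -> int:
    """Six-level Global Impression of overall medical need (1=Healthy ... 6=End of Life).

    First match wins down the need cascade: End of Life, Limited Reserve
    (organ-failure class), Long Course of Decline (progressive-decline
    class), Symptomatic Chronic, Asymptomatic Chronic, Healthy.
    """
    features = subject_features(subject, condition_map or default_condition_map())
    for category, test in _GI_CASCADE:
        if test(features):
            return category
    raise AssertionError("unreachable: Healthy is a catch-all")


def _assign_grid(scheme: SchemeDefinition, subject: SubjectRecord,
                 features: dict) -> SegmentAssignment:
    gi = next(cat for cat, test in _GI_CASCADE if test(features))
    ra = compute_ra_level(subject)
    seg_id = 3 * (gi - 1) + ra
    label = f"{scheme.gi_labels[gi]}. {scheme.ra_labels[ra]}"
    note = "not evaluable from this instrument" if seg_id in scheme.not_evaluable else ""
    return SegmentAssignment(scheme.name, subject.subject_id, seg_id, label,
                             components=(gi, ra), note=note)


# ---------------------------------------------------------------------------
# public assignment API

def _assign_one(scheme: str, subject: SubjectRecord,
                condition_map: Optional[ConditionMap] = None,
                definitions: Optional[dict] = None) -> SegmentAssignment:
    cmap = condition_map or default_condition_map()
    defs = definitions or load_scheme_definitions()
    if scheme not in defs:
        raise DomainError(f"unknown scheme {scheme!r}; available: {sorted(defs)}")
    return defs[scheme].assign(subject, subject_features(subject, cmap))


def assign_singapore(subject, condition_map=None):
    return _assign_one("singapore", subject, condition_map)


def assign_delaware(subject, condition_map=None):
    return _assign_one("delaware", subject, condition_map)


def assign_lombardy(subject, condition_map=None):
    return _assign_one("lombardy", subject, condition_map)


def assign_nwlondon(subject, condition_map=None):
    return _assign_one("nwlondon", subject, condition_map)


def assign_all(
    cohort: Cohort,
    schemes: Sequence[str] = SCHEMES,
    condition_map: Optional[ConditionMap] = None,
) -> list:
    """Assign every subject under every requested scheme.

    Deterministic and independent of subject order; returns exactly
    ``len(subjects) * len(schemes)`` assignments.
    """
    cmap = condition_map or default_condition_map()
    defs = load_scheme_definitions()
    out = []
    for subject in cohort.subjects:
        features = subject_features(subject, cmap)
        for scheme in schemes:
            if scheme not in defs:
                raise DomainError(f"unknown scheme {scheme!r}; available: {sorted(defs)}")
            out.append(defs[scheme].assign(subject, features))
    return out


def present_only_numbering(assignments: Iterable[SegmentAssignment]) -> dict:
    """Renumber observed segments 1..k in canonical-id order (display aid).

    Published summary tables often number only segments with at least one
    subject; this maps canonical ids of one scheme's assignments onto that
    dense display numbering.
    """
    ids = sorted({a.segment_id for a in assignments})
    return {seg_id: rank for rank, seg_id in enumerate(ids, start=1)}


class SegmentAssigner(BaseEstimator):
    """Rule-cascade segment classifier in scikit-learn estimator form.

    Parameters
    ----------
    scheme : one of "singapore", "delaware", "lombardy", "nwlondon"
    condition_map : ConditionMap, optional — defaults to the packaged map
    scheme_config : path to a schemes YAML, optional — defaults to packaged

    The rules are fixed by configuration, so ``fit`` only compiles and
    validates them; ``predict`` maps a survey-layout DataFrame (or a list of
    :class:`SubjectRecord`) to canonical segment ids.
    """

    def __init__(self, scheme: str = "singapore", condition_map=None,
                 scheme_config=None):
        self.scheme = scheme
        self.condition_map = condition_map
        self.scheme_config = scheme_config

    def fit(self, X=None, y=None):
        defs = load_scheme_definitions(self.scheme_config)
        if self.scheme not in defs:
            raise DomainError(f"unknown scheme {self.scheme!r}; available: {sorted(defs)}")
        self.definition_ = defs[self.scheme]
        self.condition_map_ = self.condition_map or default_condition_map()
        return self

    def _records(self, X) -> list:
        if isinstance(X, pd.DataFrame):
            return [_subject_from_row(row, idx, strict=False) for idx, row in X.iterrows()]
        return list(X)

    def assign(self, X) -> list:
        if not hasattr(self, "definition_"):
            self.fit()
        return [
            self.definition_.assign(s, subject_features(s, self.condition_map_))
            for s in self._records(X)
        ]

    def predict(self, X) -> np.ndarray:
        return np.array([a.segment_id for a in self.assign(X)], dtype=int)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        out[f"segment_{self.scheme}"] = self.predict(X)
        return out
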
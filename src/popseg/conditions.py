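"""Condition vocabulary and code -> class mapping.

Segmentation rules never consume raw condition codes: each code from the
survey checklist is resolved through a :class:`ConditionMap` into the classes
the schemes reason about (chronic, organ-failure, progressive-decline,
cancer, mental-health severity, early-stage).  The default map ships as a
versioned YAML data file and can be replaced wholesale by the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .exceptions import MappingError

MENTAL_HEALTH_LEVELS = ("none", "mild", "severe")


@dataclass(frozen=True)
class ConditionClasses:
    """Classes a single condition code belongs to."""

    chronic: bool = False
    organ_failure: bool = False
    progressive_decline: bool = False
    cancer: bool = False
    mental_health: str = "none"
    early_stage: bool = False

    def __post_init__(self) -> None:
        if self.mental_health not in MENTAL_HEALTH_LEVELS:
            raise ValueError(f"mental_health must be one of {MENTAL_HEALTH_LEVELS}")


@dataclass
class ConditionMap:
    """Mapping from condition codes to :class:`ConditionClasses`."""

    conditions: Mapping[str, ConditionClasses] = field(default_factory=dict)
    version: int = 1

    def resolve(self, code: str) -> ConditionClasses:
        try:
            return self.conditions[code]
        except KeyError:
            raise MappingError(
                f"condition code {code!r} is not in the condition map"
            ) from None

    def classes_of(self, codes: Iterable[str]) -> dict:
        """Aggregate class membership over a subject's condition codes.

        Returns chronic_count, the boolean class flags, and the highest
        mental-health severity among the codes.
        """
        chronic = 0
        organ_failure = progressive_decline = cancer = early_stage = False
        mh = 0
        for code in codes:
            cls = self.resolve(code)
            chronic += int(cls.chronic)
            organ_failure |= cls.organ_failure
            progressive_decline |= cls.progressive_decline
            cancer |= cls.cancer
            early_stage |= cls.early_stage
            mh = max(mh, MENTAL_HEALTH_LEVELS.index(cls.mental_health))
        return {
            "chronic_count": chronic,
            "organ_failure": organ_failure,
            "progressive_decline": progressive_decline,
            "cancer": cancer,
            "early_stage": early_stage,
            "mental_health": MENTAL_HEALTH_LEVELS[mh],
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConditionMap":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls._from_dict(raw)

    @classmethod
    def _from_dict(cls, raw: Mapping) -> "ConditionMap":
        conditions = {
            code: ConditionClasses(**(attrs or {}))
            for code, attrs in raw.get("conditions", {}).items()
        }
        return cls(conditions=conditions, version=raw.get("version", 1))


def default_condition_map() -> ConditionMap:
    """The condition map shipped with the package."""
    ref = resources.files("popseg.data").joinpath("condition_map.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return ConditionMap._from_dict(raw)
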
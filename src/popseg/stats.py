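"""Predictive-validity statistics: segment-wise outcome summaries and
chi-squared tests of independence.

Each 180-day outcome carries its own standard-error family: binomial for
mortality (a probability), Poisson for hospital-admission and ED-visit
counts (rates per person), and normal (sample SD based) for specialist
outpatient clinic (SOC) visits.  Confidence intervals are Wald-type,
``mean ± z * se`` at a configurable level (default 95%).  Association
between segment membership and each dichotomized ("any") outcome is tested
with plain Pearson chi-squared (no continuity correction) at α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort, OutcomeRecord
from .eq5d import ValueSet, summarize_utility
from .exceptions import DegenerateTableError, DomainError

SE_METHODS = ("normal", "poisson", "binomial")

#: outcome name -> (se family, per-record value, "any" kind)
OUTCOME_SPECS = {
    "mortality": ("binomial", lambda o: int(o.died_180d), "any_mortality"),
    "admissions": ("poisson", lambda o: o.n_admissions_180d, "any_admission"),
    "ed": ("poisson", lambda o: o.n_ed_visits_180d, "any_ed"),
    "soc": ("normal", lambda o: o.n_soc_visits_180d, "any_soc"),
}


@dataclass(frozen=True)
class SummaryCI:
    mean: float
    se: float
    ci_low: float
    ci_high: float
    se_method: str
    n: int


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    stars: str
    scheme: str = ""
    outcome: str = ""
    n_low_expected: int = 0  # cells with expected count < 5 (flagged, not fixed)


def significance_stars(p_value: float) -> str:
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def mean_with_ci(values: Sequence[float], se_method: str, level: float = 0.95) -> SummaryCI:
    """Arithmetic mean with the outcome-family standard error and Wald CI.

    normal:   se = sample SD / sqrt(n)   (SD with ddof=1; 0 when n == 1)
    poisson:  se = sqrt(mean / n)        (counts assumed Poisson)
    binomial: se = sqrt(mean (1-mean) / n)  (values must be 0/1)
    """
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n == 0:
        raise DomainError("cannot summarize an empty outcome vector")
    if se_method not in SE_METHODS:
        raise DomainError(f"unknown se_method {se_method!r}; expected one of {SE_METHODS}")
    mean = float(arr.mean())
    if se_method == "binomial":
        if not np.all(np.isin(arr, (0.0, 1.0))):
            raise DomainError("binomial standard errors require 0/1 values")
        se = float(np.sqrt(mean * (1.0 - mean) / n))
    elif se_method == "poisson":
        if np.any(arr < 0) or np.any(arr != np.round(arr)):
            raise DomainError("Poisson standard errors require non-negative integer counts")
        se = float(np.sqrt(mean / n))
    else:
        se = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    return SummaryCI(mean, se, mean - z * se, mean + z * se, se_method, n)


def segment_share(segment_count: int, total: int, decimals: int = 1) -> float:
    """Percentage of the cohort in a segment, rounded half-up."""
    if total < 1:
        raise DomainError("total must be >= 1")
    if not 0 <= segment_count <= total:
        raise DomainError("segment_count must lie in [0, total]")
    quantum = Decimal(1).scaleb(-decimals)
    pct = (Decimal(100) * Decimal(segment_count) / Decimal(total)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(pct)


def binarize_any(outcome: OutcomeRecord, kind: str) -> int:
    """1 iff the relevant 180-day outcome occurred at least once."""
    if kind == "any_mortality":
        return int(outcome.died_180d)
    if kind == "any_admission":
        return int(outcome.n_admissions_180d > 0)
    if kind == "any_ed":
        return int(outcome.n_ed_visits_180d > 0)
    if kind == "any_soc":
        return int(outcome.n_soc_visits_180d > 0)
    raise DomainError(f"unknown outcome kind {kind!r}")


def chi_square_independence(
    segment_labels: Sequence, binary_outcome: Sequence[int],
    scheme: str = "", outcome: str = "",
) -> ChiSquareResult:
    """Pearson chi-squared test of segment x (any outcome) independence.

    The contingency table is segments x {0, 1} after dropping zero-subject
    segments; df = (#segments - 1).  Cells with expected count below 5 are
    counted and flagged in the result, not corrected.
    """
    labels = pd.Series(list(segment_labels))
    y = np.asarray(list(binary_outcome), dtype=int)
    if labels.size != y.size:
        raise DomainError("segment labels and outcomes differ in length")
    if not np.all(np.isin(y, (0, 1))):
        raise DomainError("outcome must be binary 0/1")
    table = pd.crosstab(labels, y)
    table = table.loc[table.sum(axis=1) > 0]
    if table.shape[0] < 2:
        raise DegenerateTableError("need at least two non-empty segments")
    if table.shape[1] < 2 or (table.sum(axis=0) == 0).any():
        raise DegenerateTableError(
            "outcome is constant across the cohort (zero expected counts)"
        )
    observed = table.to_numpy()
    res = sps.chi2_contingency(observed, correction=False)
    expected = res.expected_freq
    if np.any(expected == 0):
        raise DegenerateTableError("zero expected cell count")
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        stars=significance_stars(float(res.pvalue)),
        scheme=scheme,
        outcome=outcome,
        n_low_expected=int((expected < 5).sum()),
    )


# ---------------------------------------------------------------------------
# report assembly


def _segment_table(cohort: Cohort, assignments: Sequence, scheme: str,
                   outcome_name: str, level: float) -> pd.DataFrame:
    se_method, value_of, _ = OUTCOME_SPECS[outcome_name]
    outcomes = cohort.outcomes_by_id()
    groups: dict = {}
    labels: dict = {}
    for a in assignments:
        if a.scheme != scheme:
            continue
        groups.setdefault(a.segment_id, []).append(value_of(outcomes[a.subject_id]))
        labels[a.segment_id] = a.segment_label
    total = sum(len(v) for v in groups.values())
    rows = []
    for seg_id in sorted(groups):
        s = mean_with_ci(groups[seg_id], se_method, level)
        rows.append({
            "scheme": scheme, "segment_id": seg_id, "segment_label": labels[seg_id],
            "n": s.n, "share_pct": segment_share(s.n, total),
            "mean": s.mean, "se": s.se, "ci_low": s.ci_low, "ci_high": s.ci_high,
            "se_method": se_method,
        })
    overall = mean_with_ci(
        [value_of(outcomes[sid]) for sid in cohort.subject_ids()], se_method, level
    )
    rows.append({
        "scheme": scheme, "segment_id": pd.NA, "segment_label": "(all subjects)",
        "n": overall.n, "share_pct": 100.0,
        "mean": overall.mean, "se": overall.se,
        "ci_low": overall.ci_low, "ci_high": overall.ci_high, "se_method": se_method,
    })
    return pd.DataFrame(rows)


def build_validity_report(
    cohort: Cohort,
    assignments: Sequence,
    schemes: Optional[Sequence[str]] = None,
    value_set: Optional[ValueSet] = None,
    level: float = 0.95,
) -> dict:
    """The full validity battery for one segmented cohort.

    Returns a dict of DataFrames: ``eq5d`` (mean utility by segment),
    ``mortality`` / ``admissions`` / ``ed`` / ``soc`` (per-segment n, share,
    mean, SE, CI with the outcome's SE family, plus an all-subjects
    reference row per scheme), and ``chisq`` (the schemes x any-outcome
    Pearson battery; degenerate tables are reported as rows with NaN
    statistics rather than dropped silently).
    """
    if not cohort.outcomes or len(cohort.outcomes) != len(cohort.subjects):
        raise DomainError("validity report requires outcomes for every subject")
    if schemes is None:
        schemes = sorted({a.scheme for a in assignments})
    outcomes = cohort.outcomes_by_id()
    report: dict = {
        "eq5d": summarize_utility(cohort, [a for a in assignments if a.scheme in schemes],
                                  value_set),
    }
    for outcome_name in OUTCOME_SPECS:
        report[outcome_name] = pd.concat(
            [_segment_table(cohort, assignments, scheme, outcome_name, level)
             for scheme in schemes],
            ignore_index=True,
        )
    chisq_rows = []
    for scheme in schemes:
        per_subject = {a.subject_id: a.segment_id for a in assignments if a.scheme == scheme}
        ids = cohort.subject_ids()
        seg_labels = [per_subject[sid] for sid in ids]
        for outcome_name, (_, _, any_kind) in OUTCOME_SPECS.items():
            y = [binarize_any(outcomes[sid], any_kind) for sid in ids]
            try:
                res = chi_square_independence(seg_labels, y, scheme, any_kind)
                chisq_rows.append({
                    "scheme": scheme, "outcome": any_kind,
                    "statistic": res.statistic, "df": res.df, "p_value": res.p_value,
                    "stars": res.stars, "n_low_expected": res.n_low_expected,
                    "degenerate": False,
                })
            except DegenerateTableError as exc:
                chisq_rows.append({
                    "scheme": scheme, "outcome": any_kind,
                    "statistic": np.nan, "df": 0, "p_value": np.nan,
                    "stars": "", "n_low_expected": 0, "degenerate": True,
                    "note": str(exc),
                })
    report["chisq"] = pd.DataFrame(chisq_rows)
    return report
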
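"""Validity statistics: SE families, shares, chi-squared, report assembly."""

import numpy as np
import pandas as pd
import pytest

from popseg.cohort import Cohort, OutcomeRecord, SubjectRecord
from popseg.exceptions import DegenerateTableError, DomainError
from popseg.segmentation import assign_all
from popseg.stats import (
    binarize_any,
    build_validity_report,
    chi_square_independence,
    mean_with_ci,
    segment_share,
    significance_stars,
)
from popseg.synthetic import generate_cohort


# ---------------------------------------------------------------------------
# mean_with_ci


def test_binomial_mean_one_death_in_seven():
    s = mean_with_ci([0, 0, 0, 0, 0, 0, 1], "binomial")
    assert s.mean == pytest.approx(1 / 7)
    assert s.se == pytest.approx(np.sqrt((1 / 7) * (6 / 7) / 7))
    assert s.ci_low <= s.mean <= s.ci_high


def test_poisson_all_zero_counts_degenerate_to_point_interval():
    s = mean_with_ci([0, 0, 0], "poisson")
    assert (s.mean, s.se, s.ci_low, s.ci_high) == (0.0, 0.0, 0.0, 0.0)


def test_poisson_hand_example_counts_2011():
    # mean 1.0, se sqrt(1/4) = 0.5, 95% CI 1 +/- 1.96*0.5 = (0.02, 1.98)
    s = mean_with_ci([2, 0, 1, 1], "poisson")
    assert s.mean == 1.0 and s.se == 0.5
    assert s.ci_low == pytest.approx(0.02, abs=5e-5)
    assert s.ci_high == pytest.approx(1.98, abs=5e-5)


def test_normal_se_is_sample_sd_over_sqrt_n():
    values = [1, 2, 3, 4]
    s = mean_with_ci(values, "normal")
    assert s.se == pytest.approx(np.std(values, ddof=1) / 2)


def test_mean_with_ci_domain_errors():
    with pytest.raises(DomainError):
        mean_with_ci([], "normal")
    with pytest.raises(DomainError):
        mean_with_ci([0, 2], "binomial")
    with pytest.raises(DomainError):
        mean_with_ci([-1, 2], "poisson")


@pytest.mark.parametrize("level", [0.90, 0.95, 0.99])
def test_ci_level_is_configurable(level):
    s = mean_with_ci([0, 1, 0, 1, 1, 0, 1, 0], "binomial", level=level)
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    assert s.ci_high - s.mean == pytest.approx(z * s.se)


# ---------------------------------------------------------------------------
# segment_share


@pytest.mark.parametrize(
    "count,total,decimals,expected",
    [
        (230, 928, 1, 24.8),
        (0, 928, 1, 0.0),
        (24, 48, 1, 50.0),
        (5, 18, 1, 27.8),
        (1, 16, 2, 6.25),
        (1, 800, 1, 0.1),  # 0.125 rounds half-up at 1 decimal
    ],
)
def test_segment_share_half_up_rounding(count, total, decimals, expected):
    assert segment_share(count, total, decimals) == expected


def test_segment_share_zero_total_is_domain_error():
    with pytest.raises(DomainError):
        segment_share(0, 0)


# ---------------------------------------------------------------------------
# binarize_any


def test_binarize_any_rules():
    o = OutcomeRecord("A", died_180d=True, n_admissions_180d=0,
                      n_ed_visits_180d=3, n_soc_visits_180d=0)
    assert binarize_any(o, "any_mortality") == 1
    assert binarize_any(o, "any_admission") == 0
    assert binarize_any(o, "any_ed") == 1
    assert binarize_any(o, "any_soc") == 0


# ---------------------------------------------------------------------------
# chi-squared


def _labels_outcomes(cells):
    """cells: {segment: (n_with_outcome, n_without)} -> per-subject vectors."""
    labels, outcome = [], []
    for seg, (ones, zeros) in cells.items():
        labels += [seg] * (ones + zeros)
        outcome += [1] * ones + [0] * zeros
    return labels, outcome


def test_chi_square_hand_computed_two_segment_table():
    labels, outcome = _labels_outcomes({"a": (20, 30), "b": (40, 10)})
    res = chi_square_independence(labels, outcome)
    assert res.statistic == pytest.approx(16.667, abs=5e-4)
    assert res.df == 1
    assert res.stars == "***"


def test_chi_square_identical_proportions_gives_zero_statistic():
    labels, outcome = _labels_outcomes({"a": (10, 30), "b": (5, 15), "c": (20, 60)})
    res = chi_square_independence(labels, outcome)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    assert res.stars == ""


def test_chi_square_invariant_under_relabeling():
    labels, outcome = _labels_outcomes({"a": (3, 9), "b": (7, 2), "c": (5, 5)})
    renamed = [{"a": "z", "b": "y", "c": "x"}[v] for v in labels]
    assert (chi_square_independence(labels, outcome).statistic
            == pytest.approx(chi_square_independence(renamed, outcome).statistic))


def test_chi_square_degenerate_tables():
    with pytest.raises(DegenerateTableError):
        chi_square_independence(["a"] * 10, [0, 1] * 5)  # single segment
    labels, outcome = _labels_outcomes({"a": (0, 10), "b": (0, 5)})
    with pytest.raises(DegenerateTableError):
        chi_square_independence(labels, outcome)  # outcome constant -> zero expected


def test_chi_square_flags_low_expected_cells():
    labels, outcome = _labels_outcomes({"a": (1, 3), "b": (2, 4)})
    assert chi_square_independence(labels, outcome).n_low_expected > 0


def test_significance_star_thresholds():
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
    assert significance_stars(0.05) == ""


# ---------------------------------------------------------------------------
# report assembly


@pytest.fixture(scope="module")
def report(default_params):
    cohort = generate_cohort(default_params, seed=11)
    return cohort, build_validity_report(cohort, assign_all(cohort))


def test_report_has_all_tables_and_shapes(report):
    _, tables = report
    assert set(tables) == {"eq5d", "mortality", "admissions", "ed", "soc", "chisq"}
    assert len(tables["chisq"]) == 4 * 4  # schemes x any-outcomes battery
    assert set(tables["mortality"]["se_method"]) == {"binomial"}
    assert set(tables["admissions"]["se_method"]) == {"poisson"}
    assert set(tables["ed"]["se_method"]) == {"poisson"}
    assert set(tables["soc"]["se_method"]) == {"normal"}


def test_report_ci_brackets_mean(report):
    _, tables = report
    for name in ("mortality", "admissions", "ed", "soc"):
        t = tables[name]
        assert (t["ci_low"] <= t["mean"]).all() and (t["mean"] <= t["ci_high"]).all()
        assert (t["se"] >= 0).all()


def test_segment_means_weighted_by_n_reproduce_overall_mean(report):
    """Within each scheme, n-weighted segment means equal the all-subjects mean."""
    _, tables = report
    for name in ("mortality", "admissions", "ed", "soc"):
        for scheme, group in tables[name].groupby("scheme"):
            segments = group[group["segment_label"] != "(all subjects)"]
            overall = group[group["segment_label"] == "(all subjects)"]["mean"].iloc[0]
            weighted = np.average(segments["mean"], weights=segments["n"])
            assert weighted == pytest.approx(overall, rel=1e-12)


def test_report_no_deaths_marks_mortality_chisq_degenerate(default_params):
    cohort = generate_cohort(default_params, seed=12, n=60)
    for o in cohort.outcomes:
        o.died_180d = False
    tables = build_validity_report(cohort, assign_all(cohort))
    mort = tables["chisq"].query("outcome == 'any_mortality'")
    assert mort["degenerate"].all()
    assert (tables["mortality"].query("segment_label != '(all subjects)'")["mean"] == 0).all()


def test_report_requires_total_outcome_join():
    cohort = Cohort(subjects=[SubjectRecord("A", 70, "male")])
    with pytest.raises(DomainError):
        build_validity_report(cohort, assign_all(cohort))
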
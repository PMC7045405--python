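"""Segment assignment: component rules, cascade order, totality, estimator API."""

import itertools

import numpy as np
import pytest
from sklearn.base import clone

from popseg.cohort import Cohort, SubjectRecord, survey_frame
from popseg.conditions import default_condition_map
from popseg.exceptions import MappingError
from popseg.segmentation import (
    SCHEMES,
    SchemeDefinition,
    SegmentAssigner,
    assign_all,
    assign_delaware,
    assign_lombardy,
    assign_nwlondon,
    assign_singapore,
    compute_global_impression,
    compute_ra_level,
    load_scheme_definitions,
    present_only_numbering,
    subject_features,
)

from conftest import random_subject

CMAP = default_condition_map()


def make_subject(**kwargs) -> SubjectRecord:
    base = dict(subject_id="X", age=65, sex="female")
    base.update(kwargs)
    return SubjectRecord(**base)


# ---------------------------------------------------------------------------
# Risk and Actionability


@pytest.mark.parametrize(
    "flags,expected",
    [
        ({"adl_deficit": True}, 3),
        ({"skilled_nursing_need": True}, 3),
        ({"adl_deficit": True, "iadl_deficit": True}, 3),
        ({"iadl_deficit": True}, 2),
        ({"social_support_deficit": True}, 2),
        ({"activation_deficit": True}, 2),
        ({"disruptive_behaviour": True}, 2),
        ({}, 1),
    ],
)
def test_ra_level_rules(flags, expected):
    assert compute_ra_level(make_subject(**flags)) == expected


# ---------------------------------------------------------------------------
# Global Impression


def _reference_gi(end_of_life, organ_failure, decline, symptomatic, chronic):
    """Independent first-match reference over the need ordering."""
    if end_of_life:
        return 6
    if organ_failure:
        return 5
    if decline:
        return 4
    if symptomatic:
        return 3
    if chronic:
        return 2
    return 1


def test_global_impression_first_match_over_all_flag_combinations():
    for eol, of, pd_, sym in itertools.product([False, True], repeat=4):
        # a symptomatic subject must hold >= 1 chronic condition
        for codes in (frozenset(), frozenset({"hypertension"})):
            if sym and not codes:
                continue
            subject = make_subject(
                end_of_life=eol, organ_failure_condition=of,
                progressive_decline_condition=pd_, any_symptomatic_condition=sym,
                chronic_conditions=codes,
            )
            expected = _reference_gi(eol, of, pd_, sym, bool(codes))
            assert compute_global_impression(subject, CMAP) == expected


def test_global_impression_from_condition_codes_alone():
    # class membership can come from the code vocabulary, not only direct flags
    assert compute_global_impression(make_subject(chronic_conditions=frozenset({"chf"})), CMAP) == 5
    assert compute_global_impression(make_subject(chronic_conditions=frozenset({"dementia"})), CMAP) == 4
    assert compute_global_impression(make_subject(chronic_conditions=frozenset({"diabetes"})), CMAP) == 2
    assert compute_global_impression(make_subject(), CMAP) == 1


def test_unmapped_condition_code_raises_naming_the_code():
    with pytest.raises(MappingError, match="gout"):
        assign_singapore(make_subject(chronic_conditions=frozenset({"gout"})), CMAP)


# ---------------------------------------------------------------------------
# Singapore grid


def test_singapore_grid_examples():
    healthy_moderate = assign_singapore(make_subject(iadl_deficit=True), CMAP)
    assert healthy_moderate.segment_id == 2
    assert healthy_moderate.segment_label == "Healthy. Moderate RA"
    assert healthy_moderate.components == (1, 2)

    limited_high = assign_singapore(
        make_subject(organ_failure_condition=True, adl_deficit=True), CMAP
    )
    assert limited_high.segment_id == 15
    assert limited_high.segment_label == "Limited Reserve with Serious Exacerbations. High RA"

    eol = assign_singapore(make_subject(end_of_life=True), CMAP)
    assert eol.segment_id == 16 and eol.note == "not evaluable from this instrument"


def test_singapore_id_gi_ra_bijection_over_all_18_cells():
    gi_setters = {
        1: {},
        2: {"chronic_conditions": frozenset({"diabetes"})},
        3: {"chronic_conditions": frozenset({"diabetes"}), "any_symptomatic_condition": True},
        4: {"progressive_decline_condition": True},
        5: {"organ_failure_condition": True},
        6: {"end_of_life": True},
    }
    ra_setters = {1: {}, 2: {"iadl_deficit": True}, 3: {"adl_deficit": True}}
    seen = {}
    for gi, ra in itertools.product(range(1, 7), range(1, 4)):
        a = assign_singapore(make_subject(**gi_setters[gi], **ra_setters[ra]), CMAP)
        assert a.components == (gi, ra)
        assert a.segment_id == 3 * (gi - 1) + ra
        seen[a.segment_id] = (gi, ra)
    assert sorted(seen) == list(range(1, 19))  # bijection covers the full grid


# ---------------------------------------------------------------------------
# Delaware


@pytest.mark.parametrize(
    "kwargs,expected_id,expected_label",
    [
        (dict(age=80), 6, "Elderly & no chronic conditions"),
        (dict(age=65, chronic_conditions=frozenset({"diabetes", "copd"}),
              mental_health="mild"), 4,
         "Adult & have mild mental health conditions (includes those with chronic illness)"),
        (dict(age=75, chronic_conditions=frozenset({"diabetes"})), 7,
         "Elderly & 1 chronic condition"),  # >= 75 boundary is elderly
        (dict(age=74, chronic_conditions=frozenset({"diabetes"})), 2,
         "Adult & 1 chronic condition"),
        (dict(age=90, mental_health="severe"), 10,
         "Elderly & have severe mental health conditions (includes those with chronic illness)"),
        (dict(age=61), 1, "Adult & no chronic conditions"),
    ],
)
def test_delaware_cascade(kwargs, expected_id, expected_label):
    a = assign_delaware(make_subject(**kwargs), CMAP)
    assert (a.segment_id, a.segment_label) == (expected_id, expected_label)


def test_delaware_mental_health_absorbs_regardless_of_chronic_count():
    many_chronic = frozenset({"diabetes", "hypertension", "copd", "stroke"})
    a = assign_delaware(make_subject(age=65, chronic_conditions=many_chronic,
                                     mental_health="severe"), CMAP)
    assert a.segment_id == 5


# ---------------------------------------------------------------------------
# Lombardy


@pytest.mark.parametrize(
    "kwargs,expected_id",
    [
        (dict(age=89, chronic_conditions=frozenset({"diabetes", "chf", "stroke"})), 6),
        (dict(age=70, chronic_conditions=frozenset({"diabetes", "hypertension"})), 5),
        (dict(age=70, chronic_conditions=frozenset({"diabetes"})), 4),
        (dict(age=60, acute_event_recent=True), 2),
        (dict(age=60), 1),
    ],
)
def test_lombardy_cascade(kwargs, expected_id):
    assert assign_lombardy(make_subject(**kwargs), CMAP).segment_id == expected_id


def test_lombardy_early_stage_reachable_only_with_populated_class():
    # default vocabulary has no early-stage codes, so segment 3 is inert
    import popseg.conditions as conditions

    assert not any(c.early_stage for c in CMAP.conditions.values())
    extended = conditions.ConditionMap(
        conditions={**CMAP.conditions,
                    "prediabetes": conditions.ConditionClasses(early_stage=True)}
    )
    subject = make_subject(chronic_conditions=frozenset({"prediabetes"}))
    assert assign_lombardy(subject, extended).segment_id == 3


# ---------------------------------------------------------------------------
# North-West London


@pytest.mark.parametrize(
    "kwargs,expected_id,label_fragment",
    [
        (dict(age=68, chronic_conditions=frozenset({"diabetes"})), 4, "Adults < 75 with 1 or more LTCs"),
        (dict(age=80), 2, "Mostly health adults > 74"),
        (dict(age=62), 1, "Mostly healthy adults < 75"),
        (dict(cancer=True, adl_deficit=True), 8, "severe physical disabilities"),
        (dict(cancer=True), 7, "cancer"),
        (dict(mental_health="severe"), 6, "SEMI"),
        (dict(age=80, chronic_conditions=frozenset({"diabetes"})), 5, "Elderly > 74"),
    ],
)
def test_nwlondon_cascade(kwargs, expected_id, label_fragment):
    a = assign_nwlondon(make_subject(**kwargs), CMAP)
    assert a.segment_id == expected_id
    assert label_fragment in a.segment_label


# ---------------------------------------------------------------------------
# cascade properties


def _random_subjects(n, seed=0):
    rng = np.random.default_rng(seed)
    return [random_subject(rng, i) for i in range(n)]


def test_totality_and_exclusivity_over_randomized_subjects():
    subjects = _random_subjects(800, seed=3)
    cohort = Cohort(subjects=subjects)
    assignments = assign_all(cohort)
    assert len(assignments) == len(subjects) * len(SCHEMES)
    per_subject = {}
    for a in assignments:
        key = (a.subject_id, a.scheme)
        assert key not in per_subject  # exactly one segment per subject per scheme
        per_subject[key] = a.segment_id


def test_assignment_is_order_invariant_and_deterministic():
    subjects = _random_subjects(200, seed=4)
    rng = np.random.default_rng(5)
    shuffled = list(subjects)
    rng.shuffle(shuffled)
    forward = {(a.subject_id, a.scheme): a for a in assign_all(Cohort(subjects=subjects))}
    backward = {(a.subject_id, a.scheme): a for a in assign_all(Cohort(subjects=shuffled))}
    assert forward == backward


def test_removing_satisfied_criterion_moves_down_the_cascade():
    """Dropping the matched rule reassigns to the next satisfied rule, never upward."""
    definitions = load_scheme_definitions()
    for subject in _random_subjects(150, seed=6):
        features = subject_features(subject, CMAP)
        for name, definition in definitions.items():
            if definition.kind != "cascade":
                continue
            matched = [i for i, (_, _, pred) in enumerate(definition.segments)
                       if pred(features)]
            assigned = definition.assign(subject, features)
            assert assigned.segment_id == definition.segments[matched[0]][0]
            if len(matched) > 1:
                trimmed = SchemeDefinition(
                    name=name, kind="cascade",
                    segments=[seg for i, seg in enumerate(definition.segments)
                              if i != matched[0]],
                )
                reassigned = trimmed.assign(subject, features)
                assert reassigned.segment_id == definition.segments[matched[1]][0]


def test_present_only_numbering_is_dense_and_order_preserving():
    cohort = Cohort(subjects=_random_subjects(300, seed=8))
    assignments = [a for a in assign_all(cohort, schemes=("singapore",))]
    renumber = present_only_numbering(assignments)
    ids = sorted(renumber)
    assert list(renumber[i] for i in ids) == list(range(1, len(ids) + 1))


# ---------------------------------------------------------------------------
# estimator surface


def test_segment_assigner_estimator_matches_function_path(demo_cohort):
    frame = survey_frame(demo_cohort.subjects)
    for scheme in SCHEMES:
        est = clone(SegmentAssigner(scheme=scheme)).fit()
        predicted = est.predict(frame)
        expected = [a.segment_id for a in assign_all(demo_cohort, schemes=(scheme,))]
        assert predicted.tolist() == expected


def test_segment_assigner_transform_appends_column(demo_cohort):
    frame = survey_frame(demo_cohort.subjects[:10])
    out = SegmentAssigner(scheme="lombardy").fit().transform(frame)
    assert "segment_lombardy" in out.columns
    assert SegmentAssigner().get_params()["scheme"] == "singapore"
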
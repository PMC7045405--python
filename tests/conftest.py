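import numpy as np
import pytest

from popseg.cohort import SubjectRecord
from popseg.conditions import default_condition_map
from popseg.synthetic import default_generator_params, generate_cohort

CONDITION_CODES = sorted(default_condition_map().conditions)


@pytest.fixture(scope="session")
def default_params():
    return default_generator_params()


@pytest.fixture(scope="session")
def demo_cohort(default_params):
    """One default synthetic cohort (n=928) shared across read-only tests."""
    return generate_cohort(default_params, seed=42)


@pytest.fixture(scope="session")
def big_cohort(default_params):
    """A large cohort for gradient/monotonicity checks."""
    return generate_cohort(default_params, seed=7, n=120_000)


def random_subject(rng: np.random.Generator, i: int = 0) -> SubjectRecord:
    """A random but schema-valid record exercising every cascade branch."""
    codes = frozenset(
        rng.choice(CONDITION_CODES, size=rng.integers(0, 5), replace=False).tolist()
    )
    levels = tuple(int(v) for v in rng.integers(1, 4, size=5))
    return SubjectRecord(
        subject_id=f"R{i:06d}",
        age=int(rng.integers(60, 101)),
        sex=str(rng.choice(["male", "female"])),
        proxy_respondent=bool(rng.random() < 0.05),
        chronic_conditions=codes,
        any_symptomatic_condition=bool(codes) and bool(rng.random() < 0.4),
        mental_health=str(rng.choice(["none", "mild", "severe"])),
        cancer=bool(rng.random() < 0.1),
        acute_event_recent=bool(rng.random() < 0.1),
        organ_failure_condition=bool(rng.random() < 0.1),
        progressive_decline_condition=bool(rng.random() < 0.1),
        end_of_life=bool(rng.random() < 0.05),
        adl_deficit=bool(rng.random() < 0.2),
        skilled_nursing_need=bool(rng.random() < 0.1),
        iadl_deficit=bool(rng.random() < 0.3),
        social_support_deficit=bool(rng.random() < 0.3),
        activation_deficit=bool(rng.random() < 0.3),
        disruptive_behaviour=bool(rng.random() < 0.1),
        eq5d_responses=levels if rng.random() > 0.1 else None,
        difficulty_meeting_expenses=bool(rng.random() < 0.3) if rng.random() > 0.1 else None,
    )
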
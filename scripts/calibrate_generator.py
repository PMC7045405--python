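"""Calibrate the synthetic-cohort generator's default parameters.

The structural choices (which features exist, their baseline prevalences and
severity slopes) are fixed here; this script solves only the link
coefficients that are pinned to the study population's printed marginals,
then freezes the whole parameter set into
``src/popseg/data/generator_defaults.yaml``:

* death:       logistic intercept at fixed slope, so overall 180-day
               mortality is 2%;
* admissions / ED / SOC counts: Poisson rates log-linear in severity; the
  (intercept, slope) pair is solved jointly so the mean count per person and
  the any-visit proportion both match (0.189, 12.5%), (0.252, 17.9%),
  (0.945, 30.9%);
* EQ-5D cutpoints: a single logit shift applied to every dimension cutpoint
  so the mean index under the shipped UK TTO tariff is 0.83.

All expectations are computed by Gauss-Hermite quadrature over the latent
severity, so the calibration is deterministic.

Run from the repository root:  python scripts/calibrate_generator.py
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

OUT = Path(__file__).resolve().parents[1] / "src" / "popseg" / "data" / "generator_defaults.yaml"

# ---- study-condition targets (overall marginals) --------------------------
MORTALITY = 0.02
COUNT_TARGETS = {  # outcome -> (mean count per person, any-visit proportion)
    "admissions": (0.189, 0.125),
    "ed": (0.252, 0.179),
    "soc": (0.945, 0.309),
}
MEAN_EQ5D = 0.83
DEATH_SLOPE = 1.2  # fixed: yields ~1-in-7 mortality in the most severe segments

# ---- structural parameters (not solved here) ------------------------------
STRUCTURE = {
    "version": 1,
    "n": 928,
    "age": {"offset": 60, "gamma_shape": 2.0, "gamma_scale": 6.0,
            "severity_coef": 2.0, "max_age": 100},
    "sex_male_p": 0.55,
    "proxy_p": 0.051,
    "conditions": {
        "hypertension": {"p0": 0.50, "slope": 0.3},
        "hyperlipidemia": {"p0": 0.40, "slope": 0.2},
        "diabetes": {"p0": 0.30, "slope": 0.4},
        "osteoarthritis": {"p0": 0.22, "slope": 0.4},
        "gastritis": {"p0": 0.10, "slope": 0.2},
        "chf": {"p0": 0.006, "slope": 0.8},
        "copd": {"p0": 0.007, "slope": 0.8},
        "esrd": {"p0": 0.003, "slope": 0.8},
        "stroke": {"p0": 0.08, "slope": 0.7},
        "dementia": {"p0": 0.08, "slope": 0.9},
        "parkinsons": {"p0": 0.01, "slope": 0.6},
        "cancer": {"p0": 0.045, "slope": 0.5},
        "depression": {"p0": 0.16, "slope": 0.7},
        "schizophrenia": {"p0": 0.05, "slope": 0.6},
    },
    "symptomatic_given_chronic": {"p0": 0.25, "slope": 0.8},
    "factors": {
        "adl_deficit": {"p0": 0.055, "slope": 1.0},
        "skilled_nursing_need": {"p0": 0.02, "slope": 1.0},
        "iadl_deficit": {"p0": 0.30, "slope": 0.8},
        "social_support_deficit": {"p0": 0.35, "slope": 0.3},
        "activation_deficit": {"p0": 0.30, "slope": 0.5},
        "disruptive_behaviour": {"p0": 0.02, "slope": 0.5},
        "acute_event_recent": {"p0": 0.02, "slope": 0.3},
    },
    "difficulty_meeting_expenses": {"p0": 0.33, "slope": 0.3},
}

# baseline EQ-5D dimension prevalences at severity 0 before the global shift:
# P(level >= 2) and P(level = 3)
EQ5D_BASE = {
    "mobility": (0.30, 0.020),
    "self_care": (0.10, 0.010),
    "usual_activities": (0.18, 0.015),
    "pain_discomfort": (0.40, 0.030),
    "anxiety_depression": (0.22, 0.020),
}
EQ5D_SLOPE = 0.9
EQ5D_MISSING_P = 0.05

# UK TTO 3L tariff terms (must match src/popseg/data/uk_tto_3l.yaml)
CONSTANT = 0.081
N3_TERM = 0.269
DEC2 = {"mobility": 0.069, "self_care": 0.104, "usual_activities": 0.036,
        "pain_discomfort": 0.123, "anxiety_depression": 0.071}
DEC3 = {"mobility": 0.314, "self_care": 0.214, "usual_activities": 0.094,
        "pain_discomfort": 0.386, "anxiety_depression": 0.236}


def _gauss_hermite(n_nodes: int = 120):
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    return nodes * np.sqrt(2.0), weights / np.sqrt(np.pi)


S, W = _gauss_hermite()


def solve_death_intercept() -> float:
    return brentq(lambda a: np.sum(W * expit(a + DEATH_SLOPE * S)) - MORTALITY, -20.0, 5.0)


def solve_count_link(mean_count: float, any_prop: float) -> tuple:
    """(intercept, slope) of a Poisson-lognormal rate matching both targets."""

    def any_given_slope(b: float) -> float:
        a = np.log(mean_count) - b * b / 2.0
        return 1.0 - np.sum(W * np.exp(-np.exp(a + b * S)))

    # P(any) decreases in the slope at fixed mean; slope 0 gives 1 - exp(-mean)
    b = brentq(lambda b: any_given_slope(b) - any_prop, 1e-9, 6.0)
    return float(np.log(mean_count) - b * b / 2.0), float(b)


def eq5d_mean_index(shift: float) -> float:
    deficit = np.zeros_like(S)
    none_ge2 = np.ones_like(S)
    none_eq3 = np.ones_like(S)
    for dim, (p2_0, p3_0) in EQ5D_BASE.items():
        p2 = expit(logit(p2_0) + shift + EQ5D_SLOPE * S)
        p3 = expit(logit(p3_0) + shift + EQ5D_SLOPE * S)
        deficit += DEC2[dim] * (p2 - p3) + DEC3[dim] * p3
        none_ge2 *= 1.0 - p2
        none_eq3 *= 1.0 - p3
    deficit += CONSTANT * (1.0 - none_ge2) + N3_TERM * (1.0 - none_eq3)
    return 1.0 - float(np.sum(W * deficit))


def main() -> None:
    params = dict(STRUCTURE)

    shift = brentq(lambda d: eq5d_mean_index(d) - MEAN_EQ5D, -5.0, 5.0)
    params["eq5d"] = {
        "missing_p": EQ5D_MISSING_P,
        "slope": EQ5D_SLOPE,
        "dimensions": {
            dim: {
                "alpha1": round(float(logit(p2_0) + shift), 6),
                "alpha2": round(float(logit(p3_0) + shift), 6),
            }
            for dim, (p2_0, p3_0) in EQ5D_BASE.items()
        },
    }

    outcomes = {"death": {"intercept": round(solve_death_intercept(), 6),
                          "slope": DEATH_SLOPE}}
    for name, (mean_count, any_prop) in COUNT_TARGETS.items():
        intercept, slope = solve_count_link(mean_count, any_prop)
        outcomes[name] = {"intercept": round(intercept, 6), "slope": round(slope, 6)}
    params["outcomes"] = outcomes

    header = (
        "# Calibrated default generator parameters — produced by\n"
        "# scripts/calibrate_generator.py; edit the structure there, not here.\n"
    )
    OUT.write_text(header + yaml.safe_dump(params, sort_keys=True), encoding="utf-8")
    print(f"wrote {OUT}")
    print(f"  eq5d shift = {shift:+.4f}  -> mean index {eq5d_mean_index(shift):.4f}")
    for name, link in outcomes.items():
        print(f"  {name}: {link}")


if __name__ == "__main__":
    main()
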
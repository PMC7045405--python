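# Methods

## Segment assignment

Each scheme is an ordered list of entry criteria over survey-derived
features, evaluated highest-to-lowest healthcare need; a subject enters the
first segment whose criterion it satisfies and each cascade ends in a
catch-all, so assignment is total, exclusive and deterministic. Criteria
never read raw condition codes: the checklist vocabulary is resolved
through a condition map (`data/condition_map.yaml`) into classes — chronic,
organ-failure (limited-reserve conditions such as CHF/COPD), progressive
decline (dementia/stroke-type), cancer, mental-health severity, and an
early-stage class used by the Lombardy "possibly affected" segment.
Class membership is the union of the survey's direct flags and the classes
of reported codes, so either source suffices.

The Singapore SST is not a flat cascade but a grid: a 6-level Global
Impression (itself a small cascade — end of life, organ failure,
progressive decline, symptomatic chronic, any chronic, healthy) crossed
with the 3-level RA summary of complicating factors. Internally the
package always uses the canonical 18-cell numbering
`segment_id = 3·(GI − 1) + RA`; `present_only_numbering` provides the
dense display renumbering used by publications that list only non-empty
segments. This avoids identifiers that depend on which segments happen to
be populated in a given cohort.

Design choices where the source schemes are under-determined by a
survey instrument:

- **Delaware elderly cutoff** is age ≥ 75; the mental-health segments
  absorb subjects regardless of chronic-condition count.
- **North-West London "severe physical disability"** is operationalized as
  any ADL deficit; the criterion is plain config and can be re-pointed at
  another flag or combined criteria without code changes.
- **Lombardy "possibly affected / early stage"** is reachable only when the
  condition map's early-stage class is populated; the default vocabulary
  leaves it empty, mirroring how rarely a one-off survey can establish it.
- Segments the instrument cannot establish at all (pediatric/maternity,
  drug dependency, learning difficulties, 3-year-utilization variants, SST
  end-of-life cells) are inert placeholders in the config with a stated
  reason; no survey-derived record can enter them, but end-of-life
  assignments are still produced (with a note) if a caller sets the flag.
- Two of the SST's eight complicating factors are not separately encoded by
  the survey summary this package models; the RA rules use the six flags
  the instrument carries (ADL, skilled nursing, IADL, social support,
  activation, disruptive behaviour).
- **Missing data**: missing segmentation flags are "deficit absent" with a
  logged warning in non-strict mode and fatal in strict mode; missing
  EQ-5D responses exclude a subject from utility summaries only. This
  matches an instrument where everyone can be segmented but not everyone
  can be scored.

## EQ-5D scoring

The index is a table-driven additive tariff: 1.0 minus a constant if any
dimension is above level 1, minus per-dimension level decrements, minus an
extra term if any dimension is at the worst level. The shipped default is
the published UK time-trade-off valuation of the 3-level instrument (floor
−0.594); any tariff file with the same structure can be substituted, and
the scorer validates levels against the tariff's declared range. Under the
default tariff, worsening any single dimension never increases the index
(verified exhaustively over all 243 three-level profiles).

## Validity statistics

Per segment and outcome: arithmetic mean, standard error by outcome family
— binomial `√(p(1−p)/n)` for 180-day mortality, Poisson `√(x̄/n)` for
admission and ED counts, normal `SD/√n` (SD with ddof = 1; 0 when n = 1)
for SOC counts — and Wald intervals `mean ± z·se` with z from the normal
quantile at a configurable level (default 95%, z ≈ 1.96). The Poisson
family uses the mean-based `√(x̄/n)` form; it is isolated behind
`se_method` so a model-based variant can be swapped in. Segment shares are
percentages rounded half-up to one decimal.

Association tests are plain Pearson chi-squared (no continuity correction)
on the segments × {0,1} table of each dichotomized outcome, with
zero-subject segments dropped and df = (#non-empty segments − 1).
Tables where the outcome never (or always) occurs, or with fewer than two
non-empty segments, are reported as degenerate rather than tested; cells
with expected count < 5 are counted and flagged, not corrected, because
small segments are an expected feature of needs-based schemes applied to
moderate cohorts. Significance is starred at 0.05/0.01/0.001. The
statistic itself is computed by `scipy.stats.chi2_contingency`; the test
suite checks it against an independent brute-force Σ(O−E)²/E.

## Synthetic cohort model

One latent severity factor `s ~ N(0,1)` per subject; all features are
conditionally independent given `s`:

- binary features (conditions, deficits, financial strain):
  `P = expit(logit(p0) + slope·s)` with per-feature baseline prevalence
  `p0` and slope ≥ 0;
- age: 60 + Gamma(2, 6) + 2·s years, clipped to [60, 100]
  (median ≈ 70, ≈ 29% aged 75+);
- EQ-5D dimensions: cumulative-logit cutpoints sharing slope 0.9, 5% of
  subjects missing all five responses;
- outcomes: death is logistic in `s` (slope fixed at 1.2, which puts the
  most severe segments near 1-in-7 mortality); each count outcome is
  Poisson with a log-linear rate in `s`, i.e. marginally
  Poisson-lognormal and therefore overdispersed.

The calibration (`scripts/calibrate_generator.py`) is deterministic: the
death intercept solves the 2% overall mortality by Gauss–Hermite
quadrature; each count link's (intercept, slope) pair is solved jointly so
the mean count per person and the any-visit proportion both match their
targets (0.189 & 12.5%, 0.252 & 17.9%, 0.945 & 30.9%) — the slope is
identified because, at a fixed marginal mean, raising the severity slope
concentrates events in fewer people and lowers the any-visit proportion;
EQ-5D cutpoints get a single global logit shift so the mean index under
the UK tariff is 0.83. Baseline prevalences for conditions and deficits
were set once to values plausible for a low-income urban cohort of older
adults (e.g. hypertension 0.50, diabetes 0.30, any level-2 complicating
factor ≈ 0.64, ADL deficit ≈ 0.06 at mean severity) so that the segment
composition is qualitatively realistic; exact segment shares are
deliberately not a calibration target.

What the generator emulates: marginal outcome rates, overdispersed
utilization, monotone severity gradients in every adverse feature, and the
downstream consequence that higher-RA segments show higher utilization
within each Global Impression level. What it does not emulate: real
condition co-occurrence beyond the single factor, informative missingness,
proxy-response effects, time-to-event structure, or any joint distribution
the study did not publish. Passing calibration tests therefore shows the
pipeline is internally consistent and correctly calibrated to published
marginals — not that it reproduces the real cohort's segment-level values.
The latent severity is stored in cohort provenance for tests and is never
visible to segmentation or scoring.

## Problem sizes and numerical choices

Calibration checks average 100 replicate cohorts of n = 928 (the study's
recruitment size); property suites use 10,000 randomized records for
cascade totality, 120,000 subjects for severity-decile monotonicity and
within-GI RA gradients, 1,000 random tables for the chi-squared oracle,
and 10,000 Monte-Carlo replicates at n = 250 for Wald-coverage checks
(Wald intervals are known to undercover for small p at small n — at
n = 250 exact coverage for p ∈ {0.05, 0.2, 0.5} lies within 0.92–0.95, the
band the tests assert). Quadrature uses 120 Gauss–Hermite nodes; root
finding uses Brent's method on bracketing intervals. Ties and degenerate
inputs: empty cohorts yield empty tables; all-zero count vectors give
point intervals; single-subject segments get se = 0 under the normal
family rather than NaN.

## Known limitations

- The cascade configs encode the published summary of each scheme's
  criteria, not the unpublished full instruments; users with access to the
  original definitions can edit the YAML without touching code.
- The generator's single-factor structure cannot produce segments whose
  outcome ordering deviates from severity ordering (the real cohort shows
  occasional exceptions, e.g. elderly severe-mental-health segments with
  below-average admissions).
- No time-to-event or competing-risk analysis: outcomes are fixed-window
  counts and a death flag, so a subject who dies early can still
  contribute utilization counts, and mortality/utilization associations
  are tested marginally.
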
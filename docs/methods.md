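# Methods

## Measurement model

Each participant answers the same question every fortnight for a year
(26 waves): the number of days, 0–14, their low back bothered or troubled
them in the preceding two weeks. The package treats each answer as an exact
integer on that closed scale; anything else is a validation error. A
fortnight with a recorded 0 is a *zero-fortnight*; two consecutive
zero-fortnights — one calendar month without low back pain — constitute a
*non-episode* (de Vet et al.'s criterion). The value 1 already counts as
pain: no severity information is carried, by design of the instrument.

## Analysis-set exclusion

A participant enters the analysis set only if they answered at least
`min_responses` waves (default 20 of 26). The threshold is configurable but
the default reflects the practical judgement that a pattern with six or more
holes cannot be interpreted reliably. Exclusion is monotone in the
threshold and partitions the enrolled cohort exhaustively; it runs *before*
imputation so values are only ever imputed for analysed participants.

## Manual mean imputation

Each remaining missing cell is filled with

    round_half_up( sum of answered day-counts / number of answered waves )

clamped to [0, 14]. Three choices deserve comment:

- **Denominator = answered waves, not 26.** Dividing a partial sum by all
  26 scheduled messages would bias imputed values toward 0 for anyone with
  missing cells. With at most 6 missing cells and the highly consistent
  reporting these diaries show, the two readings rarely differ after
  rounding, but when they do, the per-answered-wave mean is the defensible
  one.
- **Rounding half-up to an integer.** The completed panel must stay on the
  0–14 day scale because the downstream classification is defined on
  "0 days": a fractional imputed value would make "is this a
  zero-fortnight?" ill-posed. An imputed 0 counts as a zero-fortnight.
- **Consequence for episode detection.** A participant whose answered mean
  rounds to ≥ 1 can never gain a zero-fortnight through imputation; one
  whose mean rounds to 0 has all their missing fortnights counted as
  pain-free. This is the intended behaviour of within-person mean filling
  and is the main way imputation can perturb the classification.

The completed-series mean stays within 0.5·(missing/W) + rounding slack of
the answered-cell mean; the test suite asserts this bound numerically. No
model-based or covariate-based imputation is provided.

## Run-length classification

For a complete series the zero-mask (value == 0) is scanned into maximal
runs of consecutive zero-fortnights. Derived quantities per participant:

- `max_zero_run` — longest run, 0..26;
- `has_nonepisode` — any run of length ≥ 2;
- `nonepisode_count` — the number of *maximal* runs of length ≥ 2. A single
  run of length 4 is one non-episode, not two: "separate" non-episodes must
  be divided by at least one fortnight containing a pain day, otherwise the
  count would inflate meaninglessly with run length;
- `in_nonepisode_at_end` — the final two fortnights both zero, i.e. the
  participant closed the year inside a pain-free month. Fortnightly
  sampling cannot resolve "the last week" more finely than this;
- `pain_free_all_year` — all 26 cells zero.

The implementation (itertools.groupby run-length encoding) is checked
exhaustively against a naive cell-by-cell scanner on all 2^12 binary masks
of length 12, and property tests assert monotonicity: zeroing any single
cell never removes an existing non-episode nor shortens the maximal run.

## Prevalence estimation

Every cohort-level estimate is a binomial proportion k/n reported as an
integer percentage with a 95% Wald (normal-approximation) interval

    p ± 1.96 · sqrt( p (1 − p) / n ),

computed on the exact proportion, clamped to [0, 1], and only then rounded
half-up to integer percent. z = 1.96 (the conventional two-decimal
quantile) is used rather than 1.959964; at these n the difference never
survives integer rounding, and the statsmodels normal interval serves as an
independent cross-check in the tests. This convention — exact proportion
first, clamp, then round half-up — reproduces the published brackets of the
study this pipeline re-implements at n = 261: 83% → (78–88), 59% → (53–65),
52% → (46–58), 19% → (14–24). The study's fifth interval, for the 11% who
never reported a zero-fortnight, is printed inconsistently in its two
appearances ("2–22" and "12–22") and matches no standard binomial interval
(Wald gives ≈ 7–15); the package simply reports its own computed Wald
interval for that estimate.

The Wald interval is known to undercover for small n or extreme p; at
n = 261 and the proportions of interest (0.1–0.9) its coverage is close to
nominal, which the acceptance script verifies empirically (~94–96% over 500
replicate cohorts at the generating rate 0.19). Percentages elsewhere
(participant flow, imputation rate, the responder/non-responder comparison
columns) use the same half-up integer convention; no hypothesis tests are
attached to the responder comparison — it is descriptive, as in the study
design this follows.

## Synthetic cohort generator

The generator emulates the structure of the real panel, not any individual
trajectory:

- **Latent reporter classes, fixed for the whole year.** Each enrolled
  participant is `never_pain`, `low_pain` or `high_pain` with default
  mixture (0.19, 0.51, 0.30). Year-long diaries of this kind show highly
  consistent within-person reporting — people report no pain, few days, or
  many days throughout — so class switching is deliberately not modelled.
  The never-pain weight matches the observed 19% of participants with a
  fully pain-free year; the low/high split mirrors the baseline prior-year
  LBP profile (a majority reporting 1–30 days).
- **Run alternation.** Pain-class reporters start the year inside a pain
  run and flip between pain and pain-free runs with per-wave probability
  `episode_switch_prob` (default 0.08). This is the minimal mechanism that
  produces both episodes and month-long pain-free periods. The default is
  derived from the qualitative shape of the observed max-run distribution:
  with switch rate s, a pain reporter stays in pain all year with
  probability (1−s)^25, and s = 0.08 puts roughly 10% of the cohort at a
  max run of 0 (the study reports 11%) while keeping the distribution's
  modes at the two extremes. Day-counts during pain runs are uniform on
  1–5 (`low_pain`) or 6–14 (`high_pain`).
- **Enrolment and missingness.** Of `n_invited` (default 293),
  `n_declined` (16) contribute no series; `n_low_response` (16) receive
  7–26 missing cells, guaranteeing exclusion under the 20-of-26 rule;
  everyone else has i.i.d. MCAR cell missingness at `cell_missing_prob`
  (default 0.019, the observed 129/6786 ≈ 1.9% rate). No missingness
  mechanism is reported for the real study; MCAR is the weakest assumption
  consistent with so low a rate.
- **Baseline covariates** are sampled independently per participant from
  categorical marginals defaulting to the responder profile of the source
  cohort (54% female, 87% employed, ...). The extracted education rows of
  that profile are garbled in the available text; the defaults use the
  reading under which both columns sum to ~100.

Everything is a deterministic function of the config (including its seed;
NumPy `default_rng`). What the generator does *not* emulate: seasonality,
severity fluctuation within pain runs, covariate-dependent pain or
missingness, and the exact (unpublished) bar heights of the real max-run
distribution. Passing tests therefore demonstrate that the pipeline's
*rules* are implemented correctly and behave consistently on panels with
realistic structure — not that the generator reproduces the real cohort's
point estimates, which cannot be reproduced without the raw diaries.

## Numerical and degenerate-input choices

- Rounding is half-up everywhere (`floor(x + 0.5)`); inputs are ratios of
  modest integers, for which this is exact. Python's built-in banker's
  rounding is deliberately avoided.
- Waves are 1-indexed in every file and report; internal arrays are
  0-indexed but never surfaced.
- A series with zero answered waves cannot be imputed and raises (such
  participants are excluded long before imputation under any sensible
  threshold).
- An empty analysis set, an empty profile collection, and n = 0 proportions
  are errors, not silent zeros.
- For a one-wave study, `pain_free_all_year` can hold while no non-episode
  exists; the profile invariants account for W < 2.

## Problem sizes used in checks

The acceptance script runs the default 293-participant, 26-wave cohort end
to end, plus 500 replicate cohorts of n = 261 with no missingness for the
coverage estimate; the test suite uses the same sizes at its largest and
exhaustive enumeration at length 12 for the classifier oracle. These sizes
match the study design that fixed the package's defaults.

## Known limitations

- Fortnightly granularity under-detects pain-free months that straddle a
  fortnight containing a single pain day; weekly sampling would find more.
  The package classifies at the recorded granularity and applies no
  correction.
- The Wald interval is used for fidelity to the reporting convention it
  reproduces; Wilson or exact intervals would be preferable de novo.
- The responder/non-responder comparison is descriptive only.
- Mid-study dropouts are represented as trailing missing cells within a
  fixed 26-wave frame; rows absent from a long-dialect file simply become
  missing waves.
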
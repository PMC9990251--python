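# Methods

## The barometer model

The NHRS barometer is a composite indicator in the min–max (goalpost)
normalisation family. A country-year observation supplies, per
sub-function, an *actual score* `x`:

* **binary** sub-functions: 1 if the structure exists, 0 if not;
* **per-capita rates**: `count / population × scale`, scale 100,000
  (research staff; publications) or 1,000,000 (universities);
* **budget share**: `allocation / total_health_budget × 100` percent.

Each actual score is normalised to a sub-function index
`SFI = (x − min) / (max − min)`, clamped to [0, 1]. Function scores are
unweighted means of their own indices × 100; the overall score is the
unweighted mean of all indices × 100. With the default 6/6/3/2 indicator
partition this makes the overall score the *indicator-count-weighted*
mean of the function scores — for Mauritius 2020 the unweighted mean of
function scores is ≈ 59.3 while the overall score is 60.84, and both
facts are asserted in the tests. All sub-functions are equally weighted;
weighted variants are deliberately out of scope.

Performance bands partition [0, 100]: 0 nonexistent, (0, 50) below
average, 50 average, (50, 100) above average, 100 optimal. Band-endpoint
equality is tested with absolute tolerance 1e-9 and scores are *not*
pre-rounded before banding; the conventional wording "1% to 49%" is read
as the open interval (0, 50). The performance gap is `100 − score`.

## Goalposts

Three goalpost provenances are recorded explicitly, because downstream
tooling must know which goalposts to refresh from a cohort:

| provenance | default-schema members | value |
|---|---|---|
| `fixed` | 13 binaries; staff per 100k | (0, 1); (0, 100) |
| `cohort_max` | universities per million; publications per 100k | 5.39 (Cabo Verde); 12.514 (South Africa) |
| `policy_target` | budget share | 2.0% of the health budget |

`derive_cohort_goalposts` recomputes a `cohort_max` goalpost as the
maximum actual score in a cohort; ties break to the first country in
input order (logged). Because cohort maxima are historical benchmarks, a
later observation can exceed them: indices outside [0, 1] are clamped
with a `clamped` flag rather than rejected.

## Precision modes

Internal computation is full double precision; rounding is presentation
only. Two aggregation modes exist because published scorecards are
produced in spreadsheets from *printed* intermediates:

* **exact** (default): no intermediate rounding. Mauritius 2020 index
  sum 10.3427, overall 60.84%.
* **as_printed**: actual scores rounded half-up to 3 decimals, indices
  to 4 decimals, before aggregation. This reproduces the published
  intermediate sum 10.3426 exactly (the 3-decimal budget share 0.328
  yields index 0.1640 where exact arithmetic gives 0.16408…). Overall is
  60.84% in both modes.

Half-up rounding (via `decimal` on the shortest float repr) is used
rather than Python's banker's rounding, matching spreadsheet behaviour.

## Missing data

Strict mode (default) raises a `MissingDataError` naming indicator and
country. Permissive mode scores a missing *binary* flag as 0 with a
logged warning — the survey convention that undocumented structures are
treated as absent. Missing counts, populations or budgets are always
errors: there is no sensible zero-imputation for a denominator. Staff
head counts aggregate full-time and part-time staff at parity, without
FTE weighting. Currency is an opaque unit; both budget fields must share
it, and the budget-share computation is invariant to rescaling both.

## Temporal comparison

Changes between rounds are reported both as percentage points
(`current − baseline`) and as percent of baseline
(`(current − baseline)/baseline × 100`), since published narratives mix
the two framings; exports label them `abs_change_pp` and
`rel_change_pct`. Relative change is undefined at baseline 0 and
reported as missing. Earlier rounds' scores are stored as opaque
percentages (their sub-function inputs were not re-collected), so labels
absent from one round are reported as incomparable rather than erroring.

## Synthetic cohorts

`simulate_cohort` emulates the structure — not the between-country
correlation — of a regional NHRS survey:

* binary flags: independent Bernoulli(p) per indicator;
* populations: uniform integers on `population_range`
  (default 2–60 million, typical of the region's states);
* counts: Poisson with mean `rate × population`, so per-capita actual
  scores vary realistically around `rate × scale`;
* budget share: Gamma with mean `budget_share_mean` (default 0.5%) and
  sd `budget_share_dispersion` (default 0.3), chosen Gamma rather than
  truncated normal so the configured mean is the exact distribution mean
  (truncation at 0 would bias it upward and break the closed-form
  expectation check); the share is converted to currency against a total
  budget drawn as population × per-capita spend.

Default Bernoulli probabilities (0.35–0.9 by indicator) echo the mixed
regional prevalence of governance structures — ethics committees and
NGOs common, research management forums rare; default rates (5 staff per
100k, 1 university per million, 3 publications per 100k) put countries
in the interior of the goalposts, so clamping probability is negligible
(< 1e-3) and the closed-form expected overall score

`E[overall] = mean_i E[SFI_i] × 100`, with `E[SFI] = p` (binary) and
`(E[x] − min)/(max − min)` (continuous, unclamped)

is exact up to that clamping. `expected_overall_score` flags itself
`approximate` whenever the per-indicator clamping probability (Poisson
tail at the smallest population; Gamma tail for the share) exceeds 1e-3.

One integer seed drives everything; each country draws from a substream
keyed `(seed, country index)`, so enlarging the cohort never reshuffles
earlier countries, and cohort exports are byte-identical across reruns.

What passing simulator-based tests shows: the pipeline is correct under
independent indicators with known margins. What it does not show:
robustness to the correlated, missing-not-at-random structure of real
regional survey data.

## Problem sizes in tests

Statistical checks use cohorts of 2,000 countries (binary-probability
recovery and the Monte-Carlo vs analytic comparison, both at 3 standard
errors), 200-observation oracle-equivalence sweeps, and 500 random
cohorts for the goalpost scan oracle; the whole suite runs in a few
seconds on one CPU.

## Known limitations

* No uncertainty quantification: the barometer publishes point scores.
* No FX conversion, no FTE weighting, no sub-function weights.
* The publication count is an input; bibliographic search/screening is
  out of scope.
* Historical round scores are inputs, not recomputable: their underlying
  survey data are not part of the package.
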
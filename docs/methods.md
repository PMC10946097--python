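# Methods

## Data model and regimen reconstruction

The registry is five delimited tables: persons (demographics, first/nadir CD4,
first viral load), regimen episodes (one row per drug exposure interval with a
dosing-frequency flag), viral loads (copies/mL, with a below-limit flag for
"<limit" assay results), resistance results (one interpreted level per person,
test date and drug: susceptible < low < intermediate < high), and
questionnaires (Likert 1–6 physical and psychological health, missed doses in
the last week).

Regimens are derived objects: `build_regimens` sweeps the per-drug episode
intervals and returns maximal intervals of constant active drug set, in
chronological order, excluding intervals with no active drug. All intervals
are half-open `[start, end)`; a regimen ending exactly on the index date is
not current, and adjacent regimens abut without double-counting a day.
Overlapping duplicate records of one drug are merged with a warning; invalid
dates are rejected. A configurable gap tolerance (default 0 days) controls
whether a short treatment interruption between two identical drug sets merges
them; the conservative default never merges across a real gap.

Time on therapy is **cumulative exposure** (days covered by at least one
regimen), not time since first start. This is the stricter reading of a
"five years on therapy" requirement and matters for people with treatment
interruptions.

## The five category rules

Month/year phrasings are fixed to day equivalents so results are
reproducible: 3 months → 90 d, 6 months → 183 d, 12 months → 365 d,
5 years → 1826 d. All thresholds sit on a `RuleThresholds` object and can be
varied for sensitivity runs.

- **Advanced resistance** takes each drug's maximum interpreted level over
  all tests ever recorded (archived resistance persists clinically), and
  requires ≥ 2 drugs at ≥ intermediate level spanning ≥ 2 drug classes.
  Persons never tested cannot qualify; nothing is imputed.
- **Four-drug regimen** counts distinct non-booster drugs in the current
  regimen (≥ 4 qualifies) and requires some strictly earlier regimen with 2
  or 3 non-booster drugs. Ritonavir-as-booster and cobicistat are never
  counted.
- **Salvage therapy** triggers on the mere presence of ibalizumab,
  fostemsavir, enfuvirtide, maraviroc or etravirine in the current regimen,
  on twice-daily dolutegravir, or on twice-daily darunavir co-occurring with
  a booster in the same regimen. The booster itself need not be twice-daily.
  An unknown dosing flag counts as not twice-daily (conservative: salvage is
  not inflated by missing dosing data).
- **Recent virologic failure** needs two measurements ≥ 200 copies/mL inside
  the half-open window `(index − 365 d, index]`, at least 90 days apart
  (inclusive), plus ≥ 1826 cumulative therapy days. Below-limit results never
  qualify regardless of their limit.
- **Multiple switches following failure**: a regimen fails when a viral load
  ≥ 50 copies/mL dated on or after 2008-01-01 (the date the national
  register reached full coverage; the anchor applies to the failing
  measurement, not the regimen start) is measured while the person is on the
  regimen, and the next regimen starts within 183 days of that measurement.
  The flag requires two failing regimens adjacent in the regimen sequence;
  treatment gaps between them are allowed. A "switch" is a change in the set
  of non-booster drugs, so consecutive regimens differing only in boosters
  are collapsed before failure detection.

Open design points resolved here: "currently" means the regimen whose
interval contains the index date (not the most recent prescription); salvage
drugs are flagged on drug presence irrespective of co-drugs; a viral load
measured during a treatment gap cannot define failure of the preceding
regimen (it is not measured *on* the regimen); the four-drug count is ≥ 4
rather than exactly 4 (both configurable).

## Outcomes and statistics

Viral suppression is judged on the **last available** measurement (below the
50 copies/mL threshold, or a below-limit result whose assay limit is ≤ 50),
among persons with at least one measurement in the trailing year; persons
whose first-ever therapy start lies within 183 days before the index date are
excluded. Same-day ties resolve pessimistically. Patient-reported outcomes
use the most recent questionnaire within 24 months; per-item missingness is
allowed, so the physical and psychological analyses can have different n.
Missed doses are banded 0 / 1–2 / ≥ 3.

Group comparisons use the Mann-Whitney U test (two-sided normal approximation
with tie correction and continuity correction) for continuous variables and
Pearson's χ² without continuity correction for categorical ones. Odds ratios
come from logistic regression: a crude model (outcome ~ difficult) and an
adjusted model adding sex (reference: man), age in years (linear, centered at
50 for conditioning only), and risk group (reference: heterosexual; MSM, IDU,
other). Wald 95% intervals, two-sided α = 0.05, no multiple-testing
adjustment, complete-case handling of missing covariates. The crude logistic
OR is algebraically identical to the 2×2 cross-product OR; the test suite
asserts this to six significant figures. Newton fitting falls back to BFGS
when quasi-separation in a covariate cell makes Newton oscillate; genuine
non-convergence and zero cells raise explicit errors rather than returning
penalized estimates.

The asymptotic Mann-Whitney p-value tracks the exact permutation p-value to
within 0.02 at n = 8 per group for continuous (untied) data; with heavy ties
at very small n the normal approximation is rougher, a known limitation of
the approximation rather than of the implementation.

A sensitivity analysis removes the recent-virologic-failure category (whose
members have recent unsuppressed measurements by definition) from the
suppression comparison entirely; an empty difficult group is reported as
degenerate rather than as a number.

## Synthetic cohort

The generator's defaults are the study conditions of the modeled 2023
national cohort: 9.37% difficult overall with category marginals
2.20/0.60/1.65/0.69/6.08% (advanced resistance / four-drug / salvage /
recent failure / multiple switches), resistance-test coverage 67%,
questionnaire coverage 48%, suppression probability 0.84 for the difficult
group versus 0.95 for the non-difficult, physical satisfaction 0.55 vs 0.63,
psychological 0.64 vs 0.66, index date 2023-04-06, histories spanning
1985 onwards, and viral loads sampled at 90–180 day intervals.

Category co-membership within the difficult group follows the
maximum-entropy distribution over the 31 nonempty subsets consistent with
the category marginals, fitted by iterative proportional fitting and tilted
by pairwise enrichment factors (defaults: recent failure with multiple
switches ×6, advanced resistance with salvage ×3, and ×2 for the
four-drug pairings) reflecting the strong observed overlaps. Within the
difficult group, recent-failure members suppress at 0.36 and the rate for
the remaining members is solved so the overall difficult rate still meets
its 0.84 target in expectation; a `suppression_or` option instead fixes the
true crude odds ratio against the non-difficult group, which the
parameter-recovery test exploits.

Plants are **constructed, not rejection-sampled**: a planted
recent-failure person receives two measurements ≥ 220 copies/mL placed
95–240 days apart inside the final year on ≥ 1950 cumulative therapy days;
a planted switch-failure person receives a block of 2–3 failing regimens
(failing measurement followed by a switch within 30–150 days) ending at
least 430 days before the index date so the block can never double as
recent failure; non-plants violate every rule by a margin (initial viremia
at least 220 days before any switch, routine results below the assay limit,
single-class or single-drug resistance patterns, ≤ 3 non-booster drugs).
Ground-truth labels are emitted beside the tables and never read by the
classifier; the core test is exact row-for-row recovery.

What the generator does **not** emulate: transmission dynamics, within-host
viral kinetics, drug-specific switching practices, informative questionnaire
non-response, or correlated missingness. Passing tests therefore demonstrate
that the classifier implements the documented conventions exactly and that
the statistical pipeline recovers known effects — not that the rules capture
every ambiguity of real register data (e.g. backlogged pre-2008 records or
pharmacy-level adherence).

## Problem sizes and numerics

The default test scenario uses 2,000 persons (the full-scale script uses
8,531); the parameter-recovery check averages 200 replicates of 2,000
persons, giving a Monte-Carlo standard error of about 0.005 on a true odds
ratio of 0.29. Oracle-equivalence checks run 1,000 random histories against
brute-force all-pairs / adjacent-pairs scans. Percentages are displayed
rounded half-up to integers (full precision kept in CSV); intersection cells
under 10 persons are masked in display output but retained in the full
export. All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seed and configuration give
byte-identical CSV output.

## Known limitations

- The classifier consumes already-interpreted per-drug resistance levels; it
  does not score genotypes.
- The suppression eligibility window and the "last available" measurement
  are evaluated independently: the last measurement itself may be older than
  a year when an in-window measurement exists elsewhere; with the generator's
  histories this does not occur, but real extracts could exercise it.
- Wald intervals require all four 2×2 cells positive; rare-category analyses
  on small cohorts fail loudly instead of silently switching to exact
  methods.
- The gender-identity variable, comorbidities and co-medication are outside
  the data model.
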
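# Methods

## The disproportionality model

A spontaneous reporting system accumulates reports, each naming one or
more drugs (with role codes: primary suspect PS, secondary suspect SS,
concomitant C, interaction I) and one or more MedDRA-coded reactions.
For a target drug and an event term the package forms the 2×2 table
over **distinct deduplicated reports**

|                | event | other events |
|----------------|-------|--------------|
| target drug    | a     | b            |
| other drugs    | c     | d            |

and computes four families of statistics:

* **ROR** = ad/(bc), interval exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
* **PRR** = a(c+d)/(c(a+b)), interval on the log scale with standard
  error √(1/a − 1/(a+b) + 1/c − 1/(c+d)), paired with the uncorrected
  Pearson χ² = (ad−bc)²N/((a+b)(c+d)(a+c)(b+d)). The PRR interval
  formula is the conventional pharmacovigilance choice; sources that
  print PRR intervals rarely print the formula, so this is documented
  here as an assumption.
* **BCPNN information component** IC = log₂(aN/((a+c)(a+b))), the
  observed/expected log-ratio. The 95% interval is IC ± 2·√V(IC) with
  the closed-form posterior variance of Bate et al. (1998) under the
  standard priors (α₁=β₁=γ₁₁=1, α=β=2, with the joint prior parameter
  tuned so the posterior expectation vanishes under independence). A
  Monte-Carlo interval from independent beta posteriors of the three
  reporting probabilities is available via `ic_stat(..., interval="mc")`;
  a fully Bayesian point estimate via `estimator="bate"` (defined even
  at a = 0, unlike the log-ratio).
* **EBGM** in its closed form aN/((a+c)(a+b)) with a log-scale Wald
  interval reusing the ROR standard error. No gamma-Poisson shrinkage
  is fitted: the closed form is the definition used here, and a hook
  (`ebgm_stat`) is the single place a shrinkage estimator could be
  substituted. Consequently IC = log₂(EBGM) holds identically.

**Zero cells.** No continuity/Haldane correction is applied anywhere.
An estimate whose formula is unavailable for a table (e.g. ROR with
any empty cell, PRR with a = 0 or c = 0) is returned as NaN with a
`"zero-cell"` reason, and its signal flag is false. Corrections would
silently change flag decisions; explicit undefinedness does not.

**Signal criteria.** ROR: interval lower bound > 1 (strict) and n ≥ 3;
PRR: PRR ≥ 2 and χ² ≥ 4 (both inclusive) and n ≥ 3; BCPNN: IC025 > 0
(strict); EBGM: EBGM05 > 2 (strict). The combined flag defaults to
"any algorithm positive"; an "all four" flag is reported alongside.
Thresholds are configurable (`CriteriaThresholds`).

**Table inversion.** `reconstruct_table(a, N, ROR, PRR)` recovers the
real-valued (b, c, d) behind a published row: given b, the PRR
equation fixes c = a(N−a−b)/(PRR(a+b)) exactly, reducing the problem
to a one-dimensional Brent root-find in b on the ROR residual
(relative tolerance 1e-10, verified on both residuals). In the regime
b, c ≪ N the solution is unique; an infeasible target (ROR ≤ PRR or no
sign change) raises with the residual range. This is how published
interval bounds can be re-derived from printed (n, N, ROR, PRR) alone.

## Counting conventions

The counting unit is the distinct deduplicated report, at both PT and
SOC levels: a report mentioning a PT twice counts once for that PT,
and a report with several PTs of one SOC counts once for that SOC.
Database-wide totals (N) are reports, not drug–event rows; this is the
only reading consistent with per-cohort denominators in published
demographic tables.

Cohort membership requires keyword and role to hold for the *same*
drug mention. Keyword matching is case-insensitive substring matching
after removing whitespace and hyphens from both sides ("DCC-2618",
"dcc 2618" and "DCC2618 CAPSULE" all match "DCC 2618"), applied to the
verbatim drug name and the active-ingredient field. No fuzzy matching:
it would change counts silently. The default role set is {PS}.

## Ingestion rules

* Deduplication keeps, per CASEID, the row with the latest FDA receipt
  date, ties broken by the larger numeric PRIMARYID; deleted-case
  lists are applied in the same pass. The rule is deterministic,
  idempotent and never invents rows.
* Dates are accepted at 8- (day), 6- (month) and 4-digit (year)
  precision; dedup comparisons use zero-padded lexicographic order,
  which is consistent because partial dates are prefixes of YYYYMMDD.
* Ages are normalized to years (decade ×10, month ÷12, week ÷52.18,
  day ÷365.25); weights are assumed kilograms with values > 400 set
  missing (a crude outlier guard, logged here as a constant in
  `faers_io`). Unparseable values become missing, never errors.
* Ragged rows, keyless rows, orphan child rows and unknown outcome
  codes are skipped and tallied in an `AnomalyLog` that the pipeline
  manifest reproduces in full, so the report flow from raw rows to
  cohort is auditable.

## Demographics and time to onset

Weight bands <50 / 50–100 / >100 kg; age bands <18 / 18–64.9 / 65–85 /
>85 years; occupations collapsed to consumer vs health professional;
missing always reported as its own row. Outcome percentages use the
total number of outcome entries as denominator (a report may carry
several outcome codes; a code-less report contributes one missing
entry) — counts within every other characteristic sum to the number of
reports.

Time to onset is event date minus the earliest full-precision therapy
start among matched target-drug mentions. Partial dates are excluded,
not imputed, with reasons tallied (`missing_event_date`,
`missing_start_date`, `partial_date`, `negative_interval`).

Medians and quartiles use the order-statistic (inverted-CDF, R type 1)
convention: the reported median and IQR endpoints are always observed
day counts, e.g. `[27, 99, 245]` → median 99, IQR 27–245. Any fixed
convention would be defensible; this one was chosen because published
onset summaries of small cohorts report observed values, and it is
frozen in the tests. Bins use 30-day months with one coarse 6–12-month
bin and an open-ended >12-month bin; custom edges are supported
(`--bins`), with a leading 0 edge enforced.

## The synthetic generator

The generator emulates the multi-table FAERS case structure case-first:
demographics, then drugs (independent Bernoulli per catalogue drug, one
uniformly chosen mention becoming primary suspect), then reactions —
each PT with probability min(1, λ·q), where q is the PT's Zipf-like
background probability and λ the largest planted multiplier among the
report's drugs (λ = 1 when none). Planted conditional probabilities are
therefore analytic, and expected cell counts follow directly
(E[a] ≈ n·p_drug·min(1, λq)). Multiplier capping at probability 1 is
explicit: it is logged and flagged in the ground truth.

Guaranteeing at least one drug and one reaction per report uses a
background-proportional fallback draw. With a dense catalogue (the
bundled `example_config` has ≈2 expected reactions per report) the
fallback fires rarely and perturbs planted conditionals negligibly;
with a sparse catalogue it would dominate, so calibration-grade
configurations must keep the total background reporting rate well
above 1. The calibration suites (null-pair interval coverage over 200
replicates; replicate-mean ROR within 15% of λ = 5 at expected a ≥ 30)
run under such configurations at n = 2,000–4,000 reports per
replicate, sizes chosen so the whole suite completes in well under a
minute while keeping expected cell counts in the asymptotic regime the
Wald intervals assume.

Duplicate case versions copy the clinical content and perturb only
PRIMARYID and FDA date (canonical = latest); deleted cases are extra
cases listed in `DELETED.txt`, so after deduplication and deletion the
case count equals `n_reports` exactly. Onset days come from a
two-component Weibull mixture (defaults: weights 0.5/0.5, shapes
0.8/1.6, scales 60/280 days) producing the early peak plus late rise
typical of chronically dosed oncology drugs; per-SOC overrides
(`onset_by_soc`, keyed by the SOC of a report's first reaction) allow
constructing early- vs late-onset organ classes. Dates are YYYYMMDD
with configurable fractions of partial (6- or 4-digit) and missing
dates to exercise the exclusion rules.

What the generator does **not** emulate: real FAERS marginal
frequencies and dictionaries, narrative fields, correlated
demographics, reporting-delay structure beyond a uniform 0–60-day lag,
or per-field missingness beyond the date fields and the categorical
"missing" levels. Passing tests therefore demonstrate correctness of
the pipeline's logic and calibration under the stated generative
model, not robustness to every artefact of real spontaneous-report
data.

## Numerical and design notes

* Intervals use the literal z = 1.96 of the printed formulas, not the
  exact normal quantile (a 2·10⁻⁵ relative difference); the oracle
  tests against statsmodels account for exactly this ratio.
* The Bate closed-form variance is undefined nowhere (priors keep all
  denominators positive), so IC flags are available even at a = 0 when
  the Bayesian estimator is selected.
* `rank_signals` sorts NaN keys last, breaking ties by larger n then
  term name; the SOC-level table is conventionally cut at n > 100
  (configurable, `soc_min_n`).
* Pipeline outputs are byte-deterministic for a given config + seed:
  fixed column orders, `\n` newlines, gzip intermediates written with
  a zeroed timestamp, and a manifest carrying the seed and a config
  digest.

## Known limitations

* EBGM is the closed form, not a fitted gamma-Poisson shrinkage
  estimate; small-count EBGM values are therefore unshrunken and
  coincide with the relative reporting ratio.
* No multiple-testing correction is applied, matching standard
  signal-detection practice; signals are hypotheses, not confirmed
  risks, and reporting rates are not incidence rates.
* Stratified (age/sex) disproportionality, LLT→PT mapping, and
  HLT/HLGT aggregation are out of scope; PT strings are trusted as
  MedDRA-coded.
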
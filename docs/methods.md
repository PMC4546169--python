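# Methods

## The assessment model

The unit of analysis is the clinical log: one patient-day of systematic
voiding programme (SVP) documentation. Fidelity to delivery is scored by a
staged filter of key quality indicators, each stage a prerequisite for the
next:

1. **Interval validity.** The voiding interval must be present and a single
   value. A range ("2 – 3 hourly") or a blank leaves the interval undefined,
   so the correctness of everything downstream cannot be judged; assessment
   of the log terminates.
2. **Schedule validity.** With at least two proposed times, no blank entry
   may sit between the first and last proposed time, and every consecutive
   gap must equal the interval. A gap tolerance (`tolerance_minutes`,
   default 0 — exact to the minute, since the indicator demands gaps
   *identical* to the interval) is exposed for noisier transcriptions.
   Schedules that start after 07:30 or stop before 21:30 are *not* failed:
   the indicator demands completeness between its own endpoints, and
   day-span coverage is visible separately through the mean number of
   proposed times. A log with fewer than two proposed times fails here
   (`no_proposed_times`): no interval can be exhibited, which is the
   conservative reading.
3. **Timing adherence.** For each proposed occasion, was an actual void
   documented within the leeway window w (default 30 min, **inclusive**:
   |actual − proposed| ≤ w; "within 30 min" has no stated boundary
   semantics, and the inclusive convention is fixed so tests are exact)?
   Occasions carrying an accepted justification code (patient off ward,
   asleep, refused, medically unstable — a configurable list, since the
   original adjudication criteria are not public) are exempted from
   numerator and denominator. Matching of actual voids to proposed slots is
   **one-to-one maximum-cardinality**, greedy by earliest proposed slot
   then earliest admissible actual: one void can never satisfy two slots,
   and for symmetric interval admissibility this greedy order attains the
   exhaustive maximum (property-tested against full enumeration). Actual
   voids recorded on exempted rows stay in the matching pool — the patient
   did void then, and a neighbouring slot may claim it.
4. **Best practice.** Per proposed occasion, count answers literally equal
   to "yes". Missing and "no" both count as not-yes, but are represented
   distinctly end-to-end (staff often leave an answer blank rather than
   write "no", so missingness must survive IO). The asked-if-wet item
   applies to prompted-voiding logs only.

### Pooling conventions

Stage-1 and Stage-2 percentages are of **all** logs in an arm; Stage-3/4
percentages are over Stage-1&2 passers only. "On average, how often…" is
ambiguous between an unweighted mean of per-log proportions and a pooled
ratio of occasions; the default is the per-log mean (each patient-day
weighted equally), with `stage_mode="pooled"` selectable — the two are both
reported by the tests because they genuinely diverge. Passers whose every
occasion was exempted have an undefined proportion and are excluded from
the per-log average; their count is carried in the summary
(`n_stage3_undefined`). Pooling deliberately ignores clustering by site and
patient and produces no confidence intervals: the output is a descriptive
audit table, not an inferential comparison. Percentages are rounded
half-up to one decimal at presentation only; aggregation runs at full
precision. Undefined values (zero denominators) are `None`/JSON `null`,
rendered as an em dash, never 0.

## Audit-period sampling

Each site's planned recruitment window is split into three near-equal
contiguous strata, remainder days to the last stratum (the split rule is
not prescribed anywhere; near-equal is the neutral choice). Recruitment
extension beyond the planned end forms additional strata of at most one
planned-stratum length each, so long extensions gain proportionally more
sampling. Two non-overlapping 14-day periods are drawn per stratum,
**uniformly over all valid ordered start-day pairs** — the original
statistician's randomisation scheme is unknown, and uniformity is the
neutral, testable default (a chi-square test against the enumerated pair
marginals over 10,000 seeds is part of the suite). Date ranges are
half-open `[start, end)`. A stratum under 14 days is a stratification
error; one under 28 days is a sampling error. Plans of 6–9 periods match
the range observed across real sites and are flagged, not enforced.

## The synthetic-log generator

Real SVP logs are confidential, so the generator produces fleets with the
statistical structure the assessment is built to detect. Per log: a true
interval is drawn from `interval_choices`; the written interval text is
then blank with `p_interval_missing`, a range with `p_interval_range`,
else the single value. The schedule runs from 07:30 at the interval up to
21:30; with `p_schedule_miscalc` every gap shrinks by 60 minutes (the
observed "3-hourly prescribed, times every 2 hours" pattern, fixed at
−60 for determinism) keeping the slot count; each *interior* slot is
deleted with `p_schedule_gap` (never the first or last, so the
between-the-endpoints completeness rule is what catches it). Each slot's
actual void is present with 1 − `p_void_missing` at proposed +
N(0, `timing_sd_minutes`), rounded to the minute and clipped to the
07:30–21:30 window; missed slots carry a justification code with
`p_exempt_comment`. Best-practice answers are iid
yes/missing/no per the configured probabilities. Everything is driven by
one `numpy` generator seeded from the config, so identical configs give
identical fleets.

### Reference conditions (the defaults)

Defaults are fixed once to resemble the published arm-level picture of the
feasibility trial this kind of audit comes from: 2 arms × 4 sites × 10
patients × 10 days (800 logs; ~40 patients and ~400 logs per arm, matching
the audited sample sizes); interval mix {2 h: 0.50, 2.5 h: 0.34,
3 h: 0.16}, mean 2.33 h as printed; 8 % missing + 6 % range intervals
(Stage 1 ≈ 86 %); 15 % per-interior-slot gaps and 15 % miscalculated
schedules (Stage 2 given Stage 1 ≈ 39 %); σ = 25 min timing noise with
40 % missing voids and 25 % of those justified (pooled Stage-3 rate
≈ 53 %, near the printed mid-50s); 95 % prompted voiding; encouragement
yes/missing 0.58/0.30 and wet 0.60/0.28. No published distributions exist
for these error processes; the values are one realistic choice and are not
revisited.

### What the generator does not emulate

Deviations are iid Gaussian and error processes are independent across
slots, logs and staff; real documentation errors cluster by nurse, shift
and weekend staffing, and missingness is likely informative (selective
documentation when a component was not done). Interval choice is iid per
log rather than patient-individualised and persistent. The full-day
schedules give ~6.6 proposed times per passing log versus ~5 observed in
practice, where schedules often spanned less of the day. Passing the
parameter-recovery suite therefore shows the pipeline measures what the
generator encodes — not that real wards behave like the generator.

## Closed-form expectations

`expected_summaries(config)` gives the analytic expectation of each
pipeline statistic:

* Stage 1: 1 − p_missing − p_range.
* Stage 2 | Stage 1: (1 − p_miscalc) · E[(1 − p_gap)^interior] over the
  interval mix (interior = slots − 2; any interior deletion produces a
  double-length gap and fails Stage 2, so survival is exact).
* Stage 3 (pooled occasions): (1 − p_void_missing) · h̄ /
  (1 − p_void_missing · p_exempt), with h̄ the slot-weighted hit
  probability over the passer interval mix. Per slot,
  h = Φ(hi/σ) − Φ(lo/σ) with lo/hi = ∓(w + 0.5) — minute rounding widens
  the window by half a minute each side — replaced by ∓∞ when the slot
  lies within w of a day-window edge, because the clipped tail lands on
  the edge inside the window. The first slot always sits at 07:30, so
  this boundary correction is always present; at σ = 20 and w = 30 it
  moves the 2-hourly-schedule expectation from the plain 2Φ(1.5) − 1
  ≈ 0.8664 to ≈ 0.8886. Cross-slot matching (a void from one slot
  claimed by a neighbour) is possible only for deviations beyond
  interval − w ≥ 3.6 σ at the defaults and is neglected.
* Stage 4a/4b: the configured yes-probabilities.
* Means over passers use the passer-tilted interval mix
  w_i (1 − p_gap)^{n_i − 2} (longer schedules have more interior slots and
  survive Stage 2 less often, so the passer mean interval sits slightly
  above the drawn mean).

The parameter-recovery suite runs a 5,000-log fleet through the full
pipeline and requires every statistic within 3 standard errors of these
expectations (binomial SEs at the realised denominators; analytic
variances for the means). The σ = 20 timing experiment uses a clean
2-hourly configuration with ~2,080 occasions.

## Numerical and degenerate-input choices

* Times are integer minutes since midnight; "HH:MM" 24-hour IO. The
  interval grammar accepts integers or half-hours followed by a
  dash/en-dash/space and "hourly" (case-insensitive); two dash-separated
  numbers are a range; anything else is unparseable, never an exception.
* CSV reading degrades row-by-row: malformed times become missing with a
  warning in the JSON load report; rows with no time, and logs violating
  structural invariants, are skipped with warnings; a missing column is a
  schema error naming the column. Blank best-practice cells are missing
  (bladder-training wet cells read as not-applicable); the writer emits
  `not_applicable` explicitly so round-trips are exact.
* `percent` uses exact decimal division with half-up rounding (31.875 →
  31.9); zero denominators yield the undefined marker.
* Problem sizes in the test suite (160–5,000-log fleets, 10,000 sampling
  seeds, exhaustive matching up to 5×5 occasions on a 6-point grid) are
  chosen so each statistical bound is computable at 3 SE while the whole
  suite runs in seconds.

## Known limitations

Exemption semantics are code-list-driven because the original
clinically-justifiable criteria are unpublished; whether the original
analysis matched voids one-to-one, and whether its averages were per-log
or pooled, are not recoverable, so both conventions are exposed and the
defaults documented above. The trial's own arm-level stage rates are not
reproducible end-to-end without its raw logs; the pipeline's correctness
is instead established by worked-example rules, exhaustive matching
oracles, closed-form parameter recovery, and the published count
arithmetic.
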
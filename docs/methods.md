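# Methods

## Data model and cleaning

The pipeline consumes FAERS-style quarterly packages: $-delimited ASCII
tables DEMO (one row per report *version*), DRUG, REAC, INDI, OUTC, THER,
plus an optional deleted-case list (one CASEID per line, present for
quarters from 2019Q1 onward). Files are decoded as Latin-1 with
undecodable bytes replaced, since public archives contain non-UTF-8
bytes. A strict/lenient switch controls whether unexpected extra columns
abort or warn.

**Partial dates.** FAERS dates are YYYYMMDD integers that are often
truncated. The conventions here: `YYYYMM` is imputed to day 15 and
flagged, so interval arithmetic stays possible but auditable; `YYYY`
yields a missing date whose year is retained for binning; anything else
is missing with a warning. Day intervals are inclusive calendar
differences (event − start, no +1), so a same-day onset is 0 days and
falls in the first "0–30" histogram bin.

**Units.** Ages are converted to years (decades ×10, months ÷12, days
÷365.25); a missing unit with a plausible value (0–120) is assumed to be
years — the dominant convention in the raw data — and warned about.
Weights convert lbs → kg by 0.45359237. Negative values become missing.

**Deduplication.** Applied to the concatenation of all loaded quarters
(a case updated across quarters must collapse to its latest version):
sort by CASEID, FDA receipt date, PRIMARYID; keep the last row per
CASEID. A missing receipt date sorts before any real date, so a dated
version always wins; a full tie falls to the largest PRIMARYID. Cases on
the union of deleted-report lists are then removed. Satellite rows of
discarded versions are dropped. Every discard is logged to an audit
table with its reason.

## Cohort definition

A report enters the cohort when at least one DRUG row (i) matches a
configured name pattern case-insensitively in `drugname` or `prod_ai`
(defaults: the generic name and its brand synonym), (ii) carries a
qualifying role code (default: primary suspect only), and (iii) has a
whitelisted indication joined on (PRIMARYID, drug sequence) — the
indication must belong to the matched drug, not merely co-occur in the
report. Reports whose matched drug's indication is missing or ambiguous
("cancer", "malignant neoplasm", blank) are excluded from the cohort.
Reports are further restricted to a quarter window on the FDA receipt
date.

The comparator ("background") defaults to every other retained report in
the window — standard practice for spontaneous-report disproportionality
— with a configurable alternative restricted to whitelist-indication
reports, since reasonable analyses differ here. The cohort/background
partition is exact: no report is in both, and together they cover the
window.

**Demographic summaries** bin age as <18, [18, 65), [65, 85], >85 and
weight as <50, [50, 100], >100 kg, with Missing as an explicit bin so
percentages always total 100. Each report contributes one outcome
category by severity precedence Death > Life-Threatening > Disability >
Hospitalization > Congenital Anomaly > Required Intervention > Other
(the published tables this mirrors assign exactly one outcome per
report; the precedence order is this package's choice). A report is
"serious" iff any outcome code other than OT is present. Reporter
occupations map to Consumer/Health Professional/Pharmacist/Physician,
everything else to Missing. When a report lists several administration
routes, one is chosen by the precedence intravenous > parenteral >
subcutaneous > oral.

## Disproportionality statistics

Counting is report-level: for each PT occurring in the cohort, `a` is
the number of distinct cohort reports listing it (a PT listed twice in
one report counts once), `b = cohort − a`, and `c`/`d` likewise over the
background. The four measures and their criteria are as in the README
table. Numerical choices:

* **No continuity correction.** A zero cell makes the affected statistic
  undefined (NaN) rather than producing an invented finite number; an
  undefined statistic never signals. The a ≥ 3 case-count criterion makes
  the a = 0 case moot anyway.
* **χ²** is the uncorrected Pearson statistic (no Yates term).
* **PRR positivity** is the conjunction of both published criterion rows
  (CI rule AND χ² rule) — the conservative reading.
* **EBGM** is implemented as the printed closed form: the relative
  reporting ratio a·N/((a+c)(a+b)) with a log-normal 95% interval. The
  full DuMouchel gamma-Poisson mixture fit (true empirical-Bayes
  shrinkage) is an explicit non-goal; at small `a` the closed form is
  noticeably anti-conservative relative to a shrunk estimate, which is
  why the EBGM05 > 2 criterion should be read alongside the other three.
  A corollary used by the tests: IC = log₂(EBGM) identically, and for
  any all-positive table with ad > bc, ROR > PRR > EBGM > 1. Note the
  relative reporting ratio is *not* monotone in `a` at fixed b, c, d
  (it tends to 1 as a → ∞), unlike ROR and PRR.
* **IC interval dialects.** The lower credibility bound of the
  information component has no single convention. Dialect
  `log2-transform` (default) applies the same log-normal standard error
  as the EBGM interval on the log₂ scale, keeping the two intervals
  consistent. Dialect `bcpnn-approx` is the Bate-style posterior-moment
  approximation with uniform-information priors (α₁ = β₁ = 1,
  α = β = 2, γ₁₁ = 1). The dialect in use is recorded in the output
  metadata and the methods-echo file. Published IC025 values in this
  literature are reproducible by neither formula exactly, so neither
  claims to.
* **Ranking** pools ROR-positive PTs only (published top-30 tables
  contain only ROR-positive rows). Frequency mode sorts by case count,
  ties by ROR then PT name; strength mode by ROR, ties by count then PT
  name — fully deterministic.
* Display rounding is half-even at 2 decimals; computation is full
  double precision. Exports serialize at 4 decimals.

## Time to onset

Induction time is event date minus the earliest therapy-start date of
the matched target drug, in whole days. Records are per (report, PT) —
a report with three reactions contributes three records with equal days
— because per-SOC event counts exceed the number of dated reports in
this kind of data, implying per-event counting. Candidates are excluded,
with counted reasons, when either date is missing, when both dates were
month-imputed (the interval would be an artifact of the day-15
convention), or when the difference is negative. Histogram bins are
inclusive integer-day intervals 0–30, 31–60, 61–90, 91–180, 181–360,
>360. Per-SOC medians and quartiles default to linear interpolation
(type 7); a `spss` option selects the weighted-average rule (type 6)
used by common commercial software, since the two differ at small n.

## Synthetic corpus

The generator emulates the structural nuisances of a real extract while
keeping every analyzed reporting rate analytic:

* Reports are independent and single-drug; each draws a drug from a
  five-drug vocabulary (target drug marginal 0.10, half of those under
  the brand name with the generic in `prod_ai`). Target-drug reports
  draw an indication (whitelisted 0.80, ambiguous 0.10, other 0.10) and
  role codes per configuration (default all primary-suspect);
  background reports draw non-whitelisted indications.
* Each of 12 analyzed PTs enters a report independently with its base
  rate (0.01–0.08); an injected (drug, indication, reaction) triple
  multiplies that PT's rate by the configured ratio for matching
  reports. The default spec injects one pair at rate ratio 5 on a
  base-0.01 PT, leaving a same-rate PT as a matched null. Every report
  additionally draws exactly one "primary complaint" PT from a disjoint
  vocabulary with identical distribution in both arms — reports without
  reactions do not occur in real data — which leaves the analyzed PTs'
  rates untouched.
* Structural noise: ~10% multi-version cases (earlier version with
  smaller PRIMARYID and earlier-or-equal receipt date, occasionally
  tied to exercise the tie-break), 2% deleted cases (listed only in
  post-2019Q1 quarters), and missingness mirroring large published
  cohorts: weight 82%, age 51%, event date 40%, therapy start 45%,
  route 65%.
* Onset days for target-drug reports are log-normal (median 21 days,
  log-scale σ 1.1, matching the early-onset pattern of checkpoint-
  inhibitor toxicity); therapy start is back-computed so event ≤ receipt.
* Randomness is seeded per quarter from (seed, quarter index):
  quarters regenerate independently and a fixed seed is byte-identical.

Default problem sizes: 10,000 reports over four quarters (2021Q1–Q4), a
post-approval window scaled down from the nine-year span a production
analysis would load; at these sizes the injected pair yields a ≈ 39
cohort cases, enough that the a ≥ 20 regime of the recovery tests is
comfortably reached. The replicate calibration in the test suite uses
200 seeds; the analysis script version uses 50.

**What passing tests do not show.** The generator's reports are
independent with a single suspect drug and exact per-PT rates, so
recovery results say nothing about confounding by co-medication,
duplicate reports under *different* CASEIDs, drug-name free-text noise
beyond the brand synonym, reporting-rate drift over calendar time, or
masking effects from competing signals — all present in real FAERS data.
The deduplication, parsing, and statistical machinery are exercised
faithfully; the epidemiological caveats of disproportionality analysis
(no denominators, reporting bias, no causality) apply unchanged.

## Degenerate inputs and edge policies

Empty cohort aborts with per-filter removal counts. Empty background
yields all-undefined statistics, flagged accordingly. PTs absent from
the user-supplied PT→SOC mapping map to the fallback SOC "Unmapped"
(warned once per distinct term). SOCs with fewer than 3 onset records
are flagged low-n rather than suppressed. Orphan satellite rows
(PRIMARYID absent from DEMO) are dropped at read time with a warning.
Figure rendering is optional and never feeds back into any computed
value.
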
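# Methods

## Setting and model

Spontaneous reporting systems (SRS) such as FAERS collect case safety
reports: a patient, one or more drugs (each with a reporter-assigned role
code; "primary suspect" marks the drug judged responsible), and one or
more adverse events coded as MedDRA Preferred Terms (PTs).  Signal
detection asks whether a drug-event pair is reported *disproportionately*
often relative to the rest of the database.  For a pair, the database
collapses to the 2x2 table

|                        | event | other events |
|------------------------|-------|--------------|
| drug primary suspect   | a     | b            |
| all other reports      | c     | d            |

with N = a+b+c+d.  The counting unit is the deduplicated report: a report
listing the PT twice counts once, and every submitted report is an
independent instance ("person-times") even when one patient appears in
several reports.  A pair-level counting variant (units = distinct
report-PT pairs) is available behind `counting_unit="pair"` for
sensitivity analysis.

## Indices and positivity rule

* **ROR** = ad/bc, 95% interval `exp(ln ROR ± 1.96·s)` with
  `s = sqrt(1/a+1/b+1/c+1/d)`.  Positive when the lower bound exceeds 1
  and a ≥ 3.
* **PRR** = [a/(a+b)] / [c/(c+d)], paired with the Pearson chi-square of
  the table computed from the margins without Yates continuity correction
  (the common PRR convention; a corrected variant is not offered because
  the uncorrected form is what the positivity thresholds PRR ≥ 2,
  chi-square ≥ 4, a ≥ 3 were calibrated against).
* **BCPNN information component**.  Point value: the plug-in
  IC = log2[aN/((a+b)(a+c))]; the closed-form posterior expectation E(IC)
  is available as a variant and is substituted automatically at a = 0
  where the plug-in is undefined.  The lower credibility bound is always
  the closed form IC025 = E(IC) − 2·sqrt(V(IC)) under the standard unit
  priors (gamma11 = alpha1 = beta1 = 1, alpha = beta = 2), so it is finite
  (and negative) even for a = 0.  Positive when IC025 > 0.
* **MGPS**.  The default is the *simplified* variant: point value equal to
  the relative reporting ratio EBGM = aN/((a+b)(a+c)) and
  EB05 = exp(ln EBGM − 1.645·s).  The choice is deliberate: published
  result sets in this field print EBGM values that coincide with the
  relative reporting ratio (EBGM ≈ PRR for rare-exposure tables), and the
  EB05 reconstruction check below is consistent with this variant.  The
  full DuMouchel gamma-Poisson shrinker is implemented and
  configuration-selected (`mgps="full"`): a two-component gamma mixture
  prior on the reporting-rate ratio lambda, fitted by maximizing the
  negative-binomial marginal likelihood over all cells (L-BFGS-B on
  log/logit-transformed hyperparameters from the conventional start
  (0.2, 0.1, 2.0, 4.0, 1/3)); per table the posterior is again a gamma
  mixture, EBGM = 2^E[log2 lambda | a] via the digamma closed form, and
  EB05 is the exact posterior 5th percentile by bracketed root-finding on
  the mixture CDF.  Positive when EB05 > 2.

A pair is a final signal only when **all four** indices are positive.  No
multiple-comparison adjustment is applied across PTs, matching standard
practice for these thresholds.

Zero cells make ROR and the simplified EB05 undefined; the default is an
explicit error carrying the offending cell, with a uniform Haldane +0.5
correction opt-in.  In bulk scoring, undefined estimates become NaN and
the pair simply cannot be positive.  Scoring covers pairs with a ≥ 1;
a = 0 rows appear only in the full export.

## Screening and follow-up analyses

**IME filter.**  Signals are intersected with an Important Medical Event
term list supplied as plain text (one PT per line, `#` comments).  The
MedDRA IME list itself is licensed and not bundled.  Matching is
case-insensitive on whitespace-collapsed terms.

**Subgroups.**  Within the target-drug reports, each PT is contrasted
between two strata with a 2x2 table (group x event), a between-group odds
ratio (Haldane-corrected only when a zero cell occurs) and a two-sided
Fisher exact p-value.  The Fisher p is the exact enumeration sum of all
hypergeometric tables whose point probability does not exceed the observed
one; the implementation works in integer arithmetic (binomial-coefficient
numerators over a common denominator), so ties are compared exactly and no
floating-point tie tolerance is needed.  Strata conventions: age [18, 45)
vs [45, inf) with under-18 and age-missing reports excluded (the half-open
convention resolves the boundary ambiguity of "18 to 45 / >= 45" phrasing
and is recorded in the output labels); treatment duration
(therapy end − start of the primary-suspect mention) [0, 180] vs
(180, inf) days, missing durations excluded; indication matched against a
configurable term set (default "malignant hyperthermia"), reports without
a recorded indication excluded.  The subgroup denominators are reports,
mirroring the main analysis; this choice is visible in the output tables.

**Time-to-onset.**  Latency = event onset date − therapy start date of the
primary-suspect mention, in whole days.  Dates are parsed as YYYYMMDD with
YYYYMM/YYYY accepted at month/year precision; day arithmetic treats
lower-precision dates as missing, so such mentions land in the missing
count rather than producing spurious latencies.  Negative latencies are
dropped and counted separately.  Bins are closed-open [lo, hi) with an
open-ended terminal bin; defaults 0-30 / 31-60 / 61-90 / 91-120 / 121-180
/ >180 days, plus a convenience two-bin split at 100 days.

**Case-by-case extraction** lists the complete records (demographics,
outcomes, all PTs) of reports whose target-drug mention carries a given
indication.

## Ingestion and deduplication

Two dialects: FAERS-style "$"-delimited quarterly tables (DEMO/DRUG/REAC
plus optional OUTC/THER/INDI, joined on the report identifier and drug
sequence number) and a flat generic CSV (one row per report-drug-event
triple) that doubles as the package's lossless interchange format.  Field
parsing never aborts ingestion: malformed dates, ages, or codes become
missing values recorded in a parse log.  Age unit codes are converted to
years (DEC/MON/WK/DY/HR); an unknown unit yields missing.  Drug names are
normalized by lower-casing, whitespace collapsing and stripping trailing
salt words from a configurable suffix list; synonym pooling (brand names)
is an explicit user-editable set.  Deduplication keeps, per case
identifier, the record with the latest version date, breaking exact ties
by the lexicographically greatest report id — deterministic and faithful
to the "latest version of the case" intent.  CSV extracts without a
version structure treat each row as its own case.  In the demographic
summary each report contributes its single most severe outcome (ordered
death > life-threatening > hospitalization > disability >
congenital-anomaly > other-serious > not-serious) so the outcome column
partitions the total.

## Synthetic-database generator

The generator plants known drug-event relative risks over an independence
background so every stage is testable without external data.  Per base
report: drugs present independently with their marginal probabilities;
event e included with probability `min(1, baseline_e · max_d RR(d, e))`,
the maximum over the report's drugs (maximum rather than product keeps the
per-event probability interpretable and bounded); empty reports are
redrawn until at least one event is present.  Drug mentions are primary
suspect with probability 0.9, else concomitant.  Onset dates are therapy
start plus a log-normal latency (median 20 days, log-sd 1.5), which
reproduces the bimodal early (0-30 d) / late (>180 d) onset mass typical
of acute-use drugs with delayed sequelae; treatment duration is log-normal
(median 30 d, log-sd 1.2).  Demographics (sex, banded age and weight,
country, reporter, outcome, indication of the target drug) are categorical
draws with explicit missingness masses approximating the adult,
male-predominant, weight-rarely-recorded profile of hospital-administered
muscle-relaxant reports.  A configurable fraction of reports (default
10%) is re-emitted as a duplicate case version 1-400 days later,
exercising the deduplication rule.  All randomness flows from a single
seeded generator; identical configuration and seed give byte-identical
interchange output.

The reference study conditions are a target drug with marginal 1e-3, one
pair planted at RR 30 onto an event with baseline 2e-3, and n = 200,000
reports — a rare drug and a rare event inside a desk-scale database.
Under these conditions the combined rule recovers the planted pair in
19/20 seeds, the 95% ROR interval covers the true RR in 16/20 (ROR
estimates the odds ratio, which slightly exceeds the planted risk ratio at
a 6% event probability, so coverage sits at rather than above its
binomial-slack floor), and with nothing planted fewer than 0.1% of the 300
vocabulary pairs fire.  What passing these tests does *not* show: the
generator draws drugs independently and events conditionally independent
given the drugs, so it cannot expose confounding by co-medication,
masking/competition bias, duplicate reports that are not exact clones, or
reporting waves — all present in real SRS data.

## Reconstructing a table from published statistics

Published result sets often print only ROR with its interval.  Given the
database size N, the interval width fixes s = sqrt(1/a+1/b+1/c+1/d), and
for each candidate a the pair (b, c) solves a quadratic (the two roots are
transposes with identical observed/expected statistics).  ROR and interval
alone leave a weakly identified — a whole range of a admits near-exact
integer solutions — so `reconstruct_contingency` optionally takes the
published PRR, whose ratio to the ROR (~ b/(a+b)) pins the case count.
With the published respiratory-failure values (ROR 29.33, CI 20.25-42.48,
PRR 28.35, N = 18,182,912) the search lands on (29, 839, 21415, 18160629),
whose simplified EB05 of 20.76 agrees with the published 20.79 to 0.15% —
the consistency check that motivates the simplified MGPS default.

## Numerical choices

* Exact integer arithmetic for Fisher enumeration (cached per margin
  triple); p-values are capped at 1.
* Negative-binomial log-pmf and log-sum-exp for the mixture marginal;
  hyperparameters optimized on log/logit scale, so positivity constraints
  are implicit.  The fit requires at least 100 cells and errors (with the
  objective trace) if the likelihood cannot be improved.
* Posterior 5th percentiles by Brent root-finding on the monotone mixture
  CDF with geometric bracket expansion.
* Interval z-quantiles from the normal distribution at the configured
  confidence level (default 0.95).
* Percentages are reported to one decimal; per category they sum to
  100 ± 0.5 by rounding.

## Problem sizes in the shipped checks

The test suite and the acceptance script regenerate everything they
measure: unit tests use databases of 100-4,000 reports; the calibration
study uses 20 + 10 seeds (tests) or 10 + 5 seeds (acceptance script) at
n = 200,000 reports with the reference vocabulary (10 drugs x 30 PTs);
prior recovery uses 50,000 simulated cells; the Fisher cross-check sweeps
every 2x2 table with N <= 60 (635,376 tables).

## Known limitations

* No MedDRA hierarchy: analysis is strictly at PT level; SOC roll-ups are
  out of scope, and PT matching is exact (after normalization), with no
  synonym expansion across PTs.
* The full-MGPS prior is fitted on the scored vocabulary's cells; for very
  small vocabularies the mixture is weakly identified (the simplified
  variant is unaffected).
* FAERS onset dates live on the DEMO record, so all events of a report
  share one onset date in that dialect.
* The generator does not fit real FAERS marginals; its defaults are
  field-plausible, not estimated.
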
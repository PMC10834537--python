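# Methods

## Counting units and table semantics

All three screens reduce to 2×2 tables with one fixed semantics: `a` =
units with the drug of interest and the event of interest, `b` = units
with the drug but not the event, `c` = units with the event on other
drugs, `d` = the remainder. The *unit* differs per source:

* registry: the follow-up **case** — one follow-up interval of one patient
  who continued the same agent. Follow-up events are treated as independent
  cases; no within-patient correlation is modelled, because the screen's
  own counting unit is the case. Only reports with relatedness *related*
  or *indeterminate* contribute terms; severity and outcome are ignored.
* SRS: the distinct **report**. A report with k drugs and m events
  contributes to all k×m pairs; duplicate (report, drug, event) rows
  collapse before counting. Marginals and FDR ranking are computed over
  the whole observed pair universe — disproportionality marginals are
  global by definition — and candidate pairs are looked up afterwards.
* laboratory screen: the **patient**, classified by whether any
  measurement in the assessment window is abnormal in the signal's
  direction.

## Statistics

Registry and laboratory screens use the risk ratio
`RR = (a/(a+b))/(c/(c+d))` with the Katz log-normal interval
`exp(ln RR ± z_{1−α/2}·sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)))`. Zero-cell
conventions: RR = 0 when a = 0 and c > 0; RR missing when c = 0; the CI is
missing whenever a = 0 or c = 0. No continuity correction is applied here —
undefined intervals are reported as missing rather than invented.

The registry significance rule is RR > 1 **and** CI lower bound > 1,
evaluated on unrounded values. A `point_estimate_only` switch reproduces
the literal RR > 1 rule for users who want the point-estimate-only
convention; the CI-based rule is the default because a point estimate
above 1 alone is not evidence. Pairs with `a` below `min_count` (default
3) are not reported.

The SRS screen computes `PRR`, `ROR` and the BCPNN information component
`IC = log2(a·n/((a+c)(a+b)))`. When any cell is zero, 0.5 is added to all
four cells for point estimates and Wald variances (Haldane–Anscombe),
and the row is flagged `corrected`. On zero-free tables the three
statistics are sign-coherent: `a·n − (a+b)(a+c) = ad − bc`, so
PRR > 1 ⇔ ROR > 1 ⇔ IC > 0 ⇔ ad > bc — which is why frequentist PRR and
ROR decisions coincide pair-by-pair.

### FDR decisions

* PRR / ROR: one-sided Wald p-values on the log scale
  (`se_logPRR = sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d))`,
  `se_logROR = sqrt(1/a + 1/b + 1/c + 1/d)`), Benjamini–Hochberg adjusted
  across all pairs.
* IC: the posterior probability P(IC ≤ 0 | data) under a joint
  Dirichlet(a+1, b+1, c+1, d+1) posterior on the four cell probabilities,
  estimated by Monte Carlo (default 10,000 draws; below 1,000 a warning is
  logged but the value is still computed). The Bayesian FDR at rank i is
  the cumulative mean of the ascending-sorted posterior null
  probabilities, a non-decreasing sequence by construction.
* decision: any of the three FDRs below the threshold (default 0.05).

**Calibration caveat.** The Bayesian cumulative-mean rule inherits the
flat Dirichlet prior, which places roughly half its mass on IC > 0 — i.e.
it implicitly assumes a large prior signal fraction. Under a *global*
null with moderate counts the posterior null probabilities are
approximately uniform and the rule flags on the order of 10% of pairs; it
is deliberately the most liberal of the three (consistent with IC-based
flags forming a superset of PRR/ROR flags). It carries no frequentist
type-I guarantee and the calibration tests therefore assert the nominal
level only for the BH-adjusted PRR/ROR decisions; the IC rule's null flag
rate is reported as a measured quantity.

The Wald/Katz interval itself is anti-conservative at small counts: the
estimated standard error shrinks exactly when the estimate fluctuates
upward, so with expected cell counts near 20 the one-sided 0.025 rule
rejects at ≈0.030, approaching 0.025 only slowly as counts grow. Null
calibration is therefore assessed in the Wald-validity regime (expected
`a` around 60); small-count screens should be read with this bias in
mind, or gated by a higher `min_count`.

### Laboratory screen

Direction predicates use strict inequalities — a value exactly at a
reference limit is normal — and `outside_range` is exactly the union of
the two one-sided predicates. Exposed patients are assessed in a window
of 365 days (default) after first exposure; unexposed patients over their
whole observation span, so enlarging a window can only add abnormal
findings. The comparator group is patients on other catalogued drugs
(mirroring the registry's "other drugs" semantics); `all_others` is
available. p-values are two-sided Pearson chi-square, switching to
Fisher's exact test when any expected cell is below 5. A normal
pre-exposure baseline is *not* required; this is a documented extension
point. Laboratory evidence annotates final signals but does not gate
them — final selection is the registry ∩ SRS intersection alone.

### Label exclusion and final selection

The label knowledge base is a user-supplied TSV of known (generic drug,
preferred term) pairs; matching is exact on the normalised vocabulary and
disease-agnostic. Final signals are the novel candidates confirmed in the
SRS, merged across strata; a pair novel in both strata appears once with
both strata recorded, leaving any disease-specific interpretation to the
user.

## Synthetic data

The generators emulate the statistical structure the screens assume, not
real pharmacoepidemiology. One master seed feeds labelled child
generators (CRC-32 of the module label mixed into the bit generator
seed), so registry, SRS and EHR sources regenerate independently and
byte-identically.

* **Registry.** Default cohort sizes follow the emulated study flow: 2279
  RA and 1940 AS patients, withdrawal fractions 0.034 / 0.027, about three
  yearly follow-ups per non-withdrawn patient (Poisson), and follow-up
  drug statuses with continued fractions 0.575 / 0.755. Each follow-up
  case samples, per term, an independent related-or-indeterminate report
  stream at rate β·q (β = baseline term probability, default 0.01; q =
  P(related or indeterminate), default 0.7) and an unrelated stream at
  β·(1−q). An embedded (disease, drug, term, ρ) multiplies only the
  related-or-indeterminate stream by ρ, so the post-filter risk ratio
  converges to ρ exactly and the relatedness filter has real work to do.
  The visit process (fixed yearly visits, i.i.d. statuses) is an
  assumption; switching histories are not modelled beyond the status
  label, which is all the screen consumes.
* **SRS.** Each report draws one primary drug from the drug marginals
  (second drug with probability 0.1) and each event independently at its
  marginal rate, tilted by ρ for embedded pairs conditional on the
  report's drugs; a report that would carry no event draws one from its
  tilted distribution. Marginals are expected mentions per report and
  must sum to 1. Brand names substitute generics at a configurable
  fraction so the normalisation tables are exercised. Duplicate-report
  simulation and real SRS dialects are out of scope.
* **EHR laboratory.** Every patient gets one catalogued drug exposure and
  a fixed number of measurements per test over a span around the start
  day; values are uniform inside the reference range, with a background
  abnormality probability per measurement (random side). Embedded
  (drug, signal) pairs force, with the stated per-patient probability, one
  post-exposure measurement outside the range in the signal's direction,
  uniformly timed within the exposure window (timing is an assumption).
  The shipped demo catalog has 102 signals partitioned 38 above-upper /
  39 below-lower / 25 outside-range.

What passing tests on these generators show: the screens recover exactly
the associations put in, at the rates theory predicts, under independent
sampling. What they do not show: robustness to confounding, channeling,
time-varying hazards, duplicate reports or vocabulary noise — none of
which the generators emulate.

## The demo study

The demo ground truth is built by set arithmetic, not by tuning: 51 RA
and 36 AS embedded registry pairs (risk ratio 30), of which 16 / 10 are
label-known, leaving 35 / 26 novel candidates; 14 distinct pairs carry
SRS signals (rate ratio 25) — 8 RA-only, 1 AS-only and 5 shared between
strata — so 13 RA and 6 AS candidates are SRS-confirmed and the merged
final set has 14 members. Two (drug, laboratory-signal) pairs are
embedded in the EHR source as corroborating evidence. The fixture is
sized so the stage counts are structurally forced for any seed: embedded
pairs sit far inside the detection region (per-pair miss probability
below 1e−6), background pairs cannot reach the demo's `min_count` of 15
(baseline related-report counts of ≈2–3 per pair), and the terms of
unconfirmed candidates are absent from the SRS event vocabulary, so those
pairs are annotated "absent" — mirroring the NA rows real cross-database
validation produces.

## Problem sizes used in checks

Simulation-based checks run at the smallest sizes at which the asserted
property is in its asymptotic regime: null calibration over 20 seeds ×
300 registry pairs (5,000 patients, baseline 0.10) and 20 seeds × ~500
SRS pairs (1,500 reports, 20×25 vocabulary); recovery over 20 seeds with
risk ratio 3 at 20,000+ cases and rate ratio 5 at 50,000 reports; oracle
agreement on 1,000 random tables at 1e−12; the sign-coherence identity on
10,000 random tables. IC Monte-Carlo uses 2,000–10,000 draws in screens
and 100,000 where seed-to-seed stability (<0.01) is asserted.

## Known limitations

* Exact-term matching only; no MedDRA hierarchy or synonym expansion.
* The Wald-based intervals and p-values are anti-conservative at small
  counts (see above); exact alternatives are not implemented.
* The IC decision rule is liberal by construction under sparse-signal
  truth (see the calibration caveat).
* The laboratory screen has no baseline-normality requirement and no
  dose/duration adjustment; the registry screen ignores severity,
  outcome, concomitant therapy and exposure time.
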
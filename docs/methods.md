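# Methods

## Analysis model

`persistkit` treats a claims extract as four tables — enrollment,
diagnoses, drug claims, costs — and computes drug survival and cost windows
for biologic therapy (BT) in psoriasis. All dates are integer day offsets
from a fixed origin (2010-01-01 on disk, where they appear as ISO-8601
dates); "12 months" is 365 days and "24 months" 730 days throughout.

### Units and cohort selection

The analysis unit is a (patient, biologic) pair, not a patient: a patient
who received two biologics contributes two units, each with its own index
date (the first claim of that drug). This matches how drug-survival studies
count "patients per treatment group" when groups are not mutually
exclusive. ICD-10 matching is by code prefix ("L40" matches "L40.5").
Exclusion and comorbidity code sets ship as editable defaults
(`CodePolicy`): the named exclusion diseases map to conventional blocks
(M05–M06, K50–K51, M45, M08) because authoritative code lists for the
original analysis are not public; users with their own lists override them.

A unit is BT-naïve when no biologic claim of any class falls in
`[index−365, index−1]`. A unit whose pre-index enrollment is shorter than
365 days cannot be *proven* naïve; by default it is classed experienced
(`unknown_is_naive=True` flips this). Rationale: a look-back that cannot be
observed should not assert a negative.

### Episode construction

The discontinuation rule is the refill-gap convention: per drug, a
*treatment interval* (30 d ADL/IFX/SCK, 90 d UST — the scheduled spacing of
administrations) plus a *medication gap* (60 d base case) defines the
non-refill period (90/90/90/150 d). Scanning successive index-drug claims,
the first of these ends the episode:

* **gap** — the span to the next index-drug claim (or to the end of
  observation) exceeds the non-refill period. The event day is
  `last claim + treatment interval`: the end of *supplied* therapy. The
  alternatives (last claim date; end of the gap window) either undercount
  supplied therapy or make the event time move with the gap parameter; the
  chosen convention does neither, and it makes sensitivity analyses vary
  only *which* units discontinue, not *when*.
* **switch** — a different biologic is claimed before the index drug's next
  claim and no later than `last claim + non-refill period` (after that the
  gap is already provable and wins). A different biologic claimed on the
  same day as an index-drug claim counts as a switch by default
  (`switch_on_same_day=False` reverses the tie-break). "Other treatment"
  means other biologics only: non-biologic systemics are not classified in
  the data model.
* **censoring** — observation ends while the remaining claim-free window is
  shorter than the non-refill period.

Binary 12-month persistence (no event before day 365) is only defined for
units with ≥365 days of post-index observation; an event at exactly day 365
counts as persistent. The medication-gap sensitivity grid re-runs the
binary analysis under alternative gaps (defaults 30 and 90 days around the
60-day base case); persistence is provably non-decreasing in the gap.

### Survival estimation and tests

Kaplan-Meier estimation, Greenwood variance and the two-sample tests are
implemented from first principles (they are the package's analytical core;
`lifelines` appears only in the test suite as an independent oracle).
Conventions: ties between events and censorings at the same day are
resolved events-first; confidence bands are plain-scale symmetric
`S ± 1.96·SE`, clipped to [0, 1], because persistence rates are
conventionally reported as "rate ± half-width" (a log-log band is available
via `ci_scale="loglog"`); where some event time exhausts the risk set the
Greenwood term is undefined and the band is flagged unavailable from that
time on rather than extrapolated. "Wilcoxon" in the survival setting is the
Gehan-Breslow test (weights = total at risk), the standard reading for
censored persistence comparisons. Pairwise drug comparisons against a
reference (UST by default) are reported unadjusted, as is conventional for
descriptive drug-survival tables.

### Cost windows

Pre window `[index−365, index−1]`, post window `[index, index+364]`; the
index day belongs to the post window because the first administration is a
post-initiation cost. IP and OP sums include biologic drug costs (billed
wherever administered); RX counts only non-biologic pharmacy records,
identified by the `is_bt_drug_cost` flag (a code-list adapter is the
intended route for real extracts that lack such a flag). Amounts are stored
in JPY and rounded to thousand JPY only at report time. Group means are
unweighted across units; the contrast table reports non-persistent minus
persistent deltas.

## Synthetic data generator

The generator emulates the observed study conditions of a Japanese
employer-insurance psoriasis cohort. Defaults: drug mix 20.5/25.4/10.2/43.9%
(ADL/IFX/SCK/UST), naïve fraction 0.863, female fraction 18.1%, mean age
47.1 (SD 11, clipped to 18–74 — employer-insurance databases skew young),
comorbidity prevalences from the corresponding published prevalence table,
and per-30-day discontinuation hazards back-solved from published naïve
12-month persistence rates via `h = 1 − S₁₂^{1/12}`: ADL 0.061, IFX 0.052,
SCK 0.048, UST 0.019.

Discontinuation is geometric on the 30-day cycle grid: after each
administration the patient continues with probability
`(1−h)^{interval/30}`, so 12-month survival is exactly `(1−h)¹²` for every
dosing interval. The true discontinuation day is the last administration;
the corresponding detectable event time is one treatment interval later,
which is what the episode builder recovers exactly when no switching occurs
(a tested invariant). A discontinuation is a switch with probability 0.3,
in which case the replacement biologic starts one dosing interval after the
last index-drug claim and runs, undisturbed, to the end of observation.
Experienced patients receive a single "prior biologic" administration 30–300
days before the index date. Ground truth labels each unit's `role`
(`index` / `prior` / `switch`) so validation can target the units governed
by the geometric model.

Costs: monthly gamma draws per category (dispersion = variance/mean²),
anchored to the index day so each 12-month window contains exactly 12
emissions, with separate pre- and post-index parameter sets; each biologic
administration additionally emits a drug-cost record (defaults 110–570
thousand JPY per administration, chosen to reproduce the magnitude of
published annual OP cost increases given each drug's dosing frequency).
Enrollment spans 1095 days with the index drawn uniformly on days 365–795,
so most but not all units qualify for the 24-month cost population.

**What the generator does not model** — and hence what passing tests do not
establish about real claims: dose titration and weight-based dosing,
stockpiling and early refills, re-initiation of a discontinued drug,
time-varying hazards (real drug survival has a steep first-year drop),
seasonality, price schedules, correlated comorbidity–cost structure, and
informative censoring (enrollment ends independently of therapy). The
prior-biologic stub is a single claim, so a "prior" unit's detected episode
is an artifact of the stub, not of the geometric model.

## Validation choices and problem sizes

* Episode construction is checked for exact agreement (status and event
  day) against an independent brute-force day-by-day coverage scan on
  1,000 randomized claim sequences per drug, plus a derandomized
  property-based sweep.
* KM correctness: exact hand-computed product-limit values; exact equality
  with the empirical survival function on 100 fully-observed random
  samples; numerical agreement with `lifelines` on censored samples.
* Log-rank calibration: 500 equal-hazard replicates with 100 units per
  group; the empirical type-I error at α = 0.05 must lie within 3 binomial
  standard errors of 0.05.
* Parameter recovery: 2,000 single-drug units per biologic under the
  calibrated hazards; the KM 12-month estimate must lie within 3 Greenwood
  standard errors of `(1−h)¹²` (≈ 79.4% for UST's h = 0.019).
* Published-table fixtures: the bundled printed cost tables must satisfy
  every internal arithmetic identity (component sums vs totals to ±1
  thousand JPY of rounding; post = pre + increase; deltas = group-mean
  differences; group sizes partition strata).

## Known limitations

The pipeline classifies switches only between the four modelled biologics;
broadening "other treatment" requires extending the drug-claim
classification. The omnibus multi-group persistence test is not
implemented — comparisons are pairwise against a reference. Episode
construction is O(patients × claims) via per-unit table filtering, adequate
for cohorts up to ~10⁵ units but not optimized beyond that.
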
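# persistkit

Medication-persistence and medical-cost analysis of biologic therapies from
insurance-claims data, with a seeded synthetic claims generator for
validation.

Claims databases record drug dispensations, not treatment decisions, so
*drug survival* — how long patients stay on a therapy — must be inferred
from refill timing. `persistkit` implements the standard
pharmacoepidemiology workflow for biologic therapies (BTs) in psoriasis:
adalimumab (ADL), infliximab (IFX), secukinumab (SCK) and ustekinumab
(UST), as studied in Japanese employer-insurance claims. It is aimed at
health-economics and outcomes researchers who need the whole chain —
cohort selection, treatment-episode construction, survival estimation and
pre/post cost accounting — as tested, reusable functions rather than
one-off SQL and SAS scripts.

## What it computes

**Cohort construction.** Patients with an ICD-10 L40 (psoriasis) diagnosis
and at least one BT claim, minus patients with rheumatoid arthritis,
inflammatory bowel disease, ankylosing spondylitis or juvenile arthritis
(configurable code prefixes). Each patient contributes one analysis unit per
biologic received; the index date is the first claim of that biologic, and a
unit is *BT-naïve* when no biologic of any class was claimed in the prior
365 days.

**Treatment episodes.** A unit discontinues at the first of: (1) a claim-free
span exceeding the *non-refill period* — treatment interval + medication gap,
i.e. 30 + 60 = 90 days for ADL/IFX/SCK and 90 + 60 = 150 days for UST —
with the event dated at the end of supplied therapy (last claim + treatment
interval); or (2) a *switch*, a claim of a different biologic before the
next index-drug claim and before a gap is provable. Otherwise the episode is
censored at the end of enrollment.

**Survival.** Kaplan-Meier product-limit persistence
`S(t) = Π (1 − d_i/n_i)` with Greenwood variance
`S² Σ d_i / (n_i (n_i − d_i))` and plain-scale 95% bands, flagged
unavailable where the variance is undefined; two-sample log-rank and
Gehan-Breslow Wilcoxon tests, and pairwise comparisons against a reference
drug.

**Costs.** For units observable 12 months on both sides of the index date:
inpatient (IP), outpatient (OP — both including BT drug costs) and
non-biologic pharmacy (RX) sums for the pre-window `[index−365, index−1]`
and post-window `[index, index+364]`, with persistent vs non-persistent
contrasts of the pre-to-post cost increase.

**Synthetic claims.** A seeded generator emulating the four-table claims
extract with geometric per-30-day discontinuation hazards, switching,
comorbidity prevalences and gamma-distributed monthly costs, plus per-unit
ground truth, so every stage is testable without access to proprietary data.

## Worked example

Episode construction on three hand-written claim histories
(`examples/02_build_episodes.py`):

```
             unit_id              status  end_day  persistent_12m
     gap_patient:ADL    gap_discontinued       90           False
  switch_patient:ADL switch_discontinued       45           False
censored_patient:UST            censored      420            True
```

The ADL patient claimed on days 0/30/60 and never again: the 340 claim-free
days exceed the 90-day non-refill period, so the episode ends at day
60 + 30 = 90, when supplied therapy ran out. The switch patient claimed UST
on day 45, ending the ADL episode that day. The UST patient's observation
ends 60 days after the last quarterly claim — too short to prove a 150-day
gap — so the episode is censored, and with 420 event-free days the unit
counts as 12-month persistent.

Survival analysis on a simulated 400-patient cohort under the calibrated
default hazards (`examples/03_survival_analysis.py`):

```
ADL: 12-month persistence 47.0% +/- 10.0%  (n=102)
IFX: 12-month persistence 47.3% +/- 8.8%  (n=129)
SCK: 12-month persistence 50.8% +/- 11.6%  (n=79)
UST: 12-month persistence 80.0% +/- 5.8%  (n=195)

pairwise tests versus UST:
  ADL vs UST, log-rank: p = 7e-13
  ...
```

UST's quarterly dosing and low per-cycle hazard give it the highest drug
survival; the pairwise tests separate it sharply from the monthly biologics.

The same analyses run from the shell:

```bash
persistkit simulate --config cfg.yaml --out claims/
persistkit run --config cfg.yaml --in claims/ --out results/
persistkit sensitivity --config cfg.yaml --in claims/ --out grid.csv
```

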
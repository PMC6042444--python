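"""Kaplan-Meier persistence curves and drug comparisons on simulated claims.

Builds episodes for a simulated cohort under the calibrated default hazards,
estimates per-drug 12-month persistence with Greenwood confidence bands, and
tests each biologic against ustekinumab (the high-persistence reference)
with the log-rank and Gehan-Wilcoxon tests.
"""
from persistkit import (
    GapPolicy,
    SimulationConfig,
    build_episodes,
    build_patient_units,
    generate_cohort,
    km_estimate,
    pairwise_vs_reference,
    survival_at,
)

bundle, _ = generate_cohort(SimulationConfig(n_patients=400, seed=7))
units = build_patient_units(set(bundle.enrollment.patient_id), bundle)
episodes = build_episodes(units, bundle.drug_claims, GapPolicy())

samples = {}
for drug, grp in episodes.groupby("drug"):
    t = grp["end_day"].to_numpy(float)
    e = (grp["status"] != "censored").to_numpy()
    samples[drug] = (t, e)
    est, ci = km_estimate(t, e), None
    rate, band = survival_at(est, 365)
    band_txt = f"+/- {100 * (band[1] - band[0]) / 2:.1f}%" if band else "(CI not available)"
    print(f"{drug}: 12-month persistence {100 * rate:.1f}% {band_txt}  (n={len(t)})")

print("\npairwise tests versus UST:")
for row in pairwise_vs_reference(samples, "UST"):
    print(f"  {row['group']} vs UST, {row['test']}: p = {row['p_value']:.2g}")
# Drugs with higher discontinuation hazards separate sharply from UST;
# p-values are unadjusted, mirroring how such pairwise drug-survival
# comparisons are conventionally reported.
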
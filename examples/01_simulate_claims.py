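"""Simulate a claims bundle and inspect its ground truth.

Generates a seeded synthetic cohort shaped like an employer-insurance claims
extract (enrollment, diagnoses, biologic drug claims, monthly costs) and
writes it as four CSVs.  The ground truth records, per (patient, drug) unit,
the true discontinuation day and cause — the quantities the downstream
refill-gap algorithm must recover.
"""
from persistkit import SimulationConfig, generate_cohort, write_bundle

config = SimulationConfig(n_patients=100, seed=42)
bundle, truth = generate_cohort(config)
write_bundle(bundle, "scratch/example_claims")

print("table sizes:", {name: len(df) for name, df in bundle.tables().items()})
index_units = truth.units[truth.units.role == "index"]
print(f"{len(truth.units)} simulated units, {len(index_units)} index units")
print("true discontinuation causes:")
print(index_units["cause"].value_counts().to_string())
# 'stop' = refill gap, 'switch' = changed biologic, 'none' = still on therapy
# at the end of observation; the mix follows the configured per-drug hazards
# and the 30% switch share among discontinuations.
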
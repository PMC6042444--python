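"""Treatment episodes from refill claims: the gap / switch / censor rules.

Three hand-written claim histories show the three episode endings under the
base policy (treatment interval 30 d for ADL, 90 d for UST; medication gap
60 d, so the non-refill period is 90 d and 150 d respectively).
"""
import pandas as pd

from persistkit import GapPolicy, build_episodes

claims = pd.DataFrame(
    [
        # gap: adalimumab monthly for 3 claims, then nothing until day 400
        *[("gap_patient", d, "BT-ADL", "ADL", "outpatient") for d in (0, 30, 60)],
        # switch: two ADL claims, then ustekinumab on day 45
        ("switch_patient", 0, "BT-ADL", "ADL", "outpatient"),
        ("switch_patient", 30, "BT-ADL", "ADL", "outpatient"),
        ("switch_patient", 45, "BT-UST", "UST", "outpatient"),
        # censored: ustekinumab quarterly to day 360, observation ends day 420
        *[("censored_patient", d, "BT-UST", "UST", "outpatient")
          for d in (0, 90, 180, 270, 360)],
    ],
    columns=["patient_id", "date", "drug_code", "bt_class", "setting"],
)
units = pd.DataFrame([
    {"unit_id": "gap_patient:ADL", "patient_id": "gap_patient", "drug": "ADL",
     "index_day": 0, "obs_start": 0, "obs_end": 400, "age": 50, "sex": "M"},
    {"unit_id": "switch_patient:ADL", "patient_id": "switch_patient", "drug": "ADL",
     "index_day": 0, "obs_start": 0, "obs_end": 400, "age": 45, "sex": "F"},
    {"unit_id": "censored_patient:UST", "patient_id": "censored_patient", "drug": "UST",
     "index_day": 0, "obs_start": 0, "obs_end": 420, "age": 61, "sex": "M"},
])

episodes = build_episodes(units, claims, GapPolicy())
print(episodes[["unit_id", "status", "end_day", "persistent_12m"]].to_string(index=False))
# gap ends at 90 = last claim (60) + treatment interval (30): the end of
# supplied therapy.  The switch ends on the day the new biologic is claimed.
# The UST history is censored: only 60 claim-free days remain at day 420,
# short of the 150-day non-refill period, so no discontinuation is provable.
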
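"""Hand-built panel datasets for unit tests."""

import pandas as pd

from jointmsm.covariates import default_layout
from jointmsm.data import PanelDataset


def make_dataset(times=(0.0, 1.0, 2.0), active_joints=None, damage_at=None,
                 sex=1, age_onset=40.0, entry_duration=2.0, patient_id=1,
                 n_patients=1):
    """One or more patients with 28 joints observed at the given times.

    ``active_joints`` maps joint_id -> activity sequence (one per visit);
    ``damage_at`` maps (joint_id, visit_index) -> 1 to switch damage on from
    that visit onward.  All other joints stay inactive and undamaged.
    """
    layout = default_layout()
    active_joints = active_joints or {}
    damage_at = damage_at or {}
    rows = []
    for p in range(patient_id, patient_id + n_patients):
        for vi, t in enumerate(times, start=1):
            for j in layout.joint_ids:
                act = active_joints.get(j, [0] * len(times))[vi - 1]
                dmg = int(any(v <= vi for (jj, v) in damage_at if jj == j
                              and damage_at[(jj, v)]))
                rows.append((p, vi, t, j, act, dmg))
    joints = pd.DataFrame(rows, columns=["patient_id", "visit_index", "time_years",
                                         "joint_id", "active", "damaged"])
    patients = pd.DataFrame(
        {"patient_id": list(range(patient_id, patient_id + n_patients)),
         "sex": sex, "age_onset": age_onset, "entry_duration": entry_duration})
    return PanelDataset(joints, patients, layout)
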
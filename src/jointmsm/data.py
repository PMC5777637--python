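"""Panel dataset container and long-format CSV input/output.

A :class:`PanelDataset` holds intermittently observed joint states for a
cohort: one row per (patient, visit, joint) with the visit time in years
since the patient's first visit, binary activity and damage indicators, and
per-patient covariates (sex, age at arthritis onset, arthritis duration at
clinic entry).  Validation is exhaustive — every violated invariant is
reported with offending rows, not just the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import JointLayout, default_layout

__all__ = ["PanelDataset", "PanelDataError", "read_panel_csv", "write_panel_csv"]

JOINT_COLUMNS = ["patient_id", "visit_index", "time_years", "joint_id", "active", "damaged"]
PATIENT_COLUMNS = ["patient_id", "sex", "age_onset", "entry_duration"]


class PanelDataError(ValueError):
    """Raised with the full list of dataset validation problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid panel dataset:\n" + "\n".join(f"- {p}" for p in problems))


@dataclass
class PanelDataset:
    """Long-format clustered panel data: patients x visits x 28 joints."""

    joints: pd.DataFrame
    patients: pd.DataFrame
    layout: JointLayout = field(default_factory=default_layout)

    def validate(self, min_visits: int = 3) -> "PanelDataset":
        problems: list[str] = []
        j = self.joints
        missing = [c for c in JOINT_COLUMNS if c not in j.columns]
        if missing:
            raise PanelDataError([f"joint table missing columns {missing}"])
        missing = [c for c in PATIENT_COLUMNS if c not in self.patients.columns]
        if missing:
            raise PanelDataError([f"patient table missing columns {missing}"])

        for col in ("active", "damaged"):
            bad = j.index[~j[col].isin([0, 1])]
            if len(bad):
                problems.append(f"non-binary values in '{col}' at rows {list(bad[:10])}")
        dup = j.duplicated(["patient_id", "visit_index", "joint_id"])
        if dup.any():
            problems.append(f"duplicate (patient, visit, joint) rows at {list(j.index[dup][:10])}")

        n_joints = len(self.layout.joint_ids)
        expected = set(self.layout.joint_ids)
        for (pid, vi), grp in j.groupby(["patient_id", "visit_index"], sort=False):
            if set(grp["joint_id"]) != expected:
                problems.append(
                    f"patient {pid} visit {vi}: expected the {n_joints} layout joints, "
                    f"got {len(grp)} rows")
            if grp["time_years"].nunique() > 1:
                problems.append(f"patient {pid} visit {vi}: times differ across joints")

        for pid, grp in j.groupby("patient_id", sort=False):
            visits = grp.drop_duplicates("visit_index").sort_values("visit_index")
            if len(visits) < min_visits:
                problems.append(
                    f"patient {pid}: only {len(visits)} visits; the analysis set requires "
                    f"more than two clinic visits (>= {min_visits})")
            t = visits["time_years"].to_numpy()
            if np.any(np.diff(t) <= 0):
                problems.append(f"patient {pid}: visit times not strictly increasing "
                                "(zero-length or reversed intervals)")
        for (pid, jid), grp in j.groupby(["patient_id", "joint_id"], sort=False):
            dmg = grp.sort_values("visit_index")["damaged"].to_numpy()
            if np.any(np.diff(dmg) < 0):
                rows = grp.sort_values("visit_index").index[np.nonzero(np.diff(dmg) < 0)[0] + 1]
                problems.append(f"patient {pid} joint {jid}: damage reversal at rows {list(rows)} "
                                "(damage is irreversible)")

        known = set(self.patients["patient_id"])
        unknown = set(j["patient_id"]) - known
        if unknown:
            problems.append(f"joint rows reference unknown patients {sorted(unknown)[:10]}")

        if problems:
            raise PanelDataError(problems)
        return self

    @property
    def patient_ids(self) -> list:
        return list(self.patients["patient_id"])

    def c_star(self) -> pd.Series:
        """Observed mover indicator: 1 if any damaged joint at the last visit."""
        j = self.joints
        last = j.groupby("patient_id")["visit_index"].transform("max")
        at_last = j[j["visit_index"] == last]
        return (at_last.groupby("patient_id")["damaged"].max()
                .reindex(self.patients["patient_id"]).astype(int))


def read_panel_csv(path, layout: JointLayout | None = None, validate: bool = True) -> PanelDataset:
    """Read a long-format panel CSV (one row per patient-visit-joint, with the
    per-patient covariates repeated on each row)."""
    df = pd.read_csv(path)
    needed = JOINT_COLUMNS + [c for c in PATIENT_COLUMNS if c != "patient_id"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise PanelDataError([f"input file missing columns {missing}"])
    patients = df[PATIENT_COLUMNS].drop_duplicates("patient_id").reset_index(drop=True)
    ds = PanelDataset(df[JOINT_COLUMNS].copy(), patients, layout or default_layout())
    if validate:
        ds.validate()
    return ds


def write_panel_csv(dataset: PanelDataset, path) -> None:
    df = dataset.joints.merge(dataset.patients, on="patient_id", how="left")
    df["time_years"] = df["time_years"].round(6)
    df.to_csv(path, index=False)
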
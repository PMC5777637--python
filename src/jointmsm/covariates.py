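"""Fixed and dynamic covariates at the (patient, visit, joint) level.

The dynamic covariates summarise the observed history of the processes:

* adjusted mean activity (AMA) — the time-average of the linearly
  interpolated binary activity observations of a joint, AMA(t) =
  (1/t) \\int_0^t x(s) ds with the origin at the patient's first visit;
* attained damaged-joint count — how many of the patient's 28 hand joints
  are damaged at the visit;
* contralateral (opposite) damage — whether the same joint in the other
  hand is damaged at the visit.

All covariates are treated as piecewise constant between clinic visits: the
value at the visit opening an interval applies across that interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "JointLayout",
    "default_layout",
    "compute_ama",
    "attained_damaged_count",
    "opposite_damaged",
    "build_covariates",
    "JOINT_TYPES",
    "JOINT_TYPE_DUMMIES",
]

#: Joint-type levels; thumb_PIP (the thumb interphalangeal joint) is the
#: reference level and gets no dummy column.
JOINT_TYPES = ("MCP", "PIP", "DIP", "thumb_MCP", "thumb_PIP")
JOINT_TYPE_DUMMIES = ("jt_MCP", "jt_PIP", "jt_DIP", "jt_thumb_MCP")


def _default_layout_frame() -> pd.DataFrame:
    """28 hand joints: per hand, four fingers x (MCP, PIP, DIP) plus the
    thumb MCP and thumb interphalangeal; left hand is ids 1-14, right 15-28,
    contralateral partner is id +/- 14."""
    rows = []
    types = []
    for finger in range(4):
        types += ["MCP", "PIP", "DIP"]
    types += ["thumb_MCP", "thumb_PIP"]
    for hand, offset in (("L", 0), ("R", 14)):
        for k, jt in enumerate(types, start=1):
            jid = offset + k
            partner = jid + 14 if hand == "L" else jid - 14
            rows.append((jid, hand, jt, partner))
    return pd.DataFrame(rows, columns=["joint_id", "hand", "joint_type", "contralateral_id"])


@dataclass
class JointLayout:
    """Anatomical layout of the 28 hand joints with contralateral pairing."""

    table: pd.DataFrame = field(default_factory=_default_layout_frame)

    def __post_init__(self) -> None:
        t = self.table
        required = {"joint_id", "hand", "joint_type", "contralateral_id"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"layout table missing columns {sorted(missing)}")
        self._partner = dict(zip(t["joint_id"], t["contralateral_id"]))
        self._type = dict(zip(t["joint_id"], t["joint_type"]))
        for jid, pid in self._partner.items():
            if pid not in self._partner or self._partner[pid] != jid:
                raise ValueError(f"contralateral pairing is not an involution at joint {jid}")
            if self._type[pid] != self._type[jid]:
                raise ValueError(f"paired joints {jid}/{pid} have different types")
        bad = set(self._type.values()) - set(JOINT_TYPES)
        if bad:
            raise ValueError(f"unknown joint types {sorted(bad)}")

    @property
    def joint_ids(self) -> list[int]:
        return list(self.table["joint_id"])

    def contralateral(self, joint_id: int) -> int:
        try:
            return self._partner[joint_id]
        except KeyError:
            raise ValueError(f"joint {joint_id} has no contralateral partner in the layout") from None

    def joint_type(self, joint_id: int) -> str:
        return self._type[joint_id]

    @classmethod
    def from_csv(cls, path) -> "JointLayout":
        return cls(pd.read_csv(path))


def default_layout() -> JointLayout:
    return JointLayout()


def compute_ama(times, activity, t) -> float:
    """Adjusted mean activity at time ``t``.

    Trapezoidal area under the linear interpolant of the binary activity
    observations from the first observation time to ``t``, divided by the
    elapsed time.  ``t`` must be one of the observation times and strictly
    after the first (AMA is undefined at the first visit).
    """
    times = np.asarray(times, dtype=float)
    activity = np.asarray(activity, dtype=float)
    if times.shape != activity.shape or times.ndim != 1:
        raise ValueError("times and activity must be 1-d sequences of equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("observation times must be strictly increasing")
    if not np.all(np.isin(activity, (0.0, 1.0))):
        raise ValueError("activity observations must be binary (0/1)")
    if t <= times[0]:
        raise ValueError("AMA is undefined at or before the first observation; "
                         "it requires previous observations")
    idx = np.nonzero(np.isclose(times, t))[0]
    if idx.size == 0:
        raise ValueError(f"evaluation time {t} is not an observation time")
    k = idx[0]
    area = np.trapezoid(activity[: k + 1], times[: k + 1])
    return float(area / (times[k] - times[0]))


def attained_damaged_count(dataset, patient_id, visit_index) -> int:
    """Number of the patient's 28 joints damaged at the given visit."""
    d = dataset.joints
    rows = d[(d["patient_id"] == patient_id) & (d["visit_index"] == visit_index)]
    if rows.empty:
        raise ValueError(f"patient {patient_id} has no visit {visit_index}")
    expected = set(dataset.layout.joint_ids)
    missing = expected - set(rows["joint_id"])
    if missing:
        raise ValueError(f"patient {patient_id} visit {visit_index} is missing joints {sorted(missing)}")
    return int(rows["damaged"].sum())


def opposite_damaged(dataset, patient_id, joint_id, visit_index, layout: JointLayout | None = None) -> int:
    """Damage status of the contralateral joint at the same visit."""
    layout = layout or dataset.layout
    partner = layout.contralateral(joint_id)
    d = dataset.joints
    row = d[(d["patient_id"] == patient_id) & (d["visit_index"] == visit_index)
            & (d["joint_id"] == partner)]
    if row.empty:
        raise ValueError(f"no observation for patient {patient_id}, joint {partner}, visit {visit_index}")
    return int(row["damaged"].iloc[0])


def build_covariates(dataset, layout: JointLayout | None = None,
                     baseline_proxy_ama: bool = False) -> pd.DataFrame:
    """Covariate table per (patient, visit, joint).

    Each row carries the values available at that visit (which the model
    holds constant over the interval the visit opens): AMA, attained damaged
    count, opposite-joint damage, joint-type dummies (thumb interphalangeal
    reference), sex, age at arthritis onset and arthritis duration
    (duration at clinic entry plus time since first visit, in years).

    AMA at the first visit is NaN (undefined) unless ``baseline_proxy_ama``
    is set, in which case the baseline activity indicator is used as proxy.
    """
    layout = layout or dataset.layout
    d = dataset.joints.sort_values(["patient_id", "joint_id", "visit_index"], kind="mergesort")
    g = d.groupby(["patient_id", "joint_id"], sort=False)

    t = d["time_years"].to_numpy(dtype=float)
    x = d["active"].to_numpy(dtype=float)
    first = g.cumcount().to_numpy() == 0
    t0 = np.where(first, t, np.nan)
    t0 = pd.Series(t0).ffill().to_numpy()

    dt_seg = np.where(first, 0.0, np.append(np.nan, np.diff(t)))
    seg_area = np.where(first, 0.0, 0.5 * (x + np.append(np.nan, x[:-1])) * dt_seg)
    # cumulative trapezoid restarting at each (patient, joint) block
    cum = np.cumsum(seg_area)
    block_base = np.where(first, cum, np.nan)
    block_base = pd.Series(block_base).ffill().to_numpy()
    area = cum - block_base
    with np.errstate(invalid="ignore", divide="ignore"):
        ama = area / (t - t0)
    ama = np.where(t > t0, ama, np.nan)
    if baseline_proxy_ama:
        ama = np.where(np.isnan(ama), x, ama)
    ama = np.clip(ama, 0.0, 1.0)  # guards roundoff; NaN (undefined) passes through

    out = d[["patient_id", "visit_index", "joint_id"]].copy()
    out["ama"] = ama

    # attained damaged count per (patient, visit); opposite damage via partner merge
    per_visit = d.groupby(["patient_id", "visit_index"], sort=False)["damaged"].sum()
    out["attained_damaged_count"] = per_visit.reindex(
        pd.MultiIndex.from_frame(out[["patient_id", "visit_index"]])).to_numpy()
    partner = d["joint_id"].map(layout._partner)
    dmg = d.set_index(["patient_id", "visit_index", "joint_id"])["damaged"]
    out["opposite_damaged"] = dmg.reindex(
        pd.MultiIndex.from_arrays([d["patient_id"], d["visit_index"], partner])).to_numpy()

    jt = d["joint_id"].map(layout._type)
    for dummy, level in zip(JOINT_TYPE_DUMMIES, JOINT_TYPES[:4]):
        out[dummy] = (jt == level).astype(float).to_numpy()

    pat = dataset.patients.set_index("patient_id")
    out["sex"] = pat["sex"].reindex(out["patient_id"]).to_numpy(dtype=float)
    out["age_onset"] = pat["age_onset"].reindex(out["patient_id"]).to_numpy(dtype=float)
    entry = pat["entry_duration"].reindex(out["patient_id"]).to_numpy(dtype=float)
    out["duration"] = entry + (t - t0)
    return out.reset_index(drop=True)
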
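"""Event-free survival from treatment start.

For a lab-defined event (default: hemoglobin below 9 g/100 mL, i.e.
moderate-to-severe anemia), each treated patient contributes the time in
days from treatment start to the first qualifying result. Events inside
the first-week washout are discarded; follow-up is censored at 360 days
or at the patient's last observed record, whichever comes first. Curves
are Kaplan–Meier product-limit estimates and groups are compared with
the two-group log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .labs import LabThreshold

__all__ = ["SurvivalRecord", "build_event_records", "km_curve", "logrank_p"]


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: int  # days since treatment start
    event: bool
    group: str

    def __post_init__(self) -> None:
        # the washout bound (events only after day `washout_days`) is
        # enforced by build_event_records, whose washout is configurable
        if self.time < 0 or self.time > 360:
            raise ValueError(f"time {self.time} outside [0, 360]")


def build_event_records(
    patients: pd.DataFrame,
    labs: pd.DataFrame,
    threshold: LabThreshold,
    direction: str = "low",
    washout_days: int = 7,
    horizon_days: int = 360,
    group_col: str = "trait_group",
) -> list[SurvivalRecord]:
    """Per-patient time to first qualifying lab result, washed-out and clamped.

    ``patients`` needs patient_id, treatment_start and the group column;
    ``labs`` needs patient_id, date, test_id, value (any tests; the
    event test is selected here). A patient whose only qualifying
    results fall inside the washout stays event-free to censoring.
    For hyperglycemia-style rules the event is the
    ``min_high_occurrences``-th qualifying result.
    """
    sub = labs[labs["test_id"] == threshold.test_id]
    by_patient = dict(tuple(sub.groupby("patient_id", sort=False)))
    all_by_patient = dict(tuple(labs.groupby("patient_id", sort=False)))
    records: list[SurvivalRecord] = []
    for rec in patients.itertuples(index=False):
        pid = rec.patient_id
        start = pd.Timestamp(rec.treatment_start)
        group = getattr(rec, group_col)
        res = by_patient.get(pid)
        mine = all_by_patient.get(pid)
        last_day = 0
        if mine is not None and len(mine):
            last_day = int(
                (pd.to_datetime(mine["date"]).max() - start).days
            )
        event_day = None
        if res is not None and len(res):
            days = (pd.to_datetime(res["date"]) - start).dt.days
            if direction == "low":
                hit = days[res["value"] < threshold.low]
                need = 1
            else:
                hit = days[res["value"] > threshold.high]
                need = threshold.min_high_occurrences
            hit = np.sort(np.unique(hit[hit > washout_days]))
            if len(hit) >= need:
                event_day = int(hit[need - 1])
        if event_day is not None and event_day <= horizon_days:
            records.append(SurvivalRecord(pid, event_day, True, group))
        else:
            records.append(
                SurvivalRecord(pid, min(max(last_day, 0), horizon_days), False, group)
            )
    return records


def _frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "group": [r.group for r in records],
        }
    )


def km_curve(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit survival table: (time, at_risk, events, survival)."""
    if not records:
        raise ValueError("no survival records")
    df = _frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    ev = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": ev.index.to_numpy(),
            "at_risk": ev["at_risk"].to_numpy(),
            "events": ev["observed"].to_numpy(),
            "survival": surv.reindex(ev.index).to_numpy(),
        }
    )
    return out


def logrank_p(records: list[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank statistic and two-sided chi-square(1) p."""
    df = _frame(records)
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {groups}")
    for g in groups:
        if (df["group"] == g).sum() == 0:  # pragma: no cover - unreachable
            raise ValueError(f"group {g} has no records")
    a = df[df["group"] == groups[0]]
    b = df[df["group"] == groups[1]]
    res = logrank_test(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return float(res.test_statistic), float(res.p_value)
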
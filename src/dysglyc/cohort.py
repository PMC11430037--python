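"""Patient/glucose data model, delimited-text I/O and event-relative windowing.

The unit conventions are fixed package-wide: time is decimal hours since ICU
admission, glucose is mg/dL.  Monitoring is truncated at 14 days (336 h), the
assumed window in which delayed cerebral ischemia (DCI) can occur.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: End of the monitoring window, hours since ICU admission (14 days).
MONITORING_CAP_H = 336.0

WindowLabel = Literal["pre", "post", "total"]
Group = Literal["DCI", "noDCI"]

PATIENT_COLUMNS = [
    "patient_id", "group", "dci_onset_h", "age", "sex",
    "mfisher", "hunt_hess", "saps2",
]
GLUCOSE_COLUMNS = ["patient_id", "time_h", "glucose_mgdl"]


@dataclass(frozen=True)
class GlucoseMeasurement:
    """One blood-glucose measurement: ``time`` in hours since ICU admission,
    ``value`` in mg/dL."""

    time: float
    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"measurement time must be finite and >= 0, got {self.time}")
        if not np.isfinite(self.value) or self.value <= 0:
            raise ValueError(f"glucose value must be finite and > 0, got {self.value}")


@dataclass(frozen=True)
class GlucoseTrace:
    """One patient's glucose series, stored as parallel arrays.

    Times must be strictly increasing; values positive and finite.  Empty
    traces are permitted as containers (e.g. a degenerate pre-onset window);
    index computations enforce their own minimum-size requirements.
    """

    patient_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size:
            if not np.all(np.isfinite(t)) or t[0] < 0:
                raise ValueError(f"trace {self.patient_id}: times must be finite and >= 0")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"trace {self.patient_id}: times must be strictly increasing")
            if not np.all(np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"trace {self.patient_id}: glucose must be finite and > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> float:
        """Observed span (last minus first time), 0.0 for traces with < 2 points."""
        return float(self.times[-1] - self.times[0]) if self.n >= 2 else 0.0

    def measurements(self) -> Iterator[GlucoseMeasurement]:
        for t, v in zip(self.times, self.values):
            yield GlucoseMeasurement(float(t), float(v))

    def between(self, start: float, end: float, *, include_end: bool = False) -> "GlucoseTrace":
        """Sub-trace with times in [start, end) (or [start, end] if include_end)."""
        mask = (self.times >= start) & ((self.times <= end) if include_end else (self.times < end))
        return GlucoseTrace(self.patient_id, self.times[mask], self.values[mask])


@dataclass(frozen=True)
class PatientRecord:
    """Metadata for one patient.

    ``dci_onset`` (hours since admission) is present exactly when
    ``group == "DCI"``.
    """

    patient_id: str
    group: Group
    dci_onset: float | None
    age: float
    sex: Literal["female", "male"]
    mfisher: int
    hunt_hess: int
    saps2: int

    def __post_init__(self) -> None:
        if self.group not in ("DCI", "noDCI"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "DCI":
            if self.dci_onset is None or not (0 < self.dci_onset <= MONITORING_CAP_H):
                raise ValueError(
                    f"patient {self.patient_id}: DCI onset must lie in (0, {MONITORING_CAP_H}] h"
                )
        elif self.dci_onset is not None:
            raise ValueError(f"patient {self.patient_id}: no-DCI patient cannot have an onset time")
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if not 1 <= self.mfisher <= 4:
            raise ValueError(f"mfisher must be 1..4, got {self.mfisher}")
        if not 1 <= self.hunt_hess <= 5:
            raise ValueError(f"hunt_hess must be 1..5, got {self.hunt_hess}")


@dataclass(frozen=True)
class AnalysisWindow:
    """A labelled slice of the monitoring time for one patient."""

    label: WindowLabel
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"window start {self.start} must be < end {self.end}")


def windows_for(record: PatientRecord) -> list[AnalysisWindow]:
    """Applicable analysis windows: total only for no-DCI; pre/post/total for DCI.

    Pre is half-open at onset ([admission, onset)); a measurement exactly at
    onset belongs to post.
    """
    total = AnalysisWindow("total", 0.0, MONITORING_CAP_H)
    if record.group == "noDCI":
        return [total]
    onset = float(record.dci_onset)  # type: ignore[arg-type]
    return [
        AnalysisWindow("pre", 0.0, onset),
        AnalysisWindow("post", onset, MONITORING_CAP_H),
        total,
    ]


def extract_window(trace: GlucoseTrace, record: PatientRecord, label: WindowLabel) -> GlucoseTrace:
    """Restrict a trace to a window relative to the patient's DCI onset.

    pre = times < onset, post = times >= onset (half-open at onset); pre and
    post partition total.  Requesting pre/post for a no-DCI patient is an
    error.
    """
    if label == "total":
        return trace
    if label not in ("pre", "post"):
        raise ValueError(f"unknown window label {label!r}")
    if record.group != "DCI":
        raise ValueError(
            f"patient {record.patient_id}: window {label!r} only exists for DCI patients"
        )
    onset = float(record.dci_onset)  # type: ignore[arg-type]
    if label == "pre":
        return trace.between(0.0, onset)
    return trace.between(onset, np.inf)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _parse_record(row: pd.Series) -> PatientRecord:
    onset = row["dci_onset_h"]
    onset = None if pd.isna(onset) else float(onset)
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        group=str(row["group"]),  # type: ignore[arg-type]
        dci_onset=onset,
        age=float(row["age"]),
        sex=str(row["sex"]),  # type: ignore[arg-type]
        mfisher=int(row["mfisher"]),
        hunt_hess=int(row["hunt_hess"]),
        saps2=int(row["saps2"]),
    )


def read_cohort(
    patients_path: str | Path, glucose_path: str | Path
) -> tuple[list[PatientRecord], list[GlucoseTrace]]:
    """Read a cohort from ``patients.csv`` + ``glucose.csv``.

    Glucose rows after the 14-day monitoring cap are dropped (count logged).
    Unknown patient ids, non-numeric or non-positive glucose, and duplicate
    (patient, time) rows are hard errors.  Returned traces are sorted by time
    and aligned with the record list (one trace per patient, possibly empty).
    """
    pdf = pd.read_csv(patients_path, dtype={"patient_id": str})
    missing = set(PATIENT_COLUMNS) - set(pdf.columns)
    if missing:
        raise ValueError(f"{patients_path}: missing columns {sorted(missing)}")
    records = [_parse_record(row) for _, row in pdf.iterrows()]
    known = {r.patient_id for r in records}
    if len(known) != len(records):
        raise ValueError(f"{patients_path}: duplicate patient ids")

    gdf = pd.read_csv(glucose_path, dtype={"patient_id": str})
    missing = set(GLUCOSE_COLUMNS) - set(gdf.columns)
    if missing:
        raise ValueError(f"{glucose_path}: missing columns {sorted(missing)}")
    for col in ("time_h", "glucose_mgdl"):
        parsed = pd.to_numeric(gdf[col], errors="coerce")
        bad = gdf.index[parsed.isna()]
        if len(bad):
            raise ValueError(f"{glucose_path}: non-numeric {col} at row {bad[0] + 2}")
        gdf[col] = parsed
    bad = gdf.index[gdf["glucose_mgdl"] <= 0]
    if len(bad):
        raise ValueError(f"{glucose_path}: non-positive glucose at row {bad[0] + 2}")
    bad = gdf.index[gdf["time_h"] < 0]
    if len(bad):
        raise ValueError(f"{glucose_path}: negative time at row {bad[0] + 2}")
    unknown = set(gdf["patient_id"]) - known
    if unknown:
        raise ValueError(f"{glucose_path}: unknown patient ids {sorted(unknown)[:5]}")
    if gdf.duplicated(subset=["patient_id", "time_h"]).any():
        raise ValueError(f"{glucose_path}: duplicate (patient_id, time_h) rows")

    n_late = int((gdf["time_h"] > MONITORING_CAP_H).sum())
    if n_late:
        log.info("dropping %d glucose rows beyond %.0f h", n_late, MONITORING_CAP_H)
        gdf = gdf[gdf["time_h"] <= MONITORING_CAP_H]

    gdf = gdf.sort_values(["patient_id", "time_h"])
    grouped = {pid: sub for pid, sub in gdf.groupby("patient_id")}
    traces = []
    for rec in records:
        sub = grouped.get(rec.patient_id)
        if sub is None:
            traces.append(GlucoseTrace(rec.patient_id, np.array([]), np.array([])))
        else:
            traces.append(
                GlucoseTrace(rec.patient_id, sub["time_h"].to_numpy(), sub["glucose_mgdl"].to_numpy())
            )
    return records, traces


def write_cohort(
    records: Sequence[PatientRecord],
    traces: Sequence[GlucoseTrace],
    patients_path: str | Path,
    glucose_path: str | Path,
) -> None:
    """Write ``patients.csv`` + ``glucose.csv`` (times to 0.01 h, glucose to
    0.1 mg/dL — the package's round-trip precision)."""
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "group": [r.group for r in records],
            "dci_onset_h": [
                "" if r.dci_onset is None else f"{r.dci_onset:.2f}" for r in records
            ],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "mfisher": [r.mfisher for r in records],
            "hunt_hess": [r.hunt_hess for r in records],
            "saps2": [r.saps2 for r in records],
        }
    ).to_csv(patients_path, index=False)
    rows = {
        "patient_id": np.concatenate([[t.patient_id] * t.n for t in traces]) if traces else [],
        "time_h": np.concatenate([t.times for t in traces]) if traces else [],
        "glucose_mgdl": np.concatenate([t.values for t in traces]) if traces else [],
    }
    gdf = pd.DataFrame(rows)
    gdf["time_h"] = gdf["time_h"].map(lambda x: f"{x:.2f}")
    gdf["glucose_mgdl"] = gdf["glucose_mgdl"].map(lambda x: f"{x:.1f}")
    gdf.to_csv(glucose_path, index=False)
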
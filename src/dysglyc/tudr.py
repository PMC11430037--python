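"""Time-unified dysglycemic rate (TUDR) and event-aligned cumulative curves.

The monitoring time is divided into fixed-length periods (1, 3, 6 or 12 h).
A period is *dysglycemic* if any glucose value in it falls outside the target
corridor (below 70 mg/dL or above the 140/160/180 mg/dL cutoff).  The
individual TUDR is the ratio of dysglycemic to evaluated periods for one
patient, on a grid anchored at ICU admission.  Cumulative rates re-anchor the
grid at each patient's own DCI onset (periods indexed ... -2, -1, +1, +2 ...,
there is no period 0) and count, per period, the fraction of measured patients
with at least one out-of-corridor value.

Binning convention: periods are half-open ``[kL, (k+1)L)``; a final
measurement landing exactly on the last grid boundary closes the preceding
period instead of opening a new one (include-right last bin), so a 30-h trace
on a 6-h grid spans exactly five periods.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import GlucoseTrace, PatientRecord
from .indices import twag

#: Candidate period lengths, hours.
PERIOD_CANDIDATES = (1.0, 3.0, 6.0, 12.0)
#: Minimum median per-patient coverage a period length must reach.
COVERAGE_THRESHOLD = 0.95

_EPS = 1e-9


@dataclass(frozen=True)
class GlycemicCorridor:
    """Target glucose range; values below ``low`` or above ``high`` are dysglycemic."""

    high: float
    low: float = 70.0

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("corridor requires low < high")

    def out_of_range(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values)
        return (v < self.low) | (v > self.high)


@dataclass(frozen=True)
class PeriodGrid:
    """Fixed-length partition of time.

    Admission-anchored grids index periods 0, 1, 2, ... from the anchor.
    Event-anchored grids use signed indices: -1 is the period ending at the
    anchor, +1 the period starting at it; index 0 does not exist.
    """

    period_length: float
    anchor: float = 0.0
    event_anchored: bool = False

    def __post_init__(self) -> None:
        if self.period_length <= 0:
            raise ValueError("period_length must be positive")

    def bounds(self, k: int) -> tuple[float, float]:
        L = self.period_length
        if self.event_anchored:
            if k == 0:
                raise ValueError("event-anchored grids have no period 0")
            lo = self.anchor + (k if k < 0 else k - 1) * L
        else:
            if k < 0:
                raise ValueError("admission-anchored periods start at 0")
            lo = self.anchor + k * L
        return lo, lo + L

    def indices(self, times: np.ndarray) -> np.ndarray:
        """Signed period index of each time (vectorized)."""
        rel = (np.asarray(times, dtype=float) - self.anchor) / self.period_length
        idx = np.floor(rel + _EPS).astype(int)
        if self.event_anchored:
            idx = np.where(idx >= 0, idx + 1, idx)
        return idx


def _admission_indices(trace: GlucoseTrace, period_length: float) -> np.ndarray:
    """Admission-anchored period index per measurement, with boundary closure:
    the last measurement, if exactly on a grid boundary past the first period
    it shares with earlier data, closes the preceding period."""
    grid = PeriodGrid(period_length)
    idx = grid.indices(trace.times)
    if trace.n > 1:
        rel_last = trace.times[-1] / period_length
        if abs(rel_last - round(rel_last)) < _EPS and idx[-1] == round(rel_last):
            idx[-1] -= 1
    return idx


def coverage_fraction(trace: GlucoseTrace, period_length: float) -> float:
    """Fraction of grid periods between the first and last measurement that
    contain at least one measurement (admission-anchored grid)."""
    if trace.n == 0:
        raise ValueError(f"trace {trace.patient_id}: coverage undefined for an empty trace")
    idx = _admission_indices(trace, period_length)
    total = idx[-1] - idx[0] + 1
    return float(len(np.unique(idx)) / total)


def choose_period_length(
    medians: Mapping[float, float], threshold: float = COVERAGE_THRESHOLD
) -> float:
    """Shortest candidate whose median coverage reaches the threshold."""
    for length in sorted(medians):
        if medians[length] >= threshold:
            return float(length)
    raise ValueError(
        "no candidate period length reaches the coverage threshold "
        f"{threshold:.0%}; per-candidate medians: "
        + ", ".join(f"{length:g} h: {m:.1%}" for length, m in sorted(medians.items()))
    )


@dataclass(frozen=True)
class PeriodSelection:
    period_length: float
    medians: dict[float, float]
    threshold: float


def select_period_length(
    traces: Sequence[GlucoseTrace],
    candidates: Sequence[float] = PERIOD_CANDIDATES,
    threshold: float = COVERAGE_THRESHOLD,
) -> PeriodSelection:
    """Period-length calibration: for each candidate, the median across
    patients of the per-patient coverage fraction; select the shortest
    candidate whose median reaches the threshold."""
    usable = [t for t in traces if t.n > 0]
    if not usable:
        raise ValueError("no non-empty traces to calibrate the period length on")
    medians = {
        float(L): float(np.median([coverage_fraction(t, L) for t in usable]))
        for L in candidates
    }
    return PeriodSelection(choose_period_length(medians, threshold), medians, threshold)


def individual_tudr(
    trace: GlucoseTrace,
    corridor: GlycemicCorridor,
    period_length: float,
    *,
    count_empty_as_normo: bool = False,
) -> float | None:
    """Individual TUDR: dysglycemic / evaluated periods on an admission-anchored grid.

    The trace should already be restricted to the analysis window (pre/post
    windows keep the admission-anchored grid, evaluated on their own
    measurements only).  Periods without any measurement are excluded from
    numerator and denominator unless ``count_empty_as_normo`` is set, in which
    case every period spanned by the observations enters the denominator.
    Returns None when no period can be evaluated.
    """
    if trace.n == 0:
        return None
    idx = _admission_indices(trace, period_length)
    out = corridor.out_of_range(trace.values)
    n_dys = len(np.unique(idx[out]))
    if count_empty_as_normo:
        denom = int(idx[-1] - idx[0] + 1)
    else:
        denom = len(np.unique(idx))
    return float(n_dys / denom)


@dataclass(frozen=True)
class CumulativePeriodPoint:
    """Cohort summary of one event-aligned period (signed index ``period``)."""

    period: int
    n_present: int          # patients with >= 1 measurement in the period
    n_dysglycemic: int      # of those, patients with >= 1 out-of-corridor value
    rate: float             # n_dysglycemic / n_present (NaN if none present)
    twag_values: np.ndarray  # per-patient within-period TWAG (>= 2 measurements)


def cumulative_curves(
    records: Sequence[PatientRecord],
    traces: Sequence[GlucoseTrace],
    corridor: GlycemicCorridor,
    period_length: float,
    horizon: float = 168.0,
) -> list[CumulativePeriodPoint]:
    """Event-aligned cumulative dysglycemia curve for the DCI subgroup.

    Each patient's grid is anchored at their own onset; signed periods out to
    ±horizon are pooled across patients.  Per period: the number of measured
    patients, the number with at least one out-of-corridor value, their ratio,
    and the per-patient within-period TWAG distribution.
    """
    ratio = horizon / period_length
    if abs(ratio - round(ratio)) > _EPS:
        raise ValueError("horizon must be an integer multiple of period_length")
    m = int(round(ratio))
    by_id = {t.patient_id: t for t in traces}
    pats = []
    for rec in records:
        if rec.dci_onset is None:
            raise ValueError(f"patient {rec.patient_id}: cumulative curves need a DCI onset")
        trace = by_id.get(rec.patient_id)
        if trace is not None and trace.n:
            pats.append((rec, trace))

    points: list[CumulativePeriodPoint] = []
    for k in [*range(-m, 0), *range(1, m + 1)]:
        n_present = n_dys = 0
        twags: list[float] = []
        for rec, trace in pats:
            grid = PeriodGrid(period_length, anchor=float(rec.dci_onset), event_anchored=True)
            lo, hi = grid.bounds(k)
            mask = (trace.times >= lo) & (trace.times < hi)
            if not mask.any():
                continue
            n_present += 1
            if corridor.out_of_range(trace.values[mask]).any():
                n_dys += 1
            if mask.sum() >= 2:
                twags.append(
                    twag(GlucoseTrace(rec.patient_id, trace.times[mask], trace.values[mask]))
                )
        rate = n_dys / n_present if n_present else math.nan
        points.append(
            CumulativePeriodPoint(k, n_present, n_dys, rate, np.asarray(twags))
        )
    return points


def curves_to_frame(
    points: Sequence[CumulativePeriodPoint], corridor: GlycemicCorridor
) -> pd.DataFrame:
    """One row per (period, corridor): counts, rate and median period TWAG."""
    return pd.DataFrame(
        {
            "period": [p.period for p in points],
            "corridor_high": corridor.high,
            "n_present": [p.n_present for p in points],
            "n_dysglycemic": [p.n_dysglycemic for p in points],
            "rate": [p.rate for p in points],
            "twag_median": [
                float(np.median(p.twag_values)) if p.twag_values.size else math.nan
                for p in points
            ],
            "twag_n": [p.twag_values.size for p in points],
        }
    )
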
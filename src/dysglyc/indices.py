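"""Summary glycemic indices for irregularly sampled glucose traces.

Four per-window indices:

* **MBG** — mean blood glucose, the plain arithmetic mean of the measured
  values (sampling-frequency sensitive).
* **TWAG** — time-weighted average glucose: area under the piecewise-linear
  glucose curve divided by the hours analyzed (first-to-last measurement),
  robust to uneven sampling.
* **CV** — glycemic coefficient of variation, 100 * sample SD / MBG (percent).
* **AACTD** — average absolute change by time difference: the mean over
  consecutive measurement pairs of |Δglucose| / Δtime (mg/dL per hour), a
  sampling-aware fluctuation index.

Windows with fewer than two measurements cannot support the time-aware
indices; ``compute_panels`` skips such windows and logs the reason rather
than raising.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import GlucoseTrace, PatientRecord, WindowLabel, extract_window, windows_for

log = logging.getLogger(__name__)


def mbg(trace: GlucoseTrace) -> float:
    """Arithmetic mean of all glucose values (mg/dL)."""
    if trace.n == 0:
        raise ValueError(f"trace {trace.patient_id}: MBG undefined for an empty trace")
    return float(np.mean(trace.values))


def twag(trace: GlucoseTrace) -> float:
    """Time-weighted average glucose (mg/dL).

    Trapezoidal area under the piecewise-linear curve through the
    measurements, divided by the observed span.  Requires >= 2 measurements;
    otherwise returns NaN (logged).  No extrapolation beyond the first and
    last measurement.
    """
    if trace.n < 2:
        log.info("trace %s: TWAG needs >= 2 measurements, got %d", trace.patient_id, trace.n)
        return math.nan
    span = trace.span
    if span <= 0:  # unreachable for valid traces; guard against zero division
        raise ValueError(f"trace {trace.patient_id}: zero time span")
    return float(np.trapezoid(trace.values, trace.times) / span)


def glycemic_cv(trace: GlucoseTrace) -> float:
    """Coefficient of variation: 100 * sample SD (n-1 denominator) / MBG, percent."""
    if trace.n < 2:
        log.info("trace %s: CV needs >= 2 measurements, got %d", trace.patient_id, trace.n)
        return math.nan
    return float(100.0 * np.std(trace.values, ddof=1) / np.mean(trace.values))


def aactd(trace: GlucoseTrace) -> float:
    """Average absolute change by time difference (mg/dL per hour).

    Mean over consecutive pairs of |value_{i+1} - value_i| / (t_{i+1} - t_i).
    """
    if trace.n < 2:
        log.info("trace %s: AACTD needs >= 2 measurements, got %d", trace.patient_id, trace.n)
        return math.nan
    rates = np.abs(np.diff(trace.values)) / np.diff(trace.times)
    return float(np.mean(rates))


@dataclass
class IndexPanel:
    """Per-patient-per-window index values.

    The dysglycemic-rate fields (``tudr140/160/180``, proportions in [0, 1])
    are filled by :mod:`dysglyc.tudr`; they stay None until then.
    """

    patient_id: str
    window: WindowLabel
    mbg: float
    twag: float
    cv: float
    aactd: float
    n_measurements: int
    span: float
    tudr140: float | None = None
    tudr160: float | None = None
    tudr180: float | None = None


def panel_for(trace: GlucoseTrace, window: WindowLabel) -> IndexPanel:
    """Index panel for an already-windowed trace (requires >= 2 measurements)."""
    if trace.n < 2:
        raise ValueError(f"trace {trace.patient_id}: a panel needs >= 2 measurements")
    return IndexPanel(
        patient_id=trace.patient_id,
        window=window,
        mbg=mbg(trace),
        twag=twag(trace),
        cv=glycemic_cv(trace),
        aactd=aactd(trace),
        n_measurements=trace.n,
        span=trace.span,
    )


def compute_panels(
    records: Sequence[PatientRecord],
    traces: Sequence[GlucoseTrace],
    *,
    period_length: float | None = None,
    corridors: Sequence[float] = (140.0, 160.0, 180.0),
) -> list[IndexPanel]:
    """One panel per (patient, applicable window): total only for no-DCI
    patients; pre, post and total for DCI patients.

    Windows with fewer than two measurements yield no panel (logged).  If
    ``period_length`` is given, per-window individual dysglycemic rates are
    attached for each corridor.
    """
    by_id = {t.patient_id: t for t in traces}
    panels: list[IndexPanel] = []
    for rec in records:
        trace = by_id.get(rec.patient_id)
        if trace is None:
            log.info("patient %s: no glucose trace, skipped", rec.patient_id)
            continue
        for win in windows_for(rec):
            sub = extract_window(trace, rec, win.label)
            if sub.n < 2:
                log.info(
                    "patient %s window %s: %d measurement(s), panel skipped",
                    rec.patient_id, win.label, sub.n,
                )
                continue
            panel = panel_for(sub, win.label)
            if period_length is not None:
                from .tudr import GlycemicCorridor, individual_tudr

                for high in corridors:
                    rate = individual_tudr(sub, GlycemicCorridor(high=high), period_length)
                    setattr(panel, f"tudr{int(high)}", rate)
            panels.append(panel)
    return panels


def panels_to_frame(panels: Sequence[IndexPanel]) -> pd.DataFrame:
    """Panels as a tidy DataFrame, one row per (patient, window)."""
    cols = ["patient_id", "window", "mbg", "twag", "cv", "aactd",
            "tudr140", "tudr160", "tudr180", "n_measurements", "span"]
    return pd.DataFrame([asdict(p) for p in panels], columns=cols)
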
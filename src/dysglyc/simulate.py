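"""Seeded synthetic-cohort generator.

Emulates the statistical structure of a neuro-ICU aSAH cohort monitored for up
to 14 days: a DCI subgroup with an onset time drawn between day 3 and day 14,
denser glucose sampling in the DCI group, a step increase of the glucose
setpoint at onset, and multiplicative lag-1 autocorrelated noise calibrated to
a target coefficient of variation.  The generator provides ground truth for
parameter-recovery tests; it does not model insulin, nutrition or physiology.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .cohort import GlucoseTrace, PatientRecord, MONITORING_CAP_H


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator parameters.

    Defaults reproduce the study conditions the pipeline is designed for:
    46.4% DCI incidence, mean sampling intervals 4.0 ± 1.6 h (no-DCI) and
    2.8 ± 0.8 h (DCI), glucose setpoints 125.6 / 130.7 / 149.2 mg/dL for
    no-DCI / pre-onset / post-onset, ~18% within-patient coefficient of
    variation, onset uniform on days 3–14, monitoring capped at 14 days.
    """

    n_patients: int = 151
    dci_fraction: float = 0.464
    interval_mean_nodci: float = 4.0   # h
    interval_sd_nodci: float = 1.6     # h
    interval_mean_dci: float = 2.8     # h
    interval_sd_dci: float = 0.8       # h
    setpoint_nodci: float = 125.6      # mg/dL
    setpoint_pre: float = 130.7        # mg/dL
    setpoint_post: float = 149.2       # mg/dL
    cv_target: float = 0.18            # proportion of setpoint
    onset_min: float = 72.0            # h
    onset_max: float = 336.0           # h
    monitoring_max: float = MONITORING_CAP_H  # h
    ar_coefficient: float = 0.5        # lag-1 autocorrelation of the noise
    min_interval: float = 0.25         # h, truncation point of interval draws
    glucose_floor: float = 40.0        # mg/dL
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dci_fraction < 1:
            raise ValueError("dci_fraction must be in (0, 1)")
        if min(self.interval_mean_nodci, self.interval_mean_dci) <= 0:
            raise ValueError("interval means must be positive")
        if not self.onset_min < self.onset_max <= self.monitoring_max:
            raise ValueError("need onset_min < onset_max <= monitoring_max")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.cv_target < 0:
            raise ValueError("cv_target must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Per-patient generating parameters plus an echo of the config."""

    patients: pd.DataFrame  # patient_id, group, dci_onset_h, setpoint_pre, setpoint_post
    config: GeneratorConfig

    def to_frame(self) -> pd.DataFrame:
        return self.patients.copy()


def _sample_times(rng: np.random.Generator, mean: float, sd: float,
                  min_interval: float, horizon: float) -> np.ndarray:
    """Measurement times as cumulative sums of truncated-normal intervals."""
    a = (min_interval - mean) / sd
    n_draw = int(horizon / mean * 1.6) + 12
    times = np.cumsum(
        stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n_draw, random_state=rng)
    )
    while times[-1] < horizon:  # pragma: no cover - generous initial draw
        extra = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n_draw, random_state=rng)
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    return times[times <= horizon]


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary standard-normal AR(1) sequence with lag-1 correlation phi."""
    if n == 0:
        return np.array([])
    innov = np.empty(n)
    innov[0] = rng.standard_normal()
    innov[1:] = np.sqrt(1.0 - phi**2) * rng.standard_normal(n - 1)
    return signal.lfilter([1.0], [1.0, -phi], innov)


def _covariates(rng: np.random.Generator, is_dci: bool) -> dict:
    # Marginals loosely shaped like a severe-aSAH ICU population; DCI patients
    # skew younger, sicker and with heavier bleeds.
    if is_dci:
        age_mu, age_sd, saps_mu = 52.9, 11.8, 39.1
        p_female = 0.686
        p_mf = [0.10, 0.20, 0.35, 0.35]
        p_hh = [0.14, 0.25, 0.25, 0.22, 0.14]
    else:
        age_mu, age_sd, saps_mu = 57.2, 12.6, 36.0
        p_female = 0.654
        p_mf = [0.30, 0.33, 0.20, 0.17]
        p_hh = [0.25, 0.27, 0.22, 0.16, 0.10]
    return dict(
        age=float(np.clip(np.round(rng.normal(age_mu, age_sd), 1), 18.0, 95.0)),
        sex="female" if rng.random() < p_female else "male",
        mfisher=int(rng.choice(4, p=p_mf)) + 1,
        hunt_hess=int(rng.choice(5, p=p_hh)) + 1,
        saps2=int(np.clip(round(rng.normal(saps_mu, 9.0)), 6, 90)),
    )


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[PatientRecord], list[GlucoseTrace], GroundTruth]:
    """Generate a reproducible cohort from ``config``.

    round(n_patients * dci_fraction) patients are labelled DCI with onset
    uniform on [onset_min, onset_max].  Glucose values follow
    ``setpoint(t) * (1 + cv_target * z_t)`` where the setpoint steps from the
    pre to the post level at onset and ``z_t`` is a stationary standard-normal
    AR(1) sequence; values are floored at ``glucose_floor``.  Identical seeds
    give identical cohorts.
    """
    n = config.n_patients
    n_dci = round(n * config.dci_fraction)
    if n < 4 or n_dci < 2 or n - n_dci < 2:
        raise ValueError("need n_patients >= 4 with at least 2 patients per group")
    rng = np.random.default_rng(config.seed)

    records: list[PatientRecord] = []
    traces: list[GlucoseTrace] = []
    truth_rows: list[dict] = []
    width = max(3, len(str(n)))
    for i in range(n):
        is_dci = i < n_dci
        pid = f"P{i + 1:0{width}d}"
        if is_dci:
            onset = float(rng.uniform(config.onset_min, config.onset_max))
            times = _sample_times(rng, config.interval_mean_dci, config.interval_sd_dci,
                                  config.min_interval, config.monitoring_max)
            setpoints = np.where(times < onset, config.setpoint_pre, config.setpoint_post)
            sp_pre, sp_post = config.setpoint_pre, config.setpoint_post
        else:
            onset = None
            times = _sample_times(rng, config.interval_mean_nodci, config.interval_sd_nodci,
                                  config.min_interval, config.monitoring_max)
            setpoints = np.full(times.size, config.setpoint_nodci)
            sp_pre = sp_post = config.setpoint_nodci
        z = _ar1(rng, times.size, config.ar_coefficient)
        values = np.maximum(setpoints * (1.0 + config.cv_target * z), config.glucose_floor)
        records.append(
            PatientRecord(patient_id=pid, group="DCI" if is_dci else "noDCI",
                          dci_onset=onset, **_covariates(rng, is_dci))
        )
        traces.append(GlucoseTrace(pid, times, values))
        truth_rows.append(
            dict(patient_id=pid, group="DCI" if is_dci else "noDCI",
                 dci_onset_h=onset, setpoint_pre=sp_pre, setpoint_post=sp_post)
        )
    truth = GroundTruth(patients=pd.DataFrame(truth_rows), config=config)
    return records, traces, truth


def make_fixture_trace(
    points: Sequence[tuple[float, float]], patient_id: str = "fixture"
) -> GlucoseTrace:
    """Verbatim trace from (time, value) pairs; times must be strictly increasing."""
    if not points:
        return GlucoseTrace(patient_id, np.array([]), np.array([]))
    times, values = map(np.asarray, zip(*points))
    if np.any(np.diff(times) <= 0):
        raise ValueError("fixture times must be strictly increasing")
    return GlucoseTrace(patient_id, times.astype(float), values.astype(float))


def example_trace() -> GlucoseTrace:
    """A 30-hour pre-onset demonstration trace.

    Sampled every 2 h at 120 mg/dL, with two brief hyperglycemic excursions to
    150 mg/dL at t = 7 h and t = 19 h — so exactly the second and fourth of
    five 6-h periods are dysglycemic against the 70-140 mg/dL corridor,
    giving a worked individual dysglycemic rate of 40%.
    """
    pts = [(float(t), 120.0) for t in range(0, 31, 2)]
    pts += [(7.0, 150.0), (19.0, 150.0)]
    return make_fixture_trace(sorted(pts), patient_id="example")


def config_from_mapping(mapping: dict) -> GeneratorConfig:
    """Build a config from a YAML/JSON-style mapping (unknown keys rejected)."""
    valid = set(GeneratorConfig.__dataclass_fields__)
    unknown = set(mapping) - valid
    if unknown:
        raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
    return GeneratorConfig(**mapping)
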
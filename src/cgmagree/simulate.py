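"""Synthetic paired-glucose cohorts for a post-operative ICU under tight control.

The generator emulates the data-generating situation the analysis assumes:
insulin-titrated patients whose true glucose is held near a setpoint inside
the 70–140 mg/dL goal band, sampled by hourly laboratory serum draws and a
subcutaneous sensor reporting every 5 minutes, over seven post-operative
days.

Model components
----------------
* **True glucose** — a mean-reverting (Ornstein–Uhlenbeck-style) process on a
  1-minute grid: ``G(t+Δ) = G(t) + rate·(setpoint − G(t))·Δ + σ_p·√Δ·z``,
  clipped to [40, 400] mg/dL.  The reversion term is the simplest stand-in
  for the titration control law; no meal or insulin pharmacokinetics are
  modelled.
* **Serum draws** — true value plus independent assay noise, rounded to
  1 mg/dL, floored at 40.
* **CGM readings** — ``true·(1 + ε_prop) + ε_add + bias_day + drug_term``,
  where the proportional and additive error streams are stationary AR(1)
  series at the reading cadence, ``bias_day`` is a per-sensor-day constant
  bias, all sensor noise SDs are inflated by a factor during sensor day 1
  (the warm-up period), and ``drug_term`` is a constant positive bias for a
  fixed duration after each interference-drug dose.  Readings are rounded to
  1 mg/dL and clipped to the sensor range [40, 400].

Randomness is fully reproducible: every (patient, stream) pair draws from
its own child seed of ``(config.seed, patient_index, stream)``, so adding
patients to a cohort never perturbs existing patients' data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .model import Cohort, GlucoseSample, PatientRecord, Source

# First-dose day of the interference drug for each patient who receives it:
# two patients start on day 4, two on day 5, five on day 6, three on day 7;
# the remaining patients never receive it within the simulated week.
DEFAULT_DRUG_START_DAYS: tuple[int, ...] = (4, 4, 5, 5, 6, 6, 6, 6, 6, 7, 7, 7)

_STREAM_TRUE, _STREAM_SERUM, _STREAM_CGM = 1, 2, 3


class ConfigError(ValueError):
    """A simulation parameter violates its constraint."""


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters (glucose in mg/dL, times in the
    units named by each field)."""

    n_patients: int = 25
    days: int = 7
    serum_interval_min: int = 60
    cgm_interval_min: int = 5
    glucose_setpoint: float = 110.0
    glucose_start: float = 140.0  # arrival glucose; decays toward setpoint
    reversion_rate_per_h: float = 0.5
    process_sd: float = 12.0  # mg/dL per sqrt(hour)
    assay_sd: float = 5.0  # serum measurement noise, mg/dL
    sensor_prop_sd: float = 0.13  # proportional sensor error SD
    sensor_add_sd: float = 7.0  # additive sensor error SD, mg/dL
    sensor_bias_sd: float = 7.0  # per-sensor-day bias SD, mg/dL
    day1_inflation: float = 1.5  # sensor-noise multiplier during day 1
    ar1_rho: float = 0.5  # lag-1 autocorrelation of sensor error streams
    drug_start_days: tuple[int | None, ...] | None = None  # None -> default schedule
    drug_bias: float = 30.0  # positive CGM bias while interference is active
    drug_duration_h: float = 7.5  # interference duration after each dose
    drug_dose_interval_h: float = 24.0  # repeat dosing cadence after the first dose
    base_time: datetime = datetime(2021, 3, 1, 12, 0, 0)  # surgery end / sensor start
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.days < 1:
            raise ConfigError("n_patients and days must be >= 1")
        for name in ("process_sd", "assay_sd", "sensor_prop_sd", "sensor_add_sd", "sensor_bias_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0 <= self.ar1_rho < 1):
            raise ConfigError("ar1_rho must lie in [0, 1)")
        if self.day1_inflation < 1:
            raise ConfigError("day1_inflation must be >= 1")
        if self.reversion_rate_per_h < 0:
            raise ConfigError("reversion_rate_per_h must be >= 0")
        for name in ("serum_interval_min", "cgm_interval_min"):
            iv = getattr(self, name)
            if iv < 1 or (24 * 60) % iv != 0:
                raise ConfigError(f"{name} must be a positive divisor of 24 h")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "base_time" in raw:
            raw["base_time"] = datetime.fromisoformat(raw["base_time"])
        if "drug_start_days" in raw and raw["drug_start_days"] is not None:
            raw["drug_start_days"] = tuple(raw["drug_start_days"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class Trajectory:
    """True glucose on a 1-minute grid starting at ``start``."""

    start: datetime
    values: np.ndarray  # mg/dL, one per minute

    @property
    def n_minutes(self) -> int:
        return len(self.values)

    def time_at(self, minute: int) -> datetime:
        return self.start + timedelta(minutes=int(minute))


def _rng(config: SimulationConfig, patient_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, patient_index, stream]))


def simulate_true_glucose(config: SimulationConfig, patient_index: int) -> Trajectory:
    """Mean-reverting true-glucose trajectory on a 1-minute grid.

    With ``process_sd = 0`` the trajectory decays deterministically and
    monotonically from ``glucose_start`` to the setpoint.  With the default
    parameters the stationary SD is ``process_sd / sqrt(2·rate)`` and well
    over 90% of minutes lie inside the 70–140 mg/dL goal band.
    """
    config.validate()
    rng = _rng(config, patient_index, _STREAM_TRUE)
    n = config.days * 24 * 60 + 1
    dt = 1.0 / 60.0  # hours per step
    noise = rng.standard_normal(n - 1) * config.process_sd * np.sqrt(dt)
    k = config.reversion_rate_per_h * dt
    setpoint = config.glucose_setpoint
    # g[i+1] = g[i] + k (setpoint - g[i]) + noise[i]; in deviation form
    # h[i+1] = (1-k) h[i] + noise[i], an IIR filter evaluated in C
    x = np.concatenate(([config.glucose_start - setpoint], noise))
    h = lfilter([1.0], [1.0, -(1.0 - k)], x)
    g = setpoint + h
    np.clip(g, 40.0, 400.0, out=g)
    return Trajectory(start=config.base_time, values=g)


def sample_serum(
    trajectory: Trajectory, config: SimulationConfig, patient_index: int, patient_id: str
) -> list[GlucoseSample]:
    """Hourly (by default) laboratory serum draws with assay noise."""
    rng = _rng(config, patient_index, _STREAM_SERUM)
    minutes = np.arange(0, config.days * 24 * 60, config.serum_interval_min)
    true = trajectory.values[minutes]
    vals = true + rng.standard_normal(len(minutes)) * config.assay_sd
    vals = np.maximum(np.round(vals), 40.0)
    return [
        GlucoseSample(patient_id, trajectory.time_at(m), float(v), Source.SERUM)
        for m, v in zip(minutes, vals)
    ]


def _dose_times(config: SimulationConfig, first_day: int | None) -> list[datetime]:
    if first_day is None:
        return []
    first = config.base_time + timedelta(hours=(first_day - 1) * 24 + 9)
    end = config.base_time + timedelta(days=config.days)
    times = []
    t = first
    while t < end:
        times.append(t)
        t += timedelta(hours=config.drug_dose_interval_h)
    return times


def sample_cgm(
    trajectory: Trajectory,
    config: SimulationConfig,
    patient_index: int,
    patient_id: str,
    dose_times: list[datetime] | None = None,
) -> list[GlucoseSample]:
    """Five-minute (by default) CGM readings under the parametric error model."""
    rng = _rng(config, patient_index, _STREAM_CGM)
    minutes = np.arange(0, config.days * 24 * 60, config.cgm_interval_min)
    true = trajectory.values[minutes]
    n = len(minutes)

    eps_prop = _ar1(rng, n, config.ar1_rho) * config.sensor_prop_sd
    eps_add = _ar1(rng, n, config.ar1_rho) * config.sensor_add_sd
    day_bias = rng.standard_normal(config.days) * config.sensor_bias_sd
    day_index = minutes // (24 * 60)  # 0-based sensor day
    bias = day_bias[day_index]

    inflate = np.where(day_index == 0, config.day1_inflation, 1.0)
    eps_prop = eps_prop * inflate
    eps_add = eps_add * inflate
    bias = bias * inflate

    drug_term = np.zeros(n)
    for dose in dose_times or []:
        lo = (dose - trajectory.start).total_seconds() / 60.0
        hi = lo + config.drug_duration_h * 60.0
        drug_term[(minutes >= lo) & (minutes < hi)] = config.drug_bias

    vals = true * (1.0 + eps_prop) + eps_add + bias + drug_term
    vals = np.clip(np.round(vals), 40.0, 400.0)
    return [
        GlucoseSample(patient_id, trajectory.time_at(m), float(v), Source.CGM)
        for m, v in zip(minutes, vals)
    ]


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Stationary unit-variance AR(1) series of length n."""
    z = rng.standard_normal(n)
    if rho == 0.0:
        return z
    x = z * np.sqrt(1.0 - rho * rho)
    x[0] = z[0]  # start from the stationary distribution
    return lfilter([1.0], [1.0, -rho], x)


def _drug_schedule(config: SimulationConfig) -> list[int | None]:
    if config.drug_start_days is not None:
        sched = list(config.drug_start_days)
        if len(sched) > config.n_patients:
            raise ConfigError("drug_start_days longer than n_patients")
    else:
        sched = [d for d in DEFAULT_DRUG_START_DAYS if d <= config.days]
        sched = sched[: config.n_patients]
    return sched + [None] * (config.n_patients - len(sched))


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, pd.DataFrame]:
    """Assemble the full synthetic cohort plus a ground-truth sidecar.

    Returns the cohort (patients + serum and CGM samples) and a DataFrame
    with the noise-free true glucose at every sampled time — the oracle used
    by tests to recover generator parameters from pipeline output.
    """
    config.validate()
    schedule = _drug_schedule(config)
    patients: list[PatientRecord] = []
    samples: list[GlucoseSample] = []
    truth_rows: list[tuple[str, datetime, str, float]] = []

    for idx in range(config.n_patients):
        pid = f"P{idx + 1:03d}"
        doses = _dose_times(config, schedule[idx])
        patients.append(
            PatientRecord(
                patient_id=pid,
                sensor_start=config.base_time,
                surgery_end=config.base_time,
                drug_dose_times=doses,
            )
        )
        traj = simulate_true_glucose(config, idx)
        serum = sample_serum(traj, config, idx, pid)
        cgm = sample_cgm(traj, config, idx, pid, doses)
        samples.extend(serum)
        samples.extend(cgm)
        for s in serum + cgm:
            minute = int((s.timestamp - traj.start).total_seconds() // 60)
            truth_rows.append((pid, s.timestamp, s.source.value, float(traj.values[minute])))

    truth = pd.DataFrame(truth_rows, columns=["patient_id", "timestamp", "source", "true_mg_dl"])
    return Cohort(patients=patients, samples=samples), truth
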
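from __future__ import annotations

from datetime import datetime, timedelta

import pytest

from cgmagree.model import Cohort, GlucoseSample, PatientRecord, Source
from cgmagree.pairing import MatchedPair
from cgmagree.simulate import SimulationConfig, simulate_cohort

T0 = datetime(2021, 3, 1, 12, 0, 0)


def make_pair(
    serum: float,
    cgm: float,
    day: int = 2,
    pid: str = "P001",
    t: datetime | None = None,
    delta: float = 0.0,
) -> MatchedPair:
    t = t or (T0 + timedelta(days=day - 1, hours=1))
    return MatchedPair(
        patient_id=pid,
        serum_time=t,
        cgm_time=t + timedelta(seconds=delta),
        serum_value=serum,
        cgm_value=cgm,
        delta_seconds=delta,
        postop_day=day,
    )


def make_pairs(values: list[tuple[float, float]], day: int = 2) -> list[MatchedPair]:
    return [
        make_pair(s, c, day=day, t=T0 + timedelta(days=day - 1, minutes=i))
        for i, (s, c) in enumerate(values)
    ]


def tiny_cohort() -> Cohort:
    """Two patients, hand-built: serum draws, CGM readings, one POC value."""
    p1 = PatientRecord("A", T0, T0)
    p2 = PatientRecord(
        "B",
        T0,
        T0,
        drug_dose_times=[T0 + timedelta(days=3, hours=9)],
    )
    samples = [
        GlucoseSample("A", T0 + timedelta(hours=1), 100.0, Source.SERUM),
        GlucoseSample("A", T0 + timedelta(hours=1, minutes=2), 110.0, Source.CGM),
        GlucoseSample("A", T0 + timedelta(hours=1, minutes=30), 95.0, Source.POC),
        GlucoseSample("B", T0 + timedelta(hours=2), 120.0, Source.SERUM),
        GlucoseSample("B", T0 + timedelta(hours=2, minutes=4), 100.0, Source.CGM),
    ]
    return Cohort(patients=[p1, p2], samples=samples)


@pytest.fixture
def small_sim() -> tuple[Cohort, "object"]:
    """A small but fully structured simulated cohort (3 patients, 3 days)."""
    cfg = SimulationConfig(n_patients=3, days=3, seed=7, drug_start_days=(2,))
    return simulate_cohort(cfg)
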
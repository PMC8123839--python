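"""Domain data model for paired ICU glucose measurements.

Everything downstream (pairing, accuracy statistics, Clarke grid, the
synthetic generator) speaks in terms of three records:

* :class:`GlucoseSample` — one timestamped glucose measurement on one of
  three channels: laboratory serum draws (the reference), point-of-care
  fingersticks (kept for completeness, never paired) and 5-minute CGM
  readings (the device under test).
* :class:`PatientRecord` — per-patient event metadata: sensor activation,
  end of surgery, interference-drug dose times, whole-patient exclusion.
* :class:`Cohort` — the bundle of patients plus all their samples.

All glucose values are mg/dL; timestamps are timezone-naive datetimes at
second resolution (single-site ICU data, no cross-zone arithmetic).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timedelta


class Source(str, enum.Enum):
    """Measurement channel of a glucose sample."""

    SERUM = "serum"
    POC = "poc"
    CGM = "cgm"


class CohortValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(slots=True)
class GlucoseSample:
    patient_id: str
    timestamp: datetime
    value: float  # mg/dL
    source: Source

    def validate(self) -> None:
        if not (0.0 < self.value < 1000.0):
            raise CohortValidationError(
                f"glucose value {self.value!r} outside (0, 1000) mg/dL"
            )
        if not isinstance(self.timestamp, datetime):
            raise CohortValidationError(f"timestamp {self.timestamp!r} is not a datetime")


@dataclass(slots=True)
class PatientRecord:
    patient_id: str
    sensor_start: datetime
    surgery_end: datetime
    drug_dose_times: list[datetime] = field(default_factory=list)
    excluded_entirely: bool = False
    exclusion_reason: str | None = None

    def validate(self) -> None:
        if self.sensor_start < self.surgery_end - timedelta(hours=24):
            raise CohortValidationError(
                f"patient {self.patient_id}: sensor_start more than 24 h before surgery_end"
            )
        if any(a > b for a, b in zip(self.drug_dose_times, self.drug_dose_times[1:])):
            raise CohortValidationError(
                f"patient {self.patient_id}: drug_dose_times not sorted ascending"
            )


@dataclass
class Cohort:
    patients: list[PatientRecord]
    samples: list[GlucoseSample]

    def patient_ids(self) -> set[str]:
        return {p.patient_id for p in self.patients}

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def samples_for(self, patient_id: str, source: Source | None = None) -> list[GlucoseSample]:
        return [
            s
            for s in self.samples
            if s.patient_id == patient_id and (source is None or s.source == source)
        ]

    def validate(self) -> None:
        """Check every cohort invariant; raise on the first violation.

        Per-patient CGM streams must be spaced at least one minute apart —
        a finer cadence would indicate duplicated sensor rows.
        """
        known = self.patient_ids()
        for p in self.patients:
            p.validate()
        last_cgm: dict[str, datetime] = {}
        for s in sorted(self.samples, key=lambda s: (s.patient_id, s.source.value, s.timestamp)):
            s.validate()
            if s.patient_id not in known:
                raise CohortValidationError(
                    f"sample references unknown patient {s.patient_id!r}"
                )
            if s.source == Source.CGM:
                prev = last_cgm.get(s.patient_id)
                if prev is not None and (s.timestamp - prev) < timedelta(minutes=1):
                    raise CohortValidationError(
                        f"patient {s.patient_id}: CGM readings closer than 1 minute "
                        f"({prev} -> {s.timestamp})"
                    )
                last_cgm[s.patient_id] = s.timestamp

    def __len__(self) -> int:
        return len(self.samples)
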
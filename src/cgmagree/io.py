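"""CSV readers and writers for the long-format measurement and patient tables.

Two companion files describe a cohort:

``samples.csv``  — columns ``patient_id, timestamp, value_mg_dl, source``;
one row per glucose measurement, timestamps ISO 8601 at second resolution.

``patients.csv`` — columns ``patient_id, sensor_start, surgery_end,
drug_dose_times, excluded_entirely, exclusion_reason``; dose times are a
semicolon-separated list of ISO timestamps.

Column names and the input unit are configurable through :class:`CsvDialect`
(optionally loaded from YAML).  mmol/L inputs are converted to mg/dL at read
time (× 18.016); everything downstream is mg/dL.

Validation is total: every malformed row produces a warning-level diagnostic
naming the row, and is dropped (or raised, with ``on_bad_row="raise"``) —
never silently ignored.  ``read ∘ write`` is the identity on valid cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path

import pandas as pd
import yaml

from .model import Cohort, CohortValidationError, GlucoseSample, PatientRecord, Source

logger = logging.getLogger(__name__)

MMOL_TO_MGDL = 18.016

_TIME_FMT = "%Y-%m-%dT%H:%M:%S"


class FormatError(ValueError):
    """The file as a whole does not match the expected table layout."""


class RowError(ValueError):
    """A single row is malformed (used with ``on_bad_row='raise'``)."""


@dataclass(frozen=True)
class CsvDialect:
    """Column-name mapping and unit for the two cohort CSVs."""

    patient_id: str = "patient_id"
    timestamp: str = "timestamp"
    value: str = "value_mg_dl"
    source: str = "source"
    unit: str = "mg/dL"  # or "mmol/L": converted on read

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CsvDialect":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {"patient_id", "timestamp", "value", "source", "unit"}
        unknown = set(raw) - allowed
        if unknown:
            raise FormatError(f"unknown dialect keys in {path}: {sorted(unknown)}")
        return cls(**raw)


def _parse_time(text: str) -> datetime:
    return datetime.fromisoformat(str(text).strip())


def _fmt_time(t: datetime) -> str:
    return t.strftime(_TIME_FMT)


def _parse_bool(text) -> bool:
    s = str(text).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no", "", "nan"}:
        return False
    raise ValueError(f"not a boolean: {text!r}")


def read_samples(
    samples_path: str | Path,
    patients_path: str | Path,
    dialect: CsvDialect | None = None,
    on_bad_row: str = "warn",
) -> Cohort:
    """Read the two cohort CSVs and return a validated :class:`Cohort`.

    Rows violating an invariant (unparseable timestamp, non-positive or
    out-of-range value, unknown source) are rejected with a diagnostic that
    names the offending row; ``on_bad_row="raise"`` escalates the first such
    diagnostic to :class:`RowError`.  A missing column raises
    :class:`FormatError` naming the column.
    """
    if on_bad_row not in {"warn", "raise"}:
        raise ValueError("on_bad_row must be 'warn' or 'raise'")
    d = dialect or CsvDialect()

    sdf = pd.read_csv(samples_path, dtype=str, keep_default_na=False)
    for col in (d.patient_id, d.timestamp, d.value, d.source):
        if col not in sdf.columns:
            raise FormatError(f"{samples_path}: missing required column {col!r}")

    scale = MMOL_TO_MGDL if d.unit.lower().startswith("mmol") else 1.0
    samples: list[GlucoseSample] = []
    for i, row in enumerate(sdf.itertuples(index=False)):
        row = dict(zip(sdf.columns, row))
        try:
            ts = _parse_time(row[d.timestamp])
        except ValueError:
            _bad_row(samples_path, i, f"unparseable timestamp {row[d.timestamp]!r}", on_bad_row)
            continue
        try:
            value = float(row[d.value]) * scale
        except ValueError:
            _bad_row(samples_path, i, f"non-numeric value {row[d.value]!r}", on_bad_row)
            continue
        if not (0.0 < value < 1000.0):
            _bad_row(samples_path, i, f"value {value} outside (0, 1000) mg/dL", on_bad_row)
            continue
        try:
            source = Source(row[d.source].strip().lower())
        except ValueError:
            _bad_row(samples_path, i, f"unknown source {row[d.source]!r}", on_bad_row)
            continue
        samples.append(GlucoseSample(str(row[d.patient_id]), ts, value, source))

    pdf = pd.read_csv(patients_path, dtype=str, keep_default_na=False)
    required = {"patient_id", "sensor_start", "surgery_end", "drug_dose_times", "excluded_entirely"}
    missing = required - set(pdf.columns)
    if missing:
        raise FormatError(f"{patients_path}: missing required column(s) {sorted(missing)}")

    patients: list[PatientRecord] = []
    for i, row in enumerate(pdf.itertuples(index=False)):
        row = dict(zip(pdf.columns, row))
        try:
            doses = [
                _parse_time(tok) for tok in str(row["drug_dose_times"]).split(";") if tok.strip()
            ]
            rec = PatientRecord(
                patient_id=str(row["patient_id"]),
                sensor_start=_parse_time(row["sensor_start"]),
                surgery_end=_parse_time(row["surgery_end"]),
                drug_dose_times=doses,
                excluded_entirely=_parse_bool(row["excluded_entirely"]),
                exclusion_reason=(str(row.get("exclusion_reason", "")).strip() or None),
            )
            rec.validate()
        except (ValueError, CohortValidationError) as exc:
            _bad_row(patients_path, i, str(exc), on_bad_row)
            continue
        patients.append(rec)

    cohort = Cohort(patients=patients, samples=samples)
    cohort.validate()
    return cohort


def _bad_row(path, index: int, message: str, on_bad_row: str) -> None:
    diag = f"{path}: row {index}: {message}"
    if on_bad_row == "raise":
        raise RowError(diag)
    logger.warning("%s (row dropped)", diag)


def write_samples(
    cohort: Cohort,
    samples_path: str | Path,
    patients_path: str | Path,
    dialect: CsvDialect | None = None,
) -> None:
    """Write the two cohort CSVs in the dialect :func:`read_samples` accepts.

    Output is always mg/dL regardless of the dialect's input unit, so the
    written files round-trip exactly.
    """
    d = dialect or CsvDialect()
    if d.unit.lower().startswith("mmol"):
        d = replace(d, unit="mg/dL")

    sdf = pd.DataFrame(
        {
            d.patient_id: [s.patient_id for s in cohort.samples],
            d.timestamp: [_fmt_time(s.timestamp) for s in cohort.samples],
            d.value: [_fmt_value(s.value) for s in cohort.samples],
            d.source: [s.source.value for s in cohort.samples],
        }
    )
    sdf.to_csv(samples_path, index=False)

    pdf = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort.patients],
            "sensor_start": [_fmt_time(p.sensor_start) for p in cohort.patients],
            "surgery_end": [_fmt_time(p.surgery_end) for p in cohort.patients],
            "drug_dose_times": [
                ";".join(_fmt_time(t) for t in p.drug_dose_times) for p in cohort.patients
            ],
            "excluded_entirely": [str(p.excluded_entirely).lower() for p in cohort.patients],
            "exclusion_reason": [p.exclusion_reason or "" for p in cohort.patients],
        }
    )
    pdf.to_csv(patients_path, index=False)


def _fmt_value(v: float) -> str:
    # repr round-trips floats exactly; integers print without trailing .0
    return str(int(v)) if float(v).is_integer() else repr(float(v))
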
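"""Time-matched serum–CGM pairing and exclusion filtering.

Each laboratory serum draw is matched to the closest CGM reading within a
tolerance window (default ±300 s, i.e. the five minutes before or after the
draw).  Matching is one-to-one: serum draws are processed in time order and a
CGM reading already consumed by an earlier draw is skipped, so no sensor
reading serves as evidence twice.  Ties at equal |Δt| go to the earlier CGM
reading.

Post-operative day ``k`` is the half-open 24-hour block
``[(k-1)·24 h, k·24 h)`` measured from a per-patient anchor — sensor
activation by default, since sensor age is what drives the day-1 "warm-up"
inaccuracy; the end of surgery is available as an alternative anchor.

Exclusion windows express the analysis filters: the day-1 warm-up period, an
open-ended interference window from the first dose of an interfering drug
(e.g. hydroxyurea), and whole-patient exclusions (e.g. dialysis).  Window
starts are inclusive, finite ends exclusive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from .model import Cohort, PatientRecord, Source

WINDOW_SECONDS_DEFAULT = 300

DAY_ANCHORS = ("sensor_start", "surgery_end")


class ExclusionReason(str, enum.Enum):
    WARMUP_DAY1 = "warmup_day1"
    DRUG_INTERFERENCE = "drug_interference"
    PATIENT_EXCLUDED = "patient_excluded"


@dataclass(slots=True)
class MatchedPair:
    """One serum draw joined to its nearest in-window CGM reading."""

    patient_id: str
    serum_time: datetime
    cgm_time: datetime
    serum_value: float  # mg/dL
    cgm_value: float  # mg/dL
    delta_seconds: float  # signed, cgm_time - serum_time
    postop_day: int  # >= 1


@dataclass(slots=True)
class ExclusionWindow:
    """Per-patient time interval removed from analysis.

    ``start=None`` / ``end=None`` denote open-ended bounds (a whole-patient
    exclusion is open on both sides).
    """

    patient_id: str
    start: datetime | None
    end: datetime | None
    reason: ExclusionReason

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None and not (self.start < self.end):
            raise ValueError(f"exclusion window start {self.start} not before end {self.end}")

    def contains(self, t: datetime) -> bool:
        if self.start is not None and t < self.start:
            return False
        if self.end is not None and t >= self.end:
            return False
        return True


@dataclass
class MatchResult:
    """Pairs produced by :func:`match_pairs` plus matching bookkeeping."""

    pairs: list[MatchedPair]
    dropped_serum: int  # serum draws with no CGM reading in the window

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def day_anchor_time(patient: PatientRecord, anchor: str = "sensor_start") -> datetime:
    if anchor not in DAY_ANCHORS:
        raise ValueError(f"anchor must be one of {DAY_ANCHORS}, got {anchor!r}")
    return patient.sensor_start if anchor == "sensor_start" else patient.surgery_end


def assign_postop_day(
    sample_time: datetime, patient: PatientRecord, anchor: str = "sensor_start"
) -> int:
    """Post-op day index (1-based, half-open 24 h blocks from the anchor)."""
    ref = day_anchor_time(patient, anchor)
    elapsed = (sample_time - ref).total_seconds()
    if elapsed < 0:
        raise ValueError(
            f"sample at {sample_time} precedes day anchor {ref} for patient {patient.patient_id}"
        )
    return int(elapsed // 86400) + 1


def match_pairs(
    cohort: Cohort,
    window_seconds: int = WINDOW_SECONDS_DEFAULT,
    anchor: str = "sensor_start",
) -> MatchResult:
    """Match every serum draw to its nearest CGM reading within ±window_seconds.

    The window boundary is inclusive (|Δt| = window_seconds still matches).
    POC fingerstick samples are never paired.  Output is sorted by
    (patient_id, serum_time); serum draws with no available in-window reading
    are dropped and counted.
    """
    if window_seconds < 0:
        raise ValueError("window_seconds must be non-negative")
    pairs: list[MatchedPair] = []
    dropped = 0

    by_patient: dict[str, tuple[list, list]] = {}
    for s in cohort.samples:
        if s.source == Source.SERUM:
            by_patient.setdefault(s.patient_id, ([], []))[0].append(s)
        elif s.source == Source.CGM:
            by_patient.setdefault(s.patient_id, ([], []))[1].append(s)

    for pid in sorted(by_patient):
        serum, cgm = by_patient[pid]
        if not serum or not cgm:
            dropped += len(serum)
            continue
        patient = cohort.patient(pid)
        serum.sort(key=lambda s: s.timestamp)
        cgm.sort(key=lambda s: s.timestamp)
        cgm_t = np.array([_epoch_seconds(s.timestamp) for s in cgm])
        consumed = np.zeros(len(cgm), dtype=bool)

        for draw in serum:
            t = _epoch_seconds(draw.timestamp)
            j = _nearest_free(cgm_t, consumed, t, window_seconds)
            if j is None:
                dropped += 1
                continue
            consumed[j] = True
            reading = cgm[j]
            pairs.append(
                MatchedPair(
                    patient_id=pid,
                    serum_time=draw.timestamp,
                    cgm_time=reading.timestamp,
                    serum_value=draw.value,
                    cgm_value=reading.value,
                    delta_seconds=(reading.timestamp - draw.timestamp).total_seconds(),
                    postop_day=assign_postop_day(draw.timestamp, patient, anchor),
                )
            )

    pairs.sort(key=lambda p: (p.patient_id, p.serum_time))
    return MatchResult(pairs=pairs, dropped_serum=dropped)


_EPOCH = datetime(1970, 1, 1)


def _epoch_seconds(t: datetime) -> float:
    # naive-datetime arithmetic; independent of the process timezone
    return (t - _EPOCH).total_seconds()


def _nearest_free(cgm_t: np.ndarray, consumed: np.ndarray, t: float, window: float) -> int | None:
    """Index of the nearest unconsumed CGM time within ±window of t, ties earlier."""
    pos = int(np.searchsorted(cgm_t, t))
    left = pos - 1
    while left >= 0 and consumed[left]:
        left -= 1
    right = pos
    n = len(cgm_t)
    while right < n and consumed[right]:
        right += 1
    dl = t - cgm_t[left] if left >= 0 else np.inf
    dr = cgm_t[right] - t if right < n else np.inf
    if dl > window and dr > window:
        return None
    # tie at equal |delta| -> earlier reading (the left candidate)
    if dl <= dr:
        return left if dl <= window else None
    return right if dr <= window else None


def build_exclusions(
    patients: list[PatientRecord],
    exclude_day1: bool = True,
    anchor: str = "sensor_start",
) -> list[ExclusionWindow]:
    """Construct the per-patient exclusion windows from event metadata.

    Per patient: a day-1 warm-up window when ``exclude_day1``; one open-ended
    drug-interference window starting (inclusively) at the first dose time
    when any doses exist; a whole-record window when the patient is excluded
    entirely.
    """
    windows: list[ExclusionWindow] = []
    for p in patients:
        if p.excluded_entirely:
            windows.append(
                ExclusionWindow(p.patient_id, None, None, ExclusionReason.PATIENT_EXCLUDED)
            )
        if exclude_day1:
            ref = day_anchor_time(p, anchor)
            windows.append(
                ExclusionWindow(
                    p.patient_id, ref, ref + timedelta(hours=24), ExclusionReason.WARMUP_DAY1
                )
            )
        if p.drug_dose_times:
            windows.append(
                ExclusionWindow(
                    p.patient_id,
                    min(p.drug_dose_times),
                    None,
                    ExclusionReason.DRUG_INTERFERENCE,
                )
            )
    return windows


# a pair caught by several windows is tallied under the most severe reason
_REASON_PRECEDENCE = (
    ExclusionReason.PATIENT_EXCLUDED,
    ExclusionReason.WARMUP_DAY1,
    ExclusionReason.DRUG_INTERFERENCE,
)


def apply_exclusions(
    pairs: list[MatchedPair], windows: list[ExclusionWindow]
) -> tuple[list[MatchedPair], dict[ExclusionReason, int]]:
    """Partition pairs into (kept, removed-count-by-reason).

    A pair is removed iff its serum time falls inside any window for its
    patient.  Order of the kept list is preserved; counts conserve:
    ``len(kept) + sum(removed.values()) == len(pairs)``.
    """
    by_patient: dict[str, list[ExclusionWindow]] = {}
    for w in windows:
        by_patient.setdefault(w.patient_id, []).append(w)
    for ws in by_patient.values():
        ws.sort(key=lambda w: _REASON_PRECEDENCE.index(w.reason))

    kept: list[MatchedPair] = []
    removed: dict[ExclusionReason, int] = {}
    for pair in pairs:
        for w in by_patient.get(pair.patient_id, ()):
            if w.contains(pair.serum_time):
                removed[w.reason] = removed.get(w.reason, 0) + 1
                break
        else:
            kept.append(pair)
    return kept, removed
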
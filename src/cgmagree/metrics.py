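"""Device-agreement statistics for matched serum–CGM glucose pairs.

Conventions used throughout (the field's standard ones for CGM accuracy
studies):

* The serum laboratory value is the reference; the difference is
  ``CGM − serum``, so a positive mean difference reads as the sensor
  over-reporting.
* MAD is the mean of |CGM − serum| in mg/dL (sample SD, n−1 denominator);
  MARD is ``100 · mean(|CGM − serum| / serum)`` in percent.
* %20/20 (and %15/15): a pair qualifies when the CGM reading is within 20%
  of the reference if the reference exceeds 100 mg/dL, or within 20 mg/dL if
  the reference is at most 100 mg/dL.  All qualification boundaries are
  inclusive.
* Goal range is 70–140 mg/dL inclusive; out-of-range is <70 or >140.
* Quantiles use linear interpolation between order statistics; reported
  percentages round to the nearest integer (the unrounded value is retained
  internally).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .pairing import MatchedPair

GOAL_RANGE_MGDL = (70.0, 140.0)
PCT_CUTOVER_MGDL = 100.0
REPORT_BANDS_MGDL = (10, 15, 20)


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is requested for an empty set of pairs."""


def _arrays(pairs: list[MatchedPair]) -> tuple[np.ndarray, np.ndarray]:
    if not pairs:
        raise UndefinedStatisticError("statistic undefined for an empty set of pairs")
    serum = np.array([p.serum_value for p in pairs], dtype=float)
    cgm = np.array([p.cgm_value for p in pairs], dtype=float)
    return serum, cgm


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (reporting rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def format_count_pct(count: int, n: int) -> str:
    """Render a count cell as ``"134 (73%)"``."""
    return f"{count} ({round_half_up(100.0 * count / n)}%)"


def mad(pairs: list[MatchedPair]) -> tuple[float, float]:
    """Mean absolute difference |CGM − serum| in mg/dL, with its sample SD."""
    serum, cgm = _arrays(pairs)
    ad = np.abs(cgm - serum)
    sd = float(np.std(ad, ddof=1)) if len(ad) > 1 else 0.0
    return float(np.mean(ad)), sd


def mard(pairs: list[MatchedPair]) -> float:
    """Mean absolute relative difference, percent; serum is the denominator."""
    serum, cgm = _arrays(pairs)
    return float(100.0 * np.mean(np.abs(cgm - serum) / serum))


@dataclass(frozen=True)
class DiffStats:
    mean: float
    sd: float
    median: float
    q25: float
    q75: float


def signed_diff_stats(pairs: list[MatchedPair]) -> DiffStats:
    """Mean/SD/median/IQR of the signed difference CGM − serum (mg/dL)."""
    serum, cgm = _arrays(pairs)
    d = cgm - serum
    q25, q50, q75 = np.quantile(d, [0.25, 0.5, 0.75])  # linear interpolation
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    return DiffStats(float(np.mean(d)), sd, float(q50), float(q25), float(q75))


def within_band(pairs: list[MatchedPair], band_mg_dl: float) -> tuple[int, float]:
    """Count and percent of pairs with |CGM − serum| ≤ band (inclusive)."""
    if band_mg_dl <= 0:
        raise ValueError("band must be positive")
    serum, cgm = _arrays(pairs)
    count = int(np.sum(np.abs(cgm - serum) <= band_mg_dl))
    return count, 100.0 * count / len(pairs)


def pct_k_k(
    pairs: list[MatchedPair],
    k_percent: float,
    k_mg_dl: float,
    cutover: float = PCT_CUTOVER_MGDL,
) -> tuple[int, float]:
    """%k/k accuracy: relative band above the cutover, absolute band at or below.

    A pair qualifies iff serum > cutover and |CGM − serum| ≤ (k_percent/100)·serum,
    or serum ≤ cutover and |CGM − serum| ≤ k_mg_dl.  Boundaries inclusive.
    """
    if k_percent <= 0 or k_mg_dl <= 0:
        raise ValueError("k_percent and k_mg_dl must be positive")
    serum, cgm = _arrays(pairs)
    ad = np.abs(cgm - serum)
    ok = np.where(serum > cutover, ad <= (k_percent / 100.0) * serum, ad <= k_mg_dl)
    count = int(np.sum(ok))
    return count, 100.0 * count / len(pairs)


@dataclass(frozen=True)
class RangeClassification:
    n: int
    in_goal: int
    out_of_range: int
    in_goal_pct: float
    out_of_range_pct: float


def classify_goal_range(
    values, low: float = GOAL_RANGE_MGDL[0], high: float = GOAL_RANGE_MGDL[1]
) -> RangeClassification:
    """Split glucose values into goal range [low, high] vs out-of-range."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise UndefinedStatisticError("goal-range classification undefined for no values")
    if np.any(v <= 0):
        raise ValueError("glucose values must be positive")
    in_goal = int(np.sum((v >= low) & (v <= high)))
    out = int(v.size - in_goal)
    return RangeClassification(
        n=int(v.size),
        in_goal=in_goal,
        out_of_range=out,
        in_goal_pct=100.0 * in_goal / v.size,
        out_of_range_pct=100.0 * out / v.size,
    )


@dataclass(frozen=True)
class AccuracyReport:
    """The full agreement-statistics bundle for one set of matched pairs."""

    n_pairs: int
    mad: float
    mad_sd: float
    mard: float
    mean_diff: float
    diff_sd: float
    median_diff: float
    diff_iqr: tuple[float, float]
    within_bands: dict[int, tuple[int, float]]  # band mg/dL -> (count, percent)
    pct2020: tuple[int, float]
    pct1515: tuple[int, float]
    serum_range: tuple[float, float]
    cgm_range: tuple[float, float]
    serum_goal: RangeClassification
    cgm_goal: RangeClassification

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "mad_mg_dl": self.mad,
            "mad_sd_mg_dl": self.mad_sd,
            "mard_pct": self.mard,
            "mean_diff_mg_dl": self.mean_diff,
            "diff_sd_mg_dl": self.diff_sd,
            "median_diff_mg_dl": self.median_diff,
            "diff_iqr_mg_dl": list(self.diff_iqr),
            "within_bands": {
                str(b): {"count": c, "percent": p} for b, (c, p) in self.within_bands.items()
            },
            "pct2020": {"count": self.pct2020[0], "percent": self.pct2020[1]},
            "pct1515": {"count": self.pct1515[0], "percent": self.pct1515[1]},
            "serum_range_mg_dl": list(self.serum_range),
            "cgm_range_mg_dl": list(self.cgm_range),
            "serum_in_goal_pct": self.serum_goal.in_goal_pct,
            "cgm_in_goal_pct": self.cgm_goal.in_goal_pct,
        }


def compute_report(pairs: list[MatchedPair]) -> AccuracyReport:
    serum, cgm = _arrays(pairs)
    m, m_sd = mad(pairs)
    ds = signed_diff_stats(pairs)
    return AccuracyReport(
        n_pairs=len(pairs),
        mad=m,
        mad_sd=m_sd,
        mard=mard(pairs),
        mean_diff=ds.mean,
        diff_sd=ds.sd,
        median_diff=ds.median,
        diff_iqr=(ds.q25, ds.q75),
        within_bands={b: within_band(pairs, b) for b in REPORT_BANDS_MGDL},
        pct2020=pct_k_k(pairs, 20, 20),
        pct1515=pct_k_k(pairs, 15, 15),
        serum_range=(float(serum.min()), float(serum.max())),
        cgm_range=(float(cgm.min()), float(cgm.max())),
        serum_goal=classify_goal_range(serum),
        cgm_goal=classify_goal_range(cgm),
    )


def report(
    pairs: list[MatchedPair], by_day: bool = True
) -> tuple[AccuracyReport, dict[int, AccuracyReport]]:
    """Overall report plus, when ``by_day``, one report per post-op day present.

    A day with no pairs is simply absent from the map (with a warning when the
    surrounding days are present, since a gap usually means an upstream filter
    removed an entire stratum).
    """
    overall = compute_report(pairs)
    per_day: dict[int, AccuracyReport] = {}
    if by_day:
        days = sorted({p.postop_day for p in pairs})
        for d in range(days[0], days[-1] + 1):
            subset = [p for p in pairs if p.postop_day == d]
            if not subset:
                warnings.warn(f"post-op day {d} has zero pairs; omitted from by-day report")
                continue
            per_day[d] = compute_report(subset)
    return overall, per_day
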
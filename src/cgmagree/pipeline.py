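"""End-to-end analysis pipeline: read → pair → filter → summarise → report.

The pipeline mirrors how CGM accuracy studies report their results: one
agreement-statistics table over all post-operative days, a separate table for
days 2 onward (day 1 is the sensor warm-up period), per-day MARD, goal-range
classification of both channels, and a Clarke Error Grid summary of the
day-2+ pairs.  A run manifest records stage counts (samples read, pairs
matched, pairs excluded by reason, pairs analysed) that must conserve, plus
input digests and the configuration, so identical inputs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .clarke import ClarkeResult, clarke_summary, clarke_zones, plot_clarke
from .io import CsvDialect, read_samples
from .metrics import (
    AccuracyReport,
    UndefinedStatisticError,
    format_count_pct,
    report,
    round_half_up,
)
from .model import Cohort, Source
from .pairing import (
    ExclusionReason,
    MatchedPair,
    apply_exclusions,
    build_exclusions,
    match_pairs,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """The pipeline cannot produce a report (e.g. no analyzable pairs)."""


@dataclass(frozen=True)
class PipelineConfig:
    window_seconds: int = 300
    exclude_day1: bool = True
    max_day: int = 7
    day_anchor: str = "sensor_start"
    make_plots: bool = False


@dataclass
class AnalysisBundle:
    """In-memory results of one pipeline run."""

    pairs_all_days: list[MatchedPair]  # after patient/drug exclusions, ≤ max_day
    pairs_analyzed: list[MatchedPair]  # additionally minus warm-up day when excluded
    n_matched: int  # pairs produced by matching, before any exclusion
    n_beyond_max_day: int
    dropped_serum: int  # serum draws with no in-window CGM reading
    removed_by_reason: dict[ExclusionReason, int]
    overall: AccuracyReport  # all retained days (1..max_day)
    primary: AccuracyReport  # the analysis set (days 2+ when day 1 excluded)
    per_day: dict[int, AccuracyReport]
    clarke: ClarkeResult  # on the analysis set
    config: PipelineConfig

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "counts": {
                "pairs_matched": self.n_matched,
                "serum_dropped_no_cgm": self.dropped_serum,
                "pairs_beyond_max_day": self.n_beyond_max_day,
                "pairs_all_days": len(self.pairs_all_days),
                "pairs_analyzed": len(self.pairs_analyzed),
                "removed_by_reason": {r.value: c for r, c in self.removed_by_reason.items()},
            },
            "overall_days_1_to_max": self.overall.to_dict(),
            "analysis_set": self.primary.to_dict(),
            "per_day": {str(d): r.to_dict() for d, r in self.per_day.items()},
            "clarke_analysis_set": self.clarke.to_dict(),
        }


def analyze_cohort(cohort: Cohort, config: PipelineConfig | None = None) -> AnalysisBundle:
    """Run pairing, exclusions and all summaries on an in-memory cohort."""
    cfg = config or PipelineConfig()
    result = match_pairs(cohort, window_seconds=cfg.window_seconds, anchor=cfg.day_anchor)

    # patient-level and drug exclusions apply to every analysis; the warm-up
    # day is removed only from the primary (day-2+) analysis set
    windows = build_exclusions(cohort.patients, exclude_day1=False, anchor=cfg.day_anchor)
    pairs, removed = apply_exclusions(result.pairs, windows)
    n_over_max = sum(1 for p in pairs if p.postop_day > cfg.max_day)
    pairs = [p for p in pairs if p.postop_day <= cfg.max_day]

    if cfg.exclude_day1:
        warm = build_exclusions(cohort.patients, exclude_day1=True, anchor=cfg.day_anchor)
        warm = [w for w in warm if w.reason == ExclusionReason.WARMUP_DAY1]
        analyzed, removed_warm = apply_exclusions(pairs, warm)
        removed = {**removed, **removed_warm}
    else:
        analyzed = pairs

    if not analyzed:
        raise PipelineError("no analyzable pairs after matching and exclusions")

    overall, per_day = report(pairs, by_day=True)
    primary, _ = report(analyzed, by_day=False)
    bundle = AnalysisBundle(
        pairs_all_days=pairs,
        pairs_analyzed=analyzed,
        n_matched=len(result.pairs),
        n_beyond_max_day=n_over_max,
        dropped_serum=result.dropped_serum,
        removed_by_reason=removed,
        overall=overall,
        primary=primary,
        per_day=per_day,
        clarke=clarke_summary(analyzed),
        config=cfg,
    )
    logger.info(
        "matched %d pairs (%d serum draws unmatched/out-of-span); analyzing %d",
        len(result.pairs),
        bundle.dropped_serum,
        len(analyzed),
    )
    return bundle


@dataclass
class RunManifest:
    samples_read: int
    serum_samples: int
    cgm_samples: int
    pairs_matched: int
    serum_dropped: int
    pairs_excluded_by_reason: dict[str, int]
    pairs_analyzed: int
    input_digests: dict[str, str]
    config: dict
    version: str

    def check_conservation(self) -> None:
        excluded = sum(self.pairs_excluded_by_reason.values())
        if self.pairs_matched != self.pairs_analyzed + excluded:
            raise PipelineError(
                f"manifest counts do not conserve: matched {self.pairs_matched} != "
                f"analyzed {self.pairs_analyzed} + excluded {excluded}"
            )
        if self.samples_read < self.pairs_matched:
            raise PipelineError("more pairs than samples read")

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    samples_path: str | Path,
    patients_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    dialect: CsvDialect | None = None,
) -> RunManifest:
    """Run the full pipeline from CSVs to a report bundle on disk.

    Writes ``pairs.csv`` (with Clarke zone labels), ``report.json``,
    ``manifest.json``, ``tables.txt`` and optionally ``clarke.png`` under
    ``out_dir``.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = read_samples(samples_path, patients_path, dialect=dialect)
    bundle = analyze_cohort(cohort, cfg)

    zones = clarke_zones(
        [p.serum_value for p in bundle.pairs_all_days],
        [p.cgm_value for p in bundle.pairs_all_days],
    )
    with open(out / "pairs.csv", "w") as fh:
        fh.write(
            "patient_id,serum_time,cgm_time,serum_value_mg_dl,"
            "cgm_value_mg_dl,delta_seconds,postop_day,clarke_zone\n"
        )
        for p, z in zip(bundle.pairs_all_days, zones):
            fh.write(
                f"{p.patient_id},{p.serum_time.isoformat()},{p.cgm_time.isoformat()},"
                f"{p.serum_value:g},{p.cgm_value:g},{p.delta_seconds:g},{p.postop_day},{z}\n"
            )

    report_json = json.dumps(bundle.to_dict(), indent=2, sort_keys=True)
    (out / "report.json").write_text(report_json + "\n")
    (out / "tables.txt").write_text(render_tables(bundle))

    excluded = {r.value: c for r, c in bundle.removed_by_reason.items()}
    if bundle.n_beyond_max_day:
        excluded["beyond_max_day"] = bundle.n_beyond_max_day
    manifest = RunManifest(
        samples_read=len(cohort.samples),
        serum_samples=sum(1 for s in cohort.samples if s.source == Source.SERUM),
        cgm_samples=sum(1 for s in cohort.samples if s.source == Source.CGM),
        pairs_matched=bundle.n_matched,
        serum_dropped=bundle.dropped_serum,
        pairs_excluded_by_reason=excluded,
        pairs_analyzed=len(bundle.pairs_analyzed),
        input_digests={
            "samples": _sha256(Path(samples_path)),
            "patients": _sha256(Path(patients_path)),
        },
        config=asdict(cfg),
        version=__version__,
    )
    manifest.check_conservation()
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n")

    if cfg.make_plots:
        plot_clarke(bundle.pairs_analyzed, out / "clarke.png")
    return manifest


# --- paper-shaped text tables -------------------------------------------------

_MARD_TABLE_TITLE = "MARD overall and by day(s)"
_ACC_TABLE_TITLE = "CGM vs serum glucose, analysis set"


def render_tables(bundle: AnalysisBundle) -> str:
    """Render the MARD-by-day and agreement-statistics tables as aligned text."""
    rows: list[tuple[str, str]] = [("Overall", f"{bundle.overall.mard:.1f}%")]
    for d, rep in sorted(bundle.per_day.items()):
        rows.append((f"Day {d}", f"{rep.mard:.1f}%"))

    r = bundle.primary
    acc_rows = [
        ("n", str(r.n_pairs)),
        ("Mean absolute difference (MAD) ± SD", f"{r.mad:.1f} ± {r.mad_sd:.1f}"),
        ("Mean absolute relative difference (MARD)", f"{r.mard:.1f}%"),
        ("Mean difference ± Standard Deviation", f"{r.mean_diff:.1f} ± {r.diff_sd:.1f}"),
        (
            "Median difference (Interquartile Range)",
            f"{r.median_diff:.1f} ({r.diff_iqr[0]:.1f}, {r.diff_iqr[1]:.1f})",
        ),
        ("Within ± 20 mg/dL", format_count_pct(r.within_bands[20][0], r.n_pairs)),
        ("Within ± 15 mg/dL", format_count_pct(r.within_bands[15][0], r.n_pairs)),
        ("Within ± 10 mg/dL", format_count_pct(r.within_bands[10][0], r.n_pairs)),
        ("%20/20", format_count_pct(r.pct2020[0], r.n_pairs)),
        ("%15/15", format_count_pct(r.pct1515[0], r.n_pairs)),
    ]
    ck = bundle.clarke
    clarke_rows = [(f"Zone {z}", format_count_pct(ck.counts[z], ck.n)) for z in "ABCDE"] + [
        ("Clinically accurate (A)", f"{round_half_up(ck.pct_clinically_accurate)}%"),
        ("Clinically acceptable (A+B)", f"{round_half_up(ck.pct_clinically_acceptable)}%"),
    ]
    return "\n".join(
        [
            _format_block(_MARD_TABLE_TITLE, rows),
            "",
            _format_block(_ACC_TABLE_TITLE, acc_rows),
            "",
            _format_block("Clarke Error Grid, analysis set", clarke_rows),
            "",
        ]
    )


def _format_block(title: str, rows: list[tuple[str, str]]) -> str:
    width = max(len(label) for label, _ in rows)
    lines = [title, "-" * len(title)]
    lines += [f"{label.ljust(width)}  {value}" for label, value in rows]
    return "\n".join(lines)


def parse_tables(text: str) -> dict[str, dict[str, str]]:
    """Parse :func:`render_tables` output back into {table: {label: value}}.

    Inverse of the renderer on its own output; used to verify the tables are a
    faithful view of the report.
    """
    tables: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    lines = text.splitlines()
    for i, line in enumerate(lines):
        if not line.strip() or set(line.strip()) == {"-"}:
            continue
        if i + 1 < len(lines) and set(lines[i + 1].strip() or " ") == {"-"}:
            current = {}
            tables[line.strip()] = current
            continue
        if current is not None:
            m = re.match(r"^(.*?)\s{2,}(.*)$", line)
            if m:
                current[m.group(1).strip()] = m.group(2).strip()
    return tables
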
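"""Summary surfaces and end-to-end pipeline execution.

Produces the analyst-facing outputs of a disproportionality study: the
demographics composition table (counts and half-up two-decimal
percentages per gender / age group / country bucket), the per-pair
statistics table, the signal table, SOC summaries, top-N rankings — each
as deterministic delimited text with a JSON twin — plus ``run_pipeline``,
which composes ingest -> contingency -> statistics -> signal detection ->
reporting from a single configuration.
"""
from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import ingest, synthetic
from .contingency import ContingencyTable, build_all_tables
from .exceptions import ConfigError, PvSignalError
from .records import ReportRecord
from .signals import (
    DEFAULT_EXCLUDED_SOCS,
    SignalRecord,
    SocSummary,
    annotate_label,
    detect_signals,
    exclude_socs,
    rank_signals,
    summarize_by_soc,
)
from .stats import DEFAULT_MIN_COUNT, DEFAULT_Z, BcpnnHyperparams

logger = logging.getLogger("pvsignal")

AGE_BANDS = ("18-49", "50-69", ">=70", "unknown")

#: Default country bucketing: ISO-like codes for the United States and
#: Japan, a European list, everything else (including missing) -> Other.
EUROPE_CODES = frozenset(
    "AT BE BG CH CY CZ DE DK EE ES FI FR GB GR HR HU IE IS IT LT LU LV MT NL "
    "NO PL PT RO SE SI SK".split()
)
DEFAULT_COUNTRY_GROUPS = {"US": "United States", "JP": "Japan"}


def pct_half_up(n: int, total: int) -> float:
    """Composition ratio 100*n/total, rounded half-up to 2 decimals."""
    total = int(total)
    if total == 0:
        return 0.0
    q = (Decimal(100) * Decimal(int(n)) / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


def composition_table(counts: Mapping[str, int], dimension: str = "") -> pd.DataFrame:
    """Counts -> composition-ratio rows (category, n_reports, pct)."""
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "dimension": dimension,
            "category": list(counts),
            "n_reports": list(counts.values()),
            "composition_pct": [pct_half_up(v, total) for v in counts.values()],
        }
    )


def _age_band(age: Optional[float]) -> str:
    if age is None or age < 18:
        return "unknown"
    if age <= 49:
        return "18-49"
    if age <= 69:
        return "50-69"
    return ">=70"


def _country_group(country: Optional[str], groups: Mapping[str, str]) -> str:
    if not country:
        return "Other"
    code = country.strip().upper()
    if code in groups:
        return groups[code]
    if code in EUROPE_CODES:
        return "Europe"
    return "Other"


def summarize_demographics(
    reports: Sequence[ReportRecord],
    *,
    country_groups: Mapping[str, str] = DEFAULT_COUNTRY_GROUPS,
) -> pd.DataFrame:
    """Composition table over gender, age group and country bucket.

    Unknown/missing is always its own category; within each dimension the
    counts sum to the report total and the percentages to ~100.  Empty
    input yields an empty frame.
    """
    if not reports:
        return pd.DataFrame(
            columns=["dimension", "category", "n_reports", "composition_pct"]
        )
    sex_counts = {"Male": 0, "Female": 0, "Unknown or missing": 0}
    for r in reports:
        key = {"male": "Male", "female": "Female"}.get(r.sex, "Unknown or missing")
        sex_counts[key] += 1

    age_counts = {"18-49": 0, "50-69": 0, ">=70": 0, "Unknown or missing": 0}
    for r in reports:
        band = _age_band(r.age_years)
        age_counts[band if band != "unknown" else "Unknown or missing"] += 1

    buckets = list(dict.fromkeys(country_groups.values())) + ["Europe", "Other"]
    country_counts = {b: 0 for b in buckets}
    for r in reports:
        country_counts[_country_group(r.country, country_groups)] += 1

    frames = [
        composition_table(sex_counts, "gender"),
        composition_table(age_counts, "age_group"),
        composition_table(country_counts, "country"),
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# tabular output


def stats_frame(
    tables: Sequence[ContingencyTable], records: Sequence[SignalRecord]
) -> pd.DataFrame:
    """Per-pair statistics table (one row per contingency table)."""
    by_pt = {r.pt_name: r for r in records}
    rows = []
    for t in tables:
        r = by_pt[t.pt_name]
        rows.append(
            {
                "drug": t.drug,
                "pt": t.pt_name,
                "soc": r.soc_name or "",
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "N": t.n_total,
                "ror": r.ror_result.ror,
                "ror_ci_lower": r.ror_result.ci_lower,
                "ror_ci_upper": r.ror_result.ci_upper,
                "ic_raw": r.bcpnn_result.ic_raw,
                "e_ic": r.bcpnn_result.e_ic,
                "ic025": r.bcpnn_result.ic025,
                "zero_corrected": r.ror_result.zero_corrected,
                "is_signal": r.is_signal,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "drug", "pt", "soc", "a", "b", "c", "d", "N", "ror",
            "ror_ci_lower", "ror_ci_upper", "ic_raw", "e_ic", "ic025",
            "zero_corrected", "is_signal",
        ],
    )


def signals_frame(records: Sequence[SignalRecord]) -> pd.DataFrame:
    rows = [
        {
            "drug": r.drug,
            "pt": r.pt_name,
            "soc": r.soc_name or "",
            "a": r.a,
            "ror": r.ror_result.ror,
            "ror_ci_lower": r.ror_result.ci_lower,
            "ror_ci_upper": r.ror_result.ci_upper,
            "ic025": r.bcpnn_result.ic025,
            "in_label": "" if r.in_label is None else bool(r.in_label),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["drug", "pt", "soc", "a", "ror", "ror_ci_lower",
                 "ror_ci_upper", "ic025", "in_label"],
    )


def soc_frame(summaries: Sequence[SocSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"soc": s.soc_name, "n_signal_pts": s.n_signal_pts, "n_reports": s.n_reports}
         for s in summaries],
        columns=["soc", "n_signal_pts", "n_reports"],
    )


def render_outputs(
    frames: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    formats: Iterable[str] = ("tsv", "json"),
) -> list[Path]:
    """Write each named frame as ``<name>.tsv`` and/or ``<name>.json``.

    Outputs are byte-identical across reruns on identical inputs (fixed
    column orders, repr-faithful floats in JSON).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in frames.items():
        if "tsv" in formats:
            p = out_dir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False, lineterminator="\n")
            written.append(p)
        if "json" in formats:
            p = out_dir / f"{name}.json"
            payload = df.to_dict(orient="records")
            p.write_text(json.dumps(payload, indent=2, default=str) + "\n")
            written.append(p)
    return written


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineConfig:
    """Configuration for one end-to-end run.

    Exactly one of ``input_path`` (a delimited extract) or ``synthetic``
    (generate a corpus in-process) must be provided.
    """

    drug: str = ""
    input_path: Optional[str] = None
    synthetic: Optional[synthetic.SyntheticConfig] = None
    delimiter: str = "\t"
    synonym_map: Optional[dict] = None
    start_date: Optional[_dt.date] = None
    end_date: Optional[_dt.date] = None
    dedup: bool = True
    z: float = DEFAULT_Z
    min_count: int = DEFAULT_MIN_COUNT
    hyperparams: BcpnnHyperparams = field(default_factory=BcpnnHyperparams)
    pt_soc_map: Optional[dict] = None
    label_pts: Optional[list] = None
    excluded_socs: tuple = DEFAULT_EXCLUDED_SOCS
    top_n: int = 30
    out_dir: str = "pvsignal_out"
    formats: tuple = ("tsv", "json")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            kwargs["synthetic"] = synthetic.SyntheticConfig(**kwargs["synthetic"])
        if "hyperparams" in kwargs and kwargs["hyperparams"] is not None:
            kwargs["hyperparams"] = BcpnnHyperparams(**kwargs["hyperparams"])
        for key in ("start_date", "end_date"):
            if kwargs.get(key):
                kwargs[key] = _dt.date.fromisoformat(kwargs[key])
        if "excluded_socs" in kwargs and kwargs["excluded_socs"] is not None:
            kwargs["excluded_socs"] = tuple(kwargs["excluded_socs"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    status: int
    stage_counts: dict
    artifacts: list
    records: list
    soc_summaries: list
    demographics: pd.DataFrame


class PipelineStageError(PvSignalError):
    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline failed in stage {stage!r}: {original}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute ingest -> contingency -> statistics -> signals -> report.

    Logs per-stage record counts to stderr; raises
    :class:`PipelineStageError` naming the failed stage.
    """
    if not config.drug:
        raise ConfigError("pipeline config must name the target drug")
    if (config.input_path is None) == (config.synthetic is None):
        raise ConfigError("provide exactly one of input_path or synthetic config")
    counts: dict[str, int] = {}

    def stage(name, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except PvSignalError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineStageError(name, exc) from exc
        return out

    drug = ingest.normalize_drug_name(config.drug, config.synonym_map)
    pt_soc_map = config.pt_soc_map

    if config.synthetic is not None:
        reports, ground_truth = stage("synthetic", synthetic.generate_reports, config.synthetic)
        if pt_soc_map is None:
            pt_soc_map = synthetic.generate_pt_soc_map(
                config.synthetic.n_pts, config.synthetic.n_socs, config.synthetic.seed
            )
        if config.synthetic.duplicate_rate > 0:
            reports = synthetic.inject_duplicates(
                reports, config.synthetic.duplicate_rate, config.synthetic.seed
            )
    else:
        reports = stage(
            "ingest", ingest.read_reports, config.input_path,
            delimiter=config.delimiter, synonym_map=config.synonym_map,
        )
        ground_truth = None
    counts["read"] = len(reports)
    logger.info("read: %d records", len(reports))

    if config.dedup:
        reports = stage("dedup", ingest.deduplicate, reports)
    counts["deduplicated"] = len(reports)
    if config.start_date and config.end_date:
        reports = stage(
            "window", ingest.filter_window, reports, config.start_date, config.end_date
        )
    counts["in_window"] = len(reports)
    logger.info("after cleaning: %d reports", len(reports))

    tables = stage("contingency", build_all_tables, reports, drug)
    counts["tables"] = len(tables)
    records = stage(
        "signals", detect_signals, tables,
        z=config.z, min_count=config.min_count,
        hyperparams=config.hyperparams, pt_soc_map=pt_soc_map,
    )
    if config.excluded_socs and pt_soc_map is not None:
        records = stage("exclude_socs", exclude_socs, records, config.excluded_socs)
    records = stage("annotate_label", annotate_label, records, config.label_pts)
    signal_records = [r for r in records if r.is_signal]
    counts["signals"] = len(signal_records)
    logger.info("signals: %d of %d pairs", len(signal_records), len(records))

    soc_summaries = (
        stage("soc_summary", summarize_by_soc, signal_records, pt_soc_map)
        if pt_soc_map is not None
        else []
    )

    signal_pts = {r.pt_name for r in signal_records}
    assoc = [
        r
        for r in ingest.select_target_reports(reports, drug)
        if r.pt_names & signal_pts
    ]
    counts["signal_reports"] = len(assoc)
    demographics = stage("demographics", summarize_demographics, assoc)

    frames = {
        "stats": stats_frame(tables, records),
        "signals": signals_frame(signal_records),
        "soc_summary": soc_frame(soc_summaries),
        "demographics": demographics,
        "top_by_frequency": signals_frame(
            rank_signals(signal_records, "frequency", config.top_n)
        ) if signal_records else signals_frame([]),
        "top_by_ror_ci_lower": signals_frame(
            rank_signals(signal_records, "ror_ci_lower", config.top_n)
        ) if signal_records else signals_frame([]),
    }
    artifacts = stage("render", render_outputs, frames, config.out_dir, config.formats)
    if ground_truth is not None:
        gt_path = Path(config.out_dir) / "ground_truth.json"
        gt_path.write_text(json.dumps(ground_truth, indent=2) + "\n")
        artifacts.append(gt_path)
    logger.info("wrote %d artifacts to %s", len(artifacts), config.out_dir)

    return PipelineResult(
        status=0,
        stage_counts=counts,
        artifacts=artifacts,
        records=records,
        soc_summaries=soc_summaries,
        demographics=demographics,
    )
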
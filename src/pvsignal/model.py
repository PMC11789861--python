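"""Model/Results interface over the disproportionality pipeline.

``Disproportionality`` is built from a cleaned report corpus and a target
drug; ``fit()`` computes every drug-PT contingency table, both
disproportionality statistics and the dual-criterion signal verdicts, and
returns a :class:`DisproportionalityResults` carrying the estimates, their
intervals, rankings, SOC aggregation, label annotation, demographics of
signal-associated reports and a text ``summary()``.
"""
from __future__ import annotations

import datetime as _dt
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import ingest
from .contingency import ContingencyTable, build_all_tables
from .records import ReportRecord
from .report import signals_frame, soc_frame, stats_frame, summarize_demographics
from .signals import (
    SignalRecord,
    SocSummary,
    annotate_label,
    detect_signals,
    exclude_socs,
    rank_signals,
    summarize_by_soc,
)
from .stats import DEFAULT_MIN_COUNT, DEFAULT_Z, BcpnnHyperparams


class Disproportionality:
    """Disproportionality model of one target drug against a spontaneous
    report corpus.

    Parameters
    ----------
    reports
        Report corpus (cleaned or raw; see ``dedup``/``window``).
    drug
        Target drug name; normalized through ``synonym_map`` if given.
    pt_soc_map
        Optional PT -> system-organ-class mapping used for aggregation.
    dedup
        Keep only the highest version per case id (default True).
    window
        Optional closed (start, end) receipt-date interval.
    """

    def __init__(
        self,
        reports: Sequence[ReportRecord],
        drug: str,
        *,
        pt_soc_map: Optional[Mapping[str, str]] = None,
        synonym_map: Optional[Mapping[str, str]] = None,
        dedup: bool = True,
        window: Optional[tuple[_dt.date, _dt.date]] = None,
    ):
        self.drug = ingest.normalize_drug_name(drug, synonym_map)
        self.pt_soc_map = dict(pt_soc_map) if pt_soc_map else None
        reports = list(reports)
        if dedup:
            reports = ingest.deduplicate(reports)
        if window is not None:
            reports = ingest.filter_window(reports, *window)
        self.reports = reports

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        drug: str,
        *,
        synonym_map: Optional[Mapping[str, str]] = None,
        **kwargs,
    ) -> "Disproportionality":
        """Build from a long-format frame (columns as the delimited
        reader: caseid, caseversion, receiptdate, sex, age, country,
        drugname, role_cod, pt)."""
        reports = ingest.reports_from_dataframe(df, synonym_map)
        return cls(reports, drug, synonym_map=synonym_map, **kwargs)

    @classmethod
    def from_file(
        cls,
        path,
        drug: str,
        *,
        delimiter: str = "\t",
        synonym_map: Optional[Mapping[str, str]] = None,
        **kwargs,
    ) -> "Disproportionality":
        reports = ingest.read_reports(path, delimiter=delimiter, synonym_map=synonym_map)
        return cls(reports, drug, synonym_map=synonym_map, **kwargs)

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    @property
    def n_drug_reports(self) -> int:
        return len(ingest.select_target_reports(self.reports, self.drug))

    def fit(
        self,
        *,
        z: float = DEFAULT_Z,
        min_count: int = DEFAULT_MIN_COUNT,
        hyperparams: Optional[BcpnnHyperparams] = None,
    ) -> "DisproportionalityResults":
        """Count all fourfold tables, compute ROR and BCPNN statistics,
        and apply the dual signal criterion."""
        tables = build_all_tables(self.reports, self.drug)
        records = detect_signals(
            tables,
            z=z,
            min_count=min_count,
            hyperparams=hyperparams,
            pt_soc_map=self.pt_soc_map,
        )
        return DisproportionalityResults(
            self, tables, records, z=z, min_count=min_count,
            hyperparams=hyperparams or BcpnnHyperparams(),
        )


class DisproportionalityResults:
    """Fitted per-PT statistics and signal verdicts for one drug."""

    def __init__(
        self,
        model: Disproportionality,
        tables: Sequence[ContingencyTable],
        records: Sequence[SignalRecord],
        *,
        z: float,
        min_count: int,
        hyperparams: BcpnnHyperparams,
    ):
        self.model = model
        self.tables = list(tables)
        self.records = list(records)
        self.z = z
        self.min_count = min_count
        self.hyperparams = hyperparams

    # -- core views -------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        """Full statistics table, one row per drug-PT pair."""
        return stats_frame(self.tables, self.records)

    @property
    def signals(self) -> list[SignalRecord]:
        return [r for r in self.records if r.is_signal]

    @property
    def n_signals(self) -> int:
        return len(self.signals)

    # -- derived surfaces -------------------------------------------------
    def rank(self, key: str = "frequency", top_n: int = 30) -> list[SignalRecord]:
        return rank_signals(self.signals, key, top_n)

    def exclude_socs(self, excluded: Iterable[str]) -> "DisproportionalityResults":
        """New results with signals in the excluded SOCs removed."""
        return DisproportionalityResults(
            self.model, self.tables, exclude_socs(self.records, excluded),
            z=self.z, min_count=self.min_count, hyperparams=self.hyperparams,
        )

    def annotate_label(self, label_pts: Optional[Iterable[str]]) -> "DisproportionalityResults":
        """New results with ``in_label`` set by PT membership in the label."""
        return DisproportionalityResults(
            self.model, self.tables, annotate_label(self.records, label_pts),
            z=self.z, min_count=self.min_count, hyperparams=self.hyperparams,
        )

    def soc_summary(self) -> list[SocSummary]:
        if self.model.pt_soc_map is None:
            raise ValueError("model has no PT->SOC map")
        return summarize_by_soc(self.signals, self.model.pt_soc_map)

    def soc_frame(self) -> pd.DataFrame:
        return soc_frame(self.soc_summary())

    def signal_reports(self) -> list[ReportRecord]:
        """Distinct drug reports contributing to cell a of any signal PT."""
        signal_pts = {r.pt_name for r in self.signals}
        return [
            r
            for r in ingest.select_target_reports(self.model.reports, self.model.drug)
            if r.pt_names & signal_pts
        ]

    def demographics(self) -> pd.DataFrame:
        """Composition table over the signal-associated reports."""
        return summarize_demographics(self.signal_reports())

    # -- presentation -----------------------------------------------------
    def summary(self, top_n: int = 10) -> str:
        """Human-readable fit summary with the top signals by frequency."""
        lines = [
            "Disproportionality analysis (ROR + BCPNN)",
            "=" * 57,
            f"target drug:        {self.model.drug}",
            f"corpus reports:     {self.model.n_reports}",
            f"drug reports:       {self.model.n_drug_reports}",
            f"drug-PT pairs:      {len(self.records)}",
            f"signals:            {self.n_signals}"
            f"  (a >= {self.min_count}, ROR CI lower > 1, IC025 > 0)",
            "",
            f"top {min(top_n, self.n_signals)} signals by frequency:",
            f"{'PT':<34}{'a':>5}{'ROR':>9}{'CI low':>9}{'IC025':>8}",
            "-" * 65,
        ]
        for r in self.rank("frequency", top_n):
            lines.append(
                f"{r.pt_name[:33]:<34}{r.a:>5}"
                f"{r.ror_result.ror:>9.2f}{r.ror_result.ci_lower:>9.2f}"
                f"{r.bcpnn_result.ic025:>8.2f}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<DisproportionalityResults drug={self.model.drug!r} "
            f"pairs={len(self.records)} signals={self.n_signals}>"
        )
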
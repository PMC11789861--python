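"""Fourfold (2x2) contingency tables for drug-event pairs.

The counting unit is the unique deduplicated case, so each report lands in
exactly one cell:

=============  ============  ===========
               target drug   other drugs
=============  ============  ===========
target PT      a             c
other PTs      b             d
=============  ============  ===========

"Target drug" membership means the drug is named as primary suspect on the
report; the comparator is every other report in the ingested corpus.
Tables are emitted only for PTs co-reported at least once with the drug
(a >= 1); the a >= 3 signal threshold is applied later so that
sub-threshold statistics stay inspectable.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .ingest import select_target_reports
from .records import ReportRecord


@dataclass(frozen=True)
class ContingencyTable:
    drug: str
    pt_name: str
    a: int
    b: int
    c: int
    d: int
    n_total: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d != self.n_total:
            raise ValueError("a + b + c + d must equal n_total")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def build_contingency(
    reports: Sequence[ReportRecord], drug: str, pt_name: str
) -> ContingencyTable:
    """Single-pass report-level count of the fourfold table for one
    drug-PT pair over a deduplicated corpus."""
    a = b = c = d = 0
    for rep in reports:
        has_drug = any(
            dm.name == drug and dm.role.value == "PS" for dm in rep.drugs
        )
        has_pt = pt_name in rep.pt_names
        if has_drug and has_pt:
            a += 1
        elif has_drug:
            b += 1
        elif has_pt:
            c += 1
        else:
            d += 1
    return ContingencyTable(drug, pt_name, a, b, c, d, len(reports))


def build_all_tables(
    reports: Sequence[ReportRecord], drug: str
) -> list[ContingencyTable]:
    """One table per distinct PT occurring on >= 1 report with the drug.

    All tables share ``n_total`` and ``a + b`` (the drug-report count);
    consistent with :func:`build_contingency` cell by cell.
    """
    n_total = len(reports)
    drug_reports = select_target_reports(reports, drug)
    n_drug = len(drug_reports)

    a_counts: Counter[str] = Counter()
    for rep in drug_reports:
        a_counts.update(rep.pt_names)

    pt_totals: Counter[str] = Counter()  # a + c per PT, corpus-wide
    for rep in reports:
        for pt in rep.pt_names:
            if pt in a_counts:
                pt_totals[pt] += 1

    tables = []
    for pt in sorted(a_counts):
        a = a_counts[pt]
        b = n_drug - a
        c = pt_totals[pt] - a
        d = n_total - a - b - c
        tables.append(ContingencyTable(drug, pt, a, b, c, d, n_total))
    return tables
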
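"""Reading, cleaning and standardizing spontaneous-report extracts.

The on-disk format is "long": one row per case-drug-reaction combination,
with header columns ``caseid, caseversion, receiptdate, sex, age, country,
drugname, role_cod, pt`` (tab-delimited by default, ISO-8601 dates, empty
field = unknown).  This is the common denominator of OpenVigil-style and
FAERS quarterly exports.  Only ``caseid``, ``drugname``, ``role_cod`` and
``pt`` are mandatory; every other column degrades to "unknown" when absent
or unparseable, never to an error.
"""
from __future__ import annotations

import csv
import datetime as _dt
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .exceptions import FormatError
from .records import DrugMention, DrugRole, ReactionMention, ReportRecord

COLUMNS = (
    "caseid",
    "caseversion",
    "receiptdate",
    "sex",
    "age",
    "country",
    "drugname",
    "role_cod",
    "pt",
)
MANDATORY_COLUMNS = ("caseid", "drugname", "role_cod", "pt")


def _parse_date(raw: str) -> Optional[_dt.date]:
    try:
        return _dt.date.fromisoformat(raw.strip())
    except (ValueError, AttributeError):
        return None


def _parse_sex(raw: str) -> str:
    raw = (raw or "").strip().lower()
    if raw in ("m", "male"):
        return "male"
    if raw in ("f", "female"):
        return "female"
    return "unknown"


def _parse_age(raw: str) -> Optional[float]:
    try:
        age = float(raw)
    except (TypeError, ValueError):
        return None
    return age if age >= 0 else None


def normalize_pt(raw: str) -> str:
    """Trim + case-fold; PT text is otherwise left untouched (full MedDRA
    coding is out of scope)."""
    return raw.strip().casefold()


def normalize_drug_name(raw: str, synonym_map: Optional[Mapping[str, str]] = None) -> str:
    """Map a raw drug string to a canonical ingredient name.

    Lookup is case-insensitive and whitespace-trimmed; unmapped names pass
    through lower-cased (e.g. ``"TABRECTA" -> "capmatinib"`` given
    ``{"tabrecta": "capmatinib"}``).
    """
    key = raw.strip().casefold()
    if synonym_map:
        folded = {k.strip().casefold(): v.strip().casefold() for k, v in synonym_map.items()}
        return folded.get(key, key)
    return key


def _group_rows(
    rows, synonym_map: Optional[Mapping[str, str]] = None
) -> list[ReportRecord]:
    """Group long-format row mappings by (caseid, caseversion)."""
    grouped: dict[tuple[str, int], dict] = {}
    order: list[tuple[str, int]] = []
    for row in rows:
        case_id = str(row.get("caseid") or "").strip()
        if not case_id:
            continue
        try:
            version = int(row.get("caseversion") or 0)
        except (TypeError, ValueError):
            version = 0
        key = (case_id, version)
        if key not in grouped:
            grouped[key] = {
                "receipt_date": _parse_date(str(row.get("receiptdate") or "")),
                "sex": _parse_sex(str(row.get("sex") or "")),
                "age_years": _parse_age(row.get("age")),
                "country": str(row.get("country") or "").strip() or None,
                "drugs": {},
                "pts": {},
            }
            order.append(key)
        entry = grouped[key]
        drug = normalize_drug_name(str(row.get("drugname") or ""), synonym_map)
        if drug:
            try:
                role = DrugRole.from_code(str(row.get("role_cod") or ""))
            except ValueError:
                role = DrugRole.CONCOMITANT
            entry["drugs"].setdefault((drug, role), DrugMention(drug, role))
        pt = normalize_pt(str(row.get("pt") or ""))
        if pt:
            entry["pts"].setdefault(pt, ReactionMention(pt))
    out = []
    for case_id, version in order:
        e = grouped[(case_id, version)]
        out.append(
            ReportRecord(
                case_id=case_id,
                version=version,
                receipt_date=e["receipt_date"],
                sex=e["sex"],
                age_years=e["age_years"],
                country=e["country"],
                drugs=tuple(sorted(e["drugs"].values())),
                reactions=tuple(sorted(e["pts"].values())),
            )
        )
    return out


def read_reports(
    path: str | Path,
    *,
    delimiter: str = "\t",
    synonym_map: Optional[Mapping[str, str]] = None,
) -> list[ReportRecord]:
    """Read a long-format delimited extract into :class:`ReportRecord` values.

    Rows are grouped by (caseid, caseversion); drug mentions and PTs are
    de-duplicated within a report.  Missing mandatory columns raise
    :class:`FormatError` naming the column; an empty file yields ``[]``.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            return []
        missing = [c for c in MANDATORY_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
        return _group_rows(reader, synonym_map)


def reports_from_dataframe(
    df, synonym_map: Optional[Mapping[str, str]] = None
) -> list[ReportRecord]:
    """Build reports from a long-format :class:`pandas.DataFrame` with the
    same columns the delimited reader expects."""
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    rows = ({k: ("" if v is None else v) for k, v in rec.items()}
            for rec in df.to_dict(orient="records"))
    return _group_rows(rows, synonym_map)


def write_reports(
    reports: Iterable[ReportRecord], path: str | Path, *, delimiter: str = "\t"
) -> None:
    """Write reports in the same long format :func:`read_reports` reads,
    one row per drug x reaction combination (the pipeline is closed under
    its own I/O)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(COLUMNS)
        for rep in reports:
            date = rep.receipt_date.isoformat() if rep.receipt_date else ""
            sex = rep.sex if rep.sex != "unknown" else ""
            age = "" if rep.age_years is None else format(rep.age_years, "g")
            country = rep.country or ""
            for drug in rep.drugs:
                for rx in rep.reactions:
                    writer.writerow(
                        (
                            rep.case_id,
                            rep.version,
                            date,
                            sex,
                            age,
                            country,
                            drug.name,
                            drug.role.value,
                            rx.pt_name,
                        )
                    )


def _serialized_key(rep: ReportRecord) -> tuple:
    """Canonical serialization used only as the final deduplication
    tie-break (lexicographically smallest wins)."""
    return (
        rep.case_id,
        rep.version,
        rep.receipt_date.isoformat() if rep.receipt_date else "",
        rep.sex,
        -1.0 if rep.age_years is None else rep.age_years,
        rep.country or "",
        tuple((d.name, d.role.value) for d in rep.drugs),
        tuple(r.pt_name for r in rep.reactions),
    )


def deduplicate(reports: Sequence[ReportRecord]) -> list[ReportRecord]:
    """Keep exactly one record per case id: the highest case version, ties
    broken by latest receipt date, then by the lexicographically smallest
    serialized record.  Idempotent; preserves first-seen case order."""
    best: dict[str, ReportRecord] = {}
    order: list[str] = []

    def rank(rep: ReportRecord):
        date = rep.receipt_date or _dt.date.min
        return (rep.version, date)

    for rep in reports:
        cur = best.get(rep.case_id)
        if cur is None:
            best[rep.case_id] = rep
            order.append(rep.case_id)
        elif rank(rep) > rank(cur) or (
            rank(rep) == rank(cur) and _serialized_key(rep) < _serialized_key(cur)
        ):
            best[rep.case_id] = rep
    return [best[cid] for cid in order]


def filter_window(
    reports: Sequence[ReportRecord], start: _dt.date, end: _dt.date
) -> list[ReportRecord]:
    """Keep reports with ``start <= receipt_date <= end`` (closed interval).
    Reports with no parseable receipt date are excluded."""
    if start > end:
        raise ValueError(f"start date {start} is after end date {end}")
    return [
        r for r in reports if r.receipt_date is not None and start <= r.receipt_date <= end
    ]


def select_target_reports(
    reports: Sequence[ReportRecord], drug: str
) -> list[ReportRecord]:
    """Reports naming ``drug`` (already normalized) as primary suspect;
    each qualifying report appears once regardless of repeated mentions."""
    return [r for r in reports if r.has_drug(drug, DrugRole.PRIMARY_SUSPECT)]
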
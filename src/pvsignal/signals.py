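"""Signal detection, ranking, SOC aggregation and label-expectedness.

A drug-PT pair is a signal when both disproportionality criteria hold
simultaneously: a >= 3 with ROR 95% CI lower bound > 1, and IC025 > 0.
Sub-threshold pairs are carried through with ``is_signal=False`` so that
near-signals remain inspectable in rankings and outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from .contingency import ContingencyTable
from .exceptions import UnmappedTermError
from .ingest import normalize_pt
from .stats import (
    DEFAULT_MIN_COUNT,
    DEFAULT_Z,
    BcpnnHyperparams,
    BcpnnResult,
    RorResult,
    compute_bcpnn,
    compute_ror,
)

#: SOC categories conventionally excluded as unrelated to the drug's own
#: pharmacology (product/quality issues, injuries, surgical complications,
#: pregnancy, congenital conditions).
DEFAULT_EXCLUDED_SOCS = (
    "injury, poisoning and procedural complications",
    "pregnancy, puerperium and perinatal conditions",
    "congenital, familial and genetic disorders",
    "product issues",
)


@dataclass(frozen=True)
class SignalRecord:
    drug: str
    pt_name: str
    soc_name: Optional[str]
    a: int
    ror_result: RorResult
    bcpnn_result: BcpnnResult
    is_signal: bool
    in_label: Optional[bool] = None  # None = no label list supplied


@dataclass(frozen=True)
class SocSummary:
    soc_name: str
    n_signal_pts: int
    n_reports: int  # sum of a over the SOC's signal PTs


def detect_signals(
    tables: Sequence[ContingencyTable],
    *,
    z: float = DEFAULT_Z,
    min_count: int = DEFAULT_MIN_COUNT,
    hyperparams: BcpnnHyperparams | None = None,
    pt_soc_map: Optional[Mapping[str, str]] = None,
) -> list[SignalRecord]:
    """Compute both statistics for every table and flag the conjunction.

    Pairs with a < min_count keep their statistics but are never signals.
    """
    out = []
    for t in tables:
        ror = compute_ror(t, z=z, min_count=min_count)
        bcpnn = compute_bcpnn(t, hyperparams)
        out.append(
            SignalRecord(
                drug=t.drug,
                pt_name=t.pt_name,
                soc_name=pt_soc_map.get(t.pt_name) if pt_soc_map else None,
                a=t.a,
                ror_result=ror,
                bcpnn_result=bcpnn,
                is_signal=ror.meets_threshold and bcpnn.meets_threshold,
            )
        )
    return out


def rank_signals(
    signals: Sequence[SignalRecord],
    key: str = "frequency",
    top_n: int = 30,
) -> list[SignalRecord]:
    """Descending order by ``frequency`` (the a count) or ``ror_ci_lower``
    (signal intensity); ties break on the other key descending, then PT
    name ascending.  Returns the first ``top_n``."""
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    if key not in ("frequency", "ror_ci_lower"):
        raise ValueError(f"unknown ranking key: {key!r}")

    def sort_key(s: SignalRecord):
        freq, ci = s.a, s.ror_result.ci_lower
        primary, secondary = (freq, ci) if key == "frequency" else (ci, freq)
        return (-primary, -secondary, s.pt_name)

    return sorted(signals, key=sort_key)[:top_n]


def exclude_socs(
    signals: Sequence[SignalRecord], excluded_socs: Iterable[str]
) -> list[SignalRecord]:
    """Drop signals whose SOC is on the exclusion list (exact match)."""
    excluded = set(excluded_socs)
    return [s for s in signals if s.soc_name not in excluded]


def annotate_label(
    signals: Sequence[SignalRecord],
    label_pts: Optional[Iterable[str]],
) -> list[SignalRecord]:
    """Set ``in_label`` by case-folded exact PT membership in the product
    label's term list; ``None`` for every record when no list is given.

    Only exact membership is checked — clinical "relatedness" between a
    label term and a detected PT is out of scope and left to the reviewer.
    """
    if label_pts is None:
        return [replace(s, in_label=None) for s in signals]
    label = {normalize_pt(p) for p in label_pts}
    return [replace(s, in_label=normalize_pt(s.pt_name) in label) for s in signals]


def summarize_by_soc(
    signals: Sequence[SignalRecord], pt_soc_map: Mapping[str, str]
) -> list[SocSummary]:
    """Group signal records by SOC; totals are conserved.

    Raises :class:`UnmappedTermError` listing every PT absent from the map.
    """
    missing = {s.pt_name for s in signals if s.pt_name not in pt_soc_map}
    if missing:
        raise UnmappedTermError(missing)
    counts: dict[str, list[int]] = {}
    for s in signals:
        soc = pt_soc_map[s.pt_name]
        entry = counts.setdefault(soc, [0, 0])
        entry[0] += 1
        entry[1] += s.a
    return [
        SocSummary(soc, n_pts, n_rep)
        for soc, (n_pts, n_rep) in sorted(
            counts.items(), key=lambda kv: (-kv[1][0], kv[0])
        )
    ]
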
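"""Canonical in-memory model of a spontaneous adverse-event report.

A report (one case, one version) carries at least one drug mention and at
least one reaction, plus the demographic fields used for summary tables.
Drug roles follow the four FAERS role codes: primary suspect (PS),
secondary suspect (SS), concomitant (C) and interacting (I).
"""
from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field
from typing import Optional


class DrugRole(str, enum.Enum):
    PRIMARY_SUSPECT = "PS"
    SECONDARY_SUSPECT = "SS"
    CONCOMITANT = "C"
    INTERACTING = "I"

    @classmethod
    def from_code(cls, code: str) -> "DrugRole":
        code = code.strip().upper()
        aliases = {
            "PS": cls.PRIMARY_SUSPECT,
            "SS": cls.SECONDARY_SUSPECT,
            "C": cls.CONCOMITANT,
            "I": cls.INTERACTING,
        }
        if code not in aliases:
            raise ValueError(f"unknown drug role code: {code!r}")
        return aliases[code]


SEX_VALUES = ("male", "female", "unknown")


@dataclass(frozen=True, order=True)
class DrugMention:
    """One drug named on a report, with its FAERS role code."""

    name: str
    role: DrugRole


@dataclass(frozen=True, order=True)
class ReactionMention:
    """One adverse-event preferred term (PT) named on a report."""

    pt_name: str


@dataclass(frozen=True)
class ReportRecord:
    """One spontaneous report: a case id + version with drugs, reactions
    and demographics.

    ``sex`` is one of ``male``/``female``/``unknown``; ``age_years`` and
    ``country`` are ``None`` when missing; ``receipt_date`` may be ``None``
    for reports whose date could not be parsed (such reports are excluded
    by date-window filters).
    """

    case_id: str
    version: int = 0
    receipt_date: Optional[_dt.date] = None
    sex: str = "unknown"
    age_years: Optional[float] = None
    country: Optional[str] = None
    drugs: tuple[DrugMention, ...] = field(default_factory=tuple)
    reactions: tuple[ReactionMention, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.sex not in SEX_VALUES:
            object.__setattr__(self, "sex", "unknown")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError(f"negative age: {self.age_years}")
        # reactions carry distinct PTs within one report
        seen, uniq = set(), []
        for r in self.reactions:
            if r.pt_name not in seen:
                seen.add(r.pt_name)
                uniq.append(r)
        object.__setattr__(self, "reactions", tuple(uniq))
        # canonical drug order so corpora survive write/read round-trips
        object.__setattr__(self, "drugs", tuple(sorted(set(self.drugs))))

    @property
    def pt_names(self) -> frozenset[str]:
        return frozenset(r.pt_name for r in self.reactions)

    def has_drug(self, name: str, role: Optional[DrugRole] = None) -> bool:
        """Report-level membership: does this report mention ``name``
        (optionally restricted to one role)?"""
        return any(
            d.name == name and (role is None or d.role == role) for d in self.drugs
        )
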
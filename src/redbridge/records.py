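"""In-memory record types assembled from a source export.

A patient is one :class:`PatientRecord`: identity + administrative values +
an ordered list of :class:`DiagnosticBlock` (one per diagnosis-sheet row).
Values are kept verbatim (whitespace-trimmed only); all matching happens in
normalization layers so the audit trail can always show the source string.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from .terminology import normalize_code

# normalized diagnostic-status vocabulary; source strings outside this map
# keep their verbatim form and a normalized form of "" (fails eligibility)
_STATUS_MAP = {
    "confirme": "confirmed",
    "confirmed": "confirmed",
    "probable": "probable",
    "indetermine": "undetermined",
    "undetermined": "undetermined",
}


def normalize_status(raw: str) -> str:
    from ._text import fold_header

    return _STATUS_MAP.get(fold_header(raw), "")


@dataclass(frozen=True)
class Identity:
    surname: str
    given_name: str
    birth_date: dt.date | None

    def is_complete(self) -> bool:
        """All three attributes present — required for duplicate checking."""
        return bool(self.surname and self.given_name and self.birth_date)


@dataclass
class VariantEntry:
    description: str
    classification: str = ""
    zygosity: str = ""
    attributes: dict[str, str] = field(default_factory=dict)  # family -> value

    def get(self, family: str) -> str:
        if family == "description":
            return self.description
        if family == "classification":
            return self.classification
        if family == "zygosity":
            return self.zygosity
        return self.attributes.get(family, "")


@dataclass
class GeneEntry:
    symbol: str
    variants: list[VariantEntry] = field(default_factory=list)
    attributes: dict[str, str] = field(default_factory=dict)  # family -> value

    def get(self, family: str) -> str:
        if family == "symbol":
            return self.symbol
        return self.attributes.get(family, "")


@dataclass
class DiagnosticBlock:
    source_row: int
    orpha_code: str = ""  # verbatim, possibly bare digits
    status: str = ""  # verbatim source string
    hpo_terms: list[str] = field(default_factory=list)
    assertion_date: dt.date | None = None
    genes: list[GeneEntry] = field(default_factory=list)
    clinical_fields: dict[str, str] = field(default_factory=dict)  # header -> value

    @property
    def status_normalized(self) -> str:
        return normalize_status(self.status)

    @property
    def orpha_normalized(self) -> str:
        return normalize_code(self.orpha_code, "ORPHA") if self.orpha_code else ""


@dataclass
class PatientRecord:
    bamara_id: str
    identity: Identity
    administrative: dict[str, str] = field(default_factory=dict)  # header -> value
    blocks: list[DiagnosticBlock] = field(default_factory=list)  # by source_row
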
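"""Registry of inference functions for ``inferred`` mapping rules.

An inferred target value is derived by a calculation over the source record
(dates, presence of data, counts); when the inputs are missing or
inconsistent the rule's configured default applies.  Rules reference
functions by ``inference_id``; unknown identifiers are rejected when the
configuration is loaded, not at transform time.

Each function receives an :class:`InferenceContext` and returns a string
value or ``None`` (meaning: fall back to the rule default).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Callable, Optional

from .records import Identity


@dataclass
class InferenceContext:
    identity: Identity
    administrative: dict[str, str]  # source header -> value (normalized lookup done by caller helpers)
    diagnosis: "object | None" = None  # transform.MergedDiagnosis for diagnosis-scope rules
    diagnosis_rank: int = 1
    n_diagnoses: int = 1

    def admin_value(self, *header_candidates: str) -> str:
        from ._text import fold_header

        folded = {fold_header(k): v for k, v in self.administrative.items()}
        for cand in header_candidates:
            v = folded.get(fold_header(cand), "")
            if v:
                return v
        return ""


def _whole_years(start: dt.date, end: dt.date) -> Optional[int]:
    if end < start:
        return None
    years = end.year - start.year
    if (end.month, end.day) < (start.month, start.day):
        years -= 1
    return years


def _parse(raw: str) -> Optional[dt.date]:
    from .export_io import parse_date

    return parse_date(raw)


# ---- patient-scope inferences ----------------------------------------------

def year_of_birth(ctx: InferenceContext) -> Optional[str]:
    d = ctx.identity.birth_date
    return str(d.year) if d else None


def deceased_flag(ctx: InferenceContext) -> Optional[str]:
    return "1" if ctx.admin_value("Date de décès") else None


def active_unless_closed(ctx: InferenceContext) -> Optional[str]:
    return "closed" if ctx.admin_value("Date de fermeture du dossier") else None


def year_of_first_visit(ctx: InferenceContext) -> Optional[str]:
    d = _parse(ctx.admin_value("Date de première consultation"))
    return str(d.year) if d else None


def is_polydiagnostic(ctx: InferenceContext) -> Optional[str]:
    return "1" if ctx.n_diagnoses >= 2 else "0"


# ---- diagnosis-scope inferences --------------------------------------------

def age_at_diagnosis(ctx: InferenceContext) -> Optional[str]:
    if ctx.diagnosis is None or ctx.identity.birth_date is None:
        return None
    date = ctx.diagnosis.assertion_date
    if date is None:
        return None
    years = _whole_years(ctx.identity.birth_date, date)
    return None if years is None else str(years)


def age_at_first_signs(ctx: InferenceContext) -> Optional[str]:
    if ctx.diagnosis is None or ctx.identity.birth_date is None:
        return None
    d = _parse(ctx.diagnosis.get("Date des premiers signes"))
    if d is None:
        return None
    years = _whole_years(ctx.identity.birth_date, d)
    return None if years is None else str(years)


def has_hpo(ctx: InferenceContext) -> Optional[str]:
    if ctx.diagnosis is None:
        return None
    return "1" if ctx.diagnosis.hpo_terms else "0"


def has_genetics(ctx: InferenceContext) -> Optional[str]:
    if ctx.diagnosis is None:
        return None
    return "1" if ctx.diagnosis.genes else "0"


def n_source_blocks(ctx: InferenceContext) -> Optional[str]:
    if ctx.diagnosis is None:
        return None
    return str(ctx.diagnosis.n_source_blocks)


def diagnosis_rank(ctx: InferenceContext) -> Optional[str]:
    return str(ctx.diagnosis_rank)


def year_of_assertion(ctx: InferenceContext) -> Optional[str]:
    if ctx.diagnosis is None or ctx.diagnosis.assertion_date is None:
        return None
    return str(ctx.diagnosis.assertion_date.year)


def delay_signs_to_diagnosis(ctx: InferenceContext) -> Optional[str]:
    if ctx.diagnosis is None or ctx.diagnosis.assertion_date is None:
        return None
    signs = _parse(ctx.diagnosis.get("Date des premiers signes"))
    if signs is None or ctx.diagnosis.assertion_date < signs:
        return None
    return str((ctx.diagnosis.assertion_date - signs).days)


def genetically_confirmed(ctx: InferenceContext) -> Optional[str]:
    if ctx.diagnosis is None:
        return None
    confirmed = ctx.diagnosis.status_normalized == "confirmed"
    return "1" if confirmed and ctx.diagnosis.genes else "0"


def hpo_count(ctx: InferenceContext) -> Optional[str]:
    if ctx.diagnosis is None:
        return None
    return str(len(ctx.diagnosis.hpo_terms))


def gene_count(ctx: InferenceContext) -> Optional[str]:
    if ctx.diagnosis is None:
        return None
    return str(len(ctx.diagnosis.genes))


def constant_default(ctx: InferenceContext) -> Optional[str]:
    return None  # always the configured default


INFERENCES: dict[str, Callable[[InferenceContext], Optional[str]]] = {
    fn.__name__: fn
    for fn in (
        year_of_birth, deceased_flag, active_unless_closed, year_of_first_visit,
        is_polydiagnostic, age_at_diagnosis, age_at_first_signs, has_hpo,
        has_genetics, n_source_blocks, diagnosis_rank, year_of_assertion,
        delay_signs_to_diagnosis, genetically_confirmed, hpo_count, gene_count,
        constant_default,
    )
}


class UnknownInferenceError(ValueError):
    pass


def check_registered(config) -> None:
    """Reject configurations referencing unregistered inference functions."""
    for rule in config.rules:
        if rule.kind == "inferred" and rule.inference_id not in INFERENCES:
            raise UnknownInferenceError(
                f"rule {rule.target_field!r}: unregistered inference "
                f"{rule.inference_id!r}"
            )
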
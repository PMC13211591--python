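"""Loading layer: CSV template, FHIR-style bundles, paced submission, audit.

Two import mechanisms mirror the target platform: a file-based CSV template
(fixed column order, one row per patient) and an API-based route that wraps
each record into a simplified FHIR-style bundle (one patient-demographics
resource plus one questionnaire-response resource) and submits it with
pacing and retry.  Every run ends with a structured audit report — machine-
readable JSON plus a human-readable text rendering — accounting for every
input patient: imports, exclusions, retained blocks, polydiagnostic cases,
duplicates, and the tool version.
"""

from __future__ import annotations

import csv
import datetime as dt
import hashlib
import json
import time
import uuid
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .mapping import MappingConfig
from .registry import MockRegistry, TransientRegistryError
from .schema import template_columns
from .transform import FreddRecord

OUTCOMES = ("created", "duplicate_skipped", "filtered_out",
            "validation_blocked", "transport_failed")


@dataclass
class ImportOutcome:
    bamara_id: str
    outcome: str  # one of OUTCOMES
    detail: str = ""
    profile_id: str = ""
    pathway: str = ""
    orpha_in_allowed: bool | None = None
    n_blocks: int = 0
    n_disease_groups: int = 0
    has_additional: bool = False
    has_gene_variant: bool = False


# ---------------------------------------------------------------------------
# CSV template

def write_csv(records: list[FreddRecord], path: str | Path,
              config: MappingConfig) -> Path:
    """Serialize importable records to the CSV import template.

    Fixed column order from the target schema; UTF-8; unfilled slots are
    empty strings.  ``parse_csv(write_csv(x)) == x`` field-for-field.
    """
    path = Path(path)
    cols = template_columns(config)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols, extrasaction="ignore")
        writer.writeheader()
        for record in records:
            writer.writerow(record_to_row(record, config))
    return path


def record_to_row(record: FreddRecord, config: MappingConfig) -> dict[str, str]:
    row = {c: "" for c in template_columns(config)}
    row["bamara_id"] = record.bamara_id
    row["surname"] = record.identity.surname
    row["given_name"] = record.identity.given_name
    row["birth_date"] = (record.identity.birth_date.isoformat()
                         if record.identity.birth_date else "")
    row.update(record.administrative)
    for prefix, diag in record.diagnoses():
        for target, value in diag.fields.items():
            row[f"{prefix}_{target}"] = value
        for slot, value in diag.flattened_genetics.items():
            row[f"{prefix}_{slot}"] = value
    return row


def parse_csv(path: str | Path) -> list[dict[str, str]]:
    with open(path, encoding="utf-8", newline="") as fh:
        return list(csv.DictReader(fh))


# ---------------------------------------------------------------------------
# FHIR-style bundle

def build_bundle(record: FreddRecord) -> dict:
    """Wrap one importable record into a simplified FHIR-style bundle.

    Identity appears only in the demographics resource; the questionnaire
    response carries only coded answers keyed by target field.
    """
    demographics = {
        "resourceType": "Patient",
        "name": [{"family": record.identity.surname,
                  "given": [record.identity.given_name]}],
        "birthDate": (record.identity.birth_date.isoformat()
                      if record.identity.birth_date else None),
    }
    items = [
        {"linkId": target, "answer": value}
        for target, value in sorted(record.administrative.items())
    ]
    for prefix, diag in record.diagnoses():
        group = [
            {"linkId": f"{prefix}_{t}", "answer": v}
            for t, v in {**diag.fields, **diag.flattened_genetics}.items()
            if v
        ]
        items.append({"linkId": f"{prefix}_diagnosis", "item": group})
    questionnaire = {
        "resourceType": "QuestionnaireResponse",
        "status": "completed",
        "item": items,
    }
    return {
        "resourceType": "Bundle",
        "type": "transaction",
        "source_id": record.bamara_id,
        "entry": [{"resource": demographics}, {"resource": questionnaire}],
    }


# ---------------------------------------------------------------------------
# submission with pacing and retry

def submit(
    bundles: list[tuple[FreddRecord, dict]],
    registry: MockRegistry,
    token: str,
    pacing: float = 0.0,
    max_retries: int = 3,
) -> list[ImportOutcome]:
    """Create profile then questionnaire per patient, sequentially.

    Transient failures retry up to ``max_retries`` times with ``pacing``
    seconds between attempts; exhausted retries yield ``transport_failed``
    and the run continues.  If the questionnaire fails after the profile was
    created, the orphan profile_id is recorded for manual remediation.
    """
    outcomes: list[ImportOutcome] = []
    for record, bundle in bundles:
        profile_id = ""
        try:
            profile_id = _with_retry(
                lambda: registry.create_profile(
                    token,
                    record.identity.surname,
                    record.identity.given_name,
                    record.identity.birth_date.isoformat()
                    if record.identity.birth_date else "",
                ),
                pacing, max_retries,
            )
            _with_retry(
                lambda: registry.create_questionnaire(token, profile_id, bundle),
                pacing, max_retries,
            )
        except TransientRegistryError as exc:
            outcomes.append(ImportOutcome(
                bamara_id=record.bamara_id, outcome="transport_failed",
                detail=str(exc), profile_id=profile_id))
            continue
        outcomes.append(ImportOutcome(
            bamara_id=record.bamara_id, outcome="created",
            profile_id=profile_id))
    return outcomes


def _with_retry(fn, pacing: float, max_retries: int):
    attempts = max_retries + 1
    for attempt in range(attempts):
        try:
            return fn()
        except TransientRegistryError:
            if attempt == attempts - 1:
                raise
            if pacing:
                time.sleep(pacing)


# ---------------------------------------------------------------------------
# audit report

@dataclass
class AuditReport:
    run_id: str
    tool_version: str
    config_fingerprints: dict[str, str]
    outcomes: list[ImportOutcome]
    block_decisions: list[dict]
    polydiagnostic: list[str]  # bamara_ids with >1 selected diagnosis
    duplicates: list[dict]
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summary:
            self.summary = self._tally()

    def _tally(self) -> dict:
        counts = {k: 0 for k in OUTCOMES}
        for o in self.outcomes:
            counts[o.outcome] += 1
        created = [o for o in self.outcomes if o.outcome == "created"]
        attempted = counts["created"] + counts["validation_blocked"] \
            + counts["transport_failed"]
        return {
            **counts,
            "total": len(self.outcomes),
            "eligible": len(self.outcomes) - counts["filtered_out"],
            "import_success_rate_pct": (
                round(100.0 * counts["created"] / attempted, 1) if attempted else 0.0
            ),
            "imported_multi_block": sum(1 for o in created if o.n_blocks >= 2),
            "imported_multi_block_single_disease": sum(
                1 for o in created if o.n_blocks >= 2 and o.n_disease_groups == 1
            ),
            "imported_two_diagnoses": sum(1 for o in created if o.has_additional),
            "imported_undetermined_nonallowed_orpha": sum(
                1 for o in created
                if o.pathway == "undetermined_hpo" and o.orpha_in_allowed is False
            ),
            "imported_with_gene_variant": sum(
                1 for o in created if o.has_gene_variant
            ),
        }

    def to_dict(self) -> dict:
        return {
            "run_id": self.run_id,
            "tool_version": self.tool_version,
            "config_fingerprints": self.config_fingerprints,
            "summary": self.summary,
            "outcomes": [vars(o) for o in self.outcomes],
            "block_decisions": self.block_decisions,
            "polydiagnostic": self.polydiagnostic,
            "duplicates": self.duplicates,
        }


def fingerprint(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def new_report(outcomes, block_decisions, polydiagnostic, duplicates,
               config_fingerprints=None) -> AuditReport:
    return AuditReport(
        run_id=uuid.uuid4().hex[:12],
        tool_version=__version__,
        config_fingerprints=config_fingerprints or {},
        outcomes=outcomes,
        block_decisions=block_decisions,
        polydiagnostic=polydiagnostic,
        duplicates=duplicates,
    )


def write_report(report: AuditReport, directory: str | Path) -> tuple[Path, Path]:
    """Write the machine-readable JSON and the human-readable text report."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    json_path = directory / "audit_report.json"
    json_path.write_text(
        json.dumps(report.to_dict(), ensure_ascii=False, indent=1),
        encoding="utf-8",
    )
    text_path = directory / "audit_report.txt"
    text_path.write_text(_render_text(report), encoding="utf-8")
    return json_path, text_path


def _render_text(report: AuditReport) -> str:
    s = report.summary
    lines = [
        f"Import run {report.run_id} — tool version {report.tool_version}",
        f"Generated {dt.datetime.now().isoformat(timespec='seconds')}",
        "",
        "Summary",
        f"  input patients:        {s['total']}",
        f"  passed filtering:      {s['eligible']}",
        f"  filtered out:          {s['filtered_out']}",
        f"  validation blocked:    {s['validation_blocked']}",
        f"  duplicates skipped:    {s['duplicate_skipped']}",
        f"  transport failed:      {s['transport_failed']}",
        f"  profiles created:      {s['created']}",
        f"  import success rate:   {s['import_success_rate_pct']}%",
        "",
        f"Patients not imported: "
        f"{[o.bamara_id for o in report.outcomes if o.outcome != 'created'][:50]}",
        "",
        "Multiple diagnostic blocks (retained block per diagnosis):",
    ]
    lines += [f"  {d}" for d in report.block_decisions[:50]]
    lines += ["", f"Polydiagnostic cases: {report.polydiagnostic}"]
    lines += ["", f"Duplicate events: {report.duplicates}"]
    return "\n".join(lines) + "\n"


# minimal structural schema for the JSON report (documented in docs/)
REPORT_SCHEMA = {
    "run_id": str,
    "tool_version": str,
    "config_fingerprints": dict,
    "summary": dict,
    "outcomes": list,
    "block_decisions": list,
    "polydiagnostic": list,
    "duplicates": list,
}


def check_report_schema(payload: dict) -> None:
    """Validate a report dict against the published structural schema and the
    summary-arithmetic invariant; raises ValueError on violation."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in payload:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(payload[key], typ):
            raise ValueError(f"report key {key!r} must be {typ.__name__}")
    s = payload["summary"]
    tallies = {k: 0 for k in OUTCOMES}
    for o in payload["outcomes"]:
        tallies[o["outcome"]] += 1
    for k, v in tallies.items():
        if s.get(k) != v:
            raise ValueError(f"summary count {k}={s.get(k)} != tally {v}")
    if s.get("total") != sum(tallies.values()):
        raise ValueError("summary total inconsistent with outcomes")
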
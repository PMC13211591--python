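"""End-to-end orchestration: extract → transform → dedup → load → report.

Per-patient failures (ineligibility, validation errors, duplicates,
exhausted retries) never abort the run; they become audit outcomes.  A
registry *fetch* failure does abort the run — the pipeline never imports
blind against an unknown registry state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .dedup import is_duplicate
from .export_io import ReadStats, SheetManifest, load_manifest, read_export
from .load_audit import (AuditReport, ImportOutcome, build_bundle, fingerprint,
                         new_report, submit, write_csv, write_report)
from .mapping import MappingConfig, load_mapping, load_reference_mapping
from .registry import MockRegistry
from .terminology import TerminologySet, load_all
from .transform import TransformResult, transform_patient

log = logging.getLogger("redbridge")


@dataclass
class PipelineConfig:
    mapping: MappingConfig
    terms: dict[str, TerminologySet]
    manifest: SheetManifest
    fingerprints: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_paths(cls, mapping_path, allowed_path, terminology_dir,
                   manifest_path=None) -> "PipelineConfig":
        from .inference import check_registered

        mapping = load_mapping(mapping_path, allowed_path)
        check_registered(mapping)
        return cls(
            mapping=mapping,
            terms=load_all(terminology_dir),
            manifest=load_manifest(manifest_path),
            fingerprints={
                "mapping": fingerprint(mapping_path),
                "allowed_orpha": fingerprint(allowed_path),
            },
        )

    @classmethod
    def reference(cls) -> "PipelineConfig":
        """Configuration shipped with the package."""
        from .mapping import packaged_data_dir

        data = packaged_data_dir()
        return cls.from_paths(data / "mapping.csv", data / "allowed_orpha.txt",
                              data / "terminology", data / "sheets.yaml")


@dataclass
class RunResult:
    report: AuditReport
    transform_results: list[TransformResult]
    imported_records: list  # FreddRecord actually created this run
    csv_path: Path | None = None
    read_stats: ReadStats | None = None


def run_pipeline(
    export_path: str | Path,
    config: PipelineConfig | None = None,
    registry: MockRegistry | None = None,
    center: str = "default",
    csv_out: str | Path | None = None,
    report_dir: str | Path | None = None,
    dry_run: bool = False,
    subset_ids: set[str] | None = None,
    pacing: float = 0.0,
    max_retries: int = 3,
) -> RunResult:
    """Run the full pipeline on one export.

    ``registry`` enables the API route (dedup + profile/questionnaire
    creation); ``csv_out`` writes the file-based import template for the
    records that pass all rules; ``dry_run`` suppresses every registry call.
    ``subset_ids`` restricts processing to the given local identifiers
    (used e.g. for reimport tests).
    """
    config = config or PipelineConfig.reference()
    stats = ReadStats()
    patients = read_export(export_path, config.manifest, stats)
    if subset_ids is not None:
        patients = [p for p in patients if p.bamara_id in subset_ids]
    log.info("processing %d patients", len(patients))

    results = [transform_patient(p, config.mapping, config.terms)
               for p in patients]

    outcomes: list[ImportOutcome] = []
    block_decisions: list[dict] = []
    polydiagnostic: list[str] = []
    duplicates: list[dict] = []
    to_load: list = []  # FreddRecord

    # duplicate check requires the registry snapshot up front (fail-safe:
    # a fetch error aborts the run before anything is written)
    existing = []
    token = ""
    if registry is not None and not dry_run:
        token = registry.issue_token(center)
        existing = registry.list_profiles(token)

    by_id = {}
    for result in results:
        meta = _outcome_meta(result)
        if result.excluded:
            outcomes.append(ImportOutcome(
                bamara_id=result.bamara_id, outcome="filtered_out",
                detail=";".join(result.exclusion_reasons), **meta))
            continue
        record = result.record
        if record.additional_diagnosis is not None:
            polydiagnostic.append(record.bamara_id)
        if result.n_blocks >= 2:
            block_decisions.append(_block_decision(result))
        if not record.importable:
            outcomes.append(ImportOutcome(
                bamara_id=record.bamara_id, outcome="validation_blocked",
                detail=";".join(record.validation_errors), **meta))
            continue
        if registry is not None and not dry_run:
            dup = is_duplicate(record.identity, existing)
            if dup is not None:
                duplicates.append({"bamara_id": record.bamara_id,
                                   "profile_id": dup})
                outcomes.append(ImportOutcome(
                    bamara_id=record.bamara_id, outcome="duplicate_skipped",
                    detail="identity_match", profile_id=dup, **meta))
                continue
        to_load.append(record)
        by_id[record.bamara_id] = meta

    imported: list = []
    if registry is not None and not dry_run:
        bundles = [(r, build_bundle(r)) for r in to_load]
        for outcome in submit(bundles, registry, token, pacing, max_retries):
            for key, value in by_id[outcome.bamara_id].items():
                setattr(outcome, key, value)
            outcomes.append(outcome)
            if outcome.outcome == "created":
                imported.append(next(r for r in to_load
                                     if r.bamara_id == outcome.bamara_id))
    else:
        detail = "dry_run" if dry_run else "csv_only"
        for record in to_load:
            outcomes.append(ImportOutcome(
                bamara_id=record.bamara_id, outcome="created", detail=detail,
                **by_id[record.bamara_id]))
            imported.append(record)

    csv_path = None
    if csv_out is not None:
        csv_path = write_csv(to_load, csv_out, config.mapping)

    report = new_report(outcomes, block_decisions, polydiagnostic, duplicates,
                        config.fingerprints)
    assert report.summary["total"] == len(patients)  # outcome conservation
    if report_dir is not None:
        write_report(report, report_dir)
    return RunResult(report=report, transform_results=results,
                     imported_records=imported, csv_path=csv_path,
                     read_stats=stats)


def _outcome_meta(result: TransformResult) -> dict:
    meta = {
        "n_blocks": result.n_blocks,
        "n_disease_groups": result.n_disease_groups,
    }
    if result.record is not None:
        main = result.record.main_diagnosis
        meta.update(
            pathway=main.pathway,
            orpha_in_allowed=main.orpha_in_allowed if main.orpha_code else None,
            has_additional=result.record.additional_diagnosis is not None,
            has_gene_variant=any(d.has_gene_variant
                                 for _, d in result.record.diagnoses()),
        )
    return meta


def _block_decision(result: TransformResult) -> dict:
    donors: dict[str, dict[str, int]] = {}
    for slot, diag in result.record.diagnoses():
        retained = result.retained_rows.get(slot)
        inherited = {f: row for f, row in diag.provenance.items()
                     if row != retained}
        if inherited:
            donors[slot] = inherited
    return {
        "bamara_id": result.bamara_id,
        "n_blocks": result.n_blocks,
        "n_disease_groups": result.n_disease_groups,
        "retained_rows": result.retained_rows,
        "inherited_fields": donors,
    }
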
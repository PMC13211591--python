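import datetime as dt
import json

import pytest

from redbridge.load_audit import (build_bundle, check_report_schema,
                                  parse_csv, record_to_row, submit, write_csv)
from redbridge.pipeline import run_pipeline
from redbridge.records import Identity
from redbridge.registry import MockRegistry, RegistryError
from redbridge.schema import template_columns
from redbridge.synthetic import CohortSpec, Stratum, generate
from redbridge.transform import transform_patient


@pytest.fixture()
def small_records(tmp_path, ref_config):
    spec = CohortSpec(n_patients=12, seed=11, strata=[
        Stratum(count=6, profile="plain_eligible", genetics=True),
        Stratum(count=3, profile="multiblock_single_disease"),
        Stratum(count=3, profile="two_eligible_reds", genetics=True),
    ])
    export, _ = generate(spec, tmp_path)
    from redbridge.export_io import read_export

    patients = read_export(export, ref_config.manifest)
    results = [transform_patient(p, ref_config.mapping, ref_config.terms)
               for p in patients]
    return [r.record for r in results if r.record and r.record.importable]


def test_empty_csv_is_header_only(tmp_path, mapping):
    path = write_csv([], tmp_path / "out.csv", mapping)
    lines = path.read_text(encoding="utf-8").splitlines()
    assert len(lines) == 1
    assert lines[0].split(",")[:4] == ["bamara_id", "surname", "given_name",
                                       "birth_date"]


def test_two_diagnosis_record_fills_both_column_groups(small_records, mapping,
                                                       tmp_path):
    record = next(r for r in small_records if r.additional_diagnosis)
    path = write_csv([record], tmp_path / "out.csv", mapping)
    (row,) = parse_csv(path)
    assert row["main_dia_orpha_code"] and row["add_dia_orpha_code"]
    assert row["main_dia_orpha_code"] != row["add_dia_orpha_code"]


def test_csv_round_trip_fidelity(small_records, mapping, tmp_path):
    path = write_csv(small_records, tmp_path / "out.csv", mapping)
    rows = parse_csv(path)
    assert len(rows) == len(small_records)
    for record, row in zip(small_records, rows):
        assert row == record_to_row(record, mapping)
    assert list(rows[0]) == template_columns(mapping)


def test_bundle_has_two_resources(small_records):
    bundle = build_bundle(small_records[0])
    types = [e["resource"]["resourceType"] for e in bundle["entry"]]
    assert types == ["Patient", "QuestionnaireResponse"]


def test_identity_only_in_demographics(small_records):
    record = small_records[0]
    bundle = build_bundle(record)
    questionnaire = json.dumps(bundle["entry"][1])
    assert record.identity.surname not in questionnaire
    assert record.identity.given_name not in questionnaire
    demographics = bundle["entry"][0]["resource"]
    assert demographics["name"][0]["family"] == record.identity.surname


def test_bundle_contains_both_diagnosis_groups(small_records):
    record = next(r for r in small_records if r.additional_diagnosis)
    items = build_bundle(record)["entry"][1]["resource"]["item"]
    link_ids = {i["linkId"] for i in items}
    assert {"main_diagnosis", "add_diagnosis"} <= link_ids


def test_submit_retries_transient_failure(small_records):
    registry = MockRegistry(fail_queue=["create_profile"])
    token = registry.issue_token()
    outcomes = submit([(small_records[0], build_bundle(small_records[0]))],
                      registry, token, pacing=0, max_retries=3)
    assert outcomes[0].outcome == "created"
    assert outcomes[0].profile_id


def test_submit_exhausts_retries_then_continues(small_records):
    registry = MockRegistry(fail_permanently=True)
    records = small_records[:2]
    outcomes = submit([(r, build_bundle(r)) for r in records], registry,
                      "tok-default", pacing=0, max_retries=3)
    assert [o.outcome for o in outcomes] == ["transport_failed"] * 2
    # 4 attempts (1 + 3 retries) on the first call of each patient
    assert registry.call_count == 8


def test_questionnaire_failure_records_orphan_profile(small_records):
    registry = MockRegistry(
        fail_queue=["create_questionnaire"] * 4)  # exhaust retries
    token = registry.issue_token()
    (outcome,) = submit([(small_records[0], build_bundle(small_records[0]))],
                        registry, token, pacing=0, max_retries=3)
    assert outcome.outcome == "transport_failed"
    assert outcome.profile_id  # profile exists, flagged for remediation


def test_registry_fetch_failure_aborts_run(tmp_path, ref_config):
    spec = CohortSpec(n_patients=2, seed=1, strata=[
        Stratum(count=2, profile="plain_eligible")])
    export, _ = generate(spec, tmp_path)
    registry = MockRegistry(fail_permanently=True)
    with pytest.raises(RegistryError):
        run_pipeline(export, ref_config, registry=registry)
    assert registry.write_count == 0  # never imported blind


def test_report_schema_valid_on_real_run(cargo_run):
    payload = json.loads(
        (cargo_run["report_dir"] / "audit_report.json").read_text("utf-8"))
    check_report_schema(payload)  # raises on violation
    assert payload["tool_version"]


def test_report_schema_rejects_bad_summary(cargo_run):
    payload = json.loads(
        (cargo_run["report_dir"] / "audit_report.json").read_text("utf-8"))
    payload["summary"]["created"] += 1
    with pytest.raises(ValueError, match="summary count"):
        check_report_schema(payload)


def test_empty_export_yields_all_zero_report(tmp_path, ref_config):
    spec = CohortSpec(n_patients=0, seed=1, strata=[])
    export, _ = generate(spec, tmp_path)
    result = run_pipeline(export, ref_config, registry=MockRegistry(),
                          report_dir=tmp_path / "rep")
    s = result.report.summary
    assert s["total"] == 0 and s["created"] == 0
    check_report_schema(result.report.to_dict())


def test_identity_dates_survive_csv(small_records, mapping, tmp_path):
    path = write_csv(small_records, tmp_path / "out.csv", mapping)
    for record, row in zip(small_records, parse_csv(path)):
        assert row["birth_date"] == record.identity.birth_date.isoformat()
        assert isinstance(record.identity.birth_date, dt.date)
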
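import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redbridge.inference import InferenceContext
from redbridge.records import (DiagnosticBlock, GeneEntry, Identity,
                               PatientRecord, VariantEntry)
from redbridge.transform import (UNDETERMINED, apply_direct, apply_inferred,
                                 assess_block, flatten_genetics, group_blocks,
                                 reconcile, select_diagnoses,
                                 transform_patient, unflatten_genetics,
                                 validate)

ALLOWED = "ORPHA:65"  # in the allowed list
VALID_NOT_ALLOWED = "ORPHA:829"  # in the terminology, not allowed
INVALID = "ORPHA:999999"
HPO_OK = "HP:0000505"
HPO_BAD = "HP:9999999"


def _block(row=0, orpha="", status="", hpo=(), date=None, genes=(), **fields):
    return DiagnosticBlock(source_row=row, orpha_code=orpha, status=status,
                           hpo_terms=list(hpo), assertion_date=date,
                           genes=list(genes), clinical_fields=dict(fields))


# ---------------------------------------------------------------------------
# eligibility

@pytest.mark.parametrize(
    ("status", "orpha", "hpo", "eligible", "pathway", "reason"),
    [
        ("Confirmé", ALLOWED, [], True, "confirmed_probable", ""),
        ("Probable", ALLOWED, [], True, "confirmed_probable", ""),
        ("Indéterminé", VALID_NOT_ALLOWED, [HPO_OK], True, "undetermined_hpo", ""),
        ("Indéterminé", "", [HPO_OK], True, "undetermined_hpo", ""),
        ("Probable", "", [], False, "none", "missing_orpha"),
        ("Confirmé", VALID_NOT_ALLOWED, [], False, "none", "orpha_not_allowed"),
        ("Confirmé", INVALID, [HPO_OK], False, "none", "invalid_orpha"),
        ("Indéterminé", ALLOWED, [], False, "none", "undetermined_no_valid_hpo"),
        ("Indéterminé", "", [HPO_BAD], False, "none", "undetermined_no_valid_hpo"),
        ("En cours", ALLOWED, [HPO_OK], False, "none", "status_not_eligible"),
        ("", ALLOWED, [], False, "none", "status_not_eligible"),
    ],
)
def test_eligibility_rule_table(mapping, terms, status, orpha, hpo, eligible,
                                pathway, reason):
    decision = assess_block(_block(orpha=orpha, status=status, hpo=hpo),
                            mapping.allowed_orpha, terms)
    assert (decision.eligible, decision.pathway, decision.reason) == \
        (eligible, pathway, reason)


@settings(derandomize=True, max_examples=300)
@given(
    status=st.sampled_from(["Confirmé", "Probable", "Indéterminé",
                            "En attente", ""]),
    orpha=st.sampled_from([ALLOWED, VALID_NOT_ALLOWED, INVALID, ""]),
    hpo=st.lists(st.sampled_from([HPO_OK, "HP:0000639", HPO_BAD]), max_size=3),
)
def test_eligibility_matches_truth_table_oracle(mapping, terms, status, orpha,
                                                hpo):
    """Eligibility is exactly the disjunction of the two pathways."""
    decision = assess_block(_block(orpha=orpha, status=status, hpo=hpo),
                            mapping.allowed_orpha, terms)
    # independent oracle, written straight from the rule statement
    confirmed_path = (status in ("Confirmé", "Probable")
                      and orpha == ALLOWED)
    undetermined_path = (status == "Indéterminé"
                         and any(h != HPO_BAD for h in hpo))
    assert decision.eligible == (confirmed_path or undetermined_path)
    assert decision.eligible == (decision.pathway != "none")


# ---------------------------------------------------------------------------
# grouping

def test_group_by_normalized_orpha():
    blocks = [_block(row=0, orpha="ORPHA:98666"), _block(row=1, orpha="98666"),
              _block(row=2, orpha="ORPHA:65")]
    groups = group_blocks(blocks)
    assert [(g.key, len(g.blocks)) for g in groups] == \
        [("ORPHA:98666", 2), ("ORPHA:65", 1)]


def test_group_sorted_most_recent_first():
    d = [dt.date(2020, 1, 1), dt.date(2021, 1, 1), dt.date(2022, 1, 1)]
    blocks = [_block(row=i, orpha="65", date=d[i]) for i in range(3)]
    (group,) = group_blocks(blocks)
    assert [b.assertion_date for b in group.blocks] == [d[2], d[1], d[0]]


def test_dateless_tiebreak_prefers_higher_row():
    blocks = [_block(row=5, orpha="65"), _block(row=9, orpha="65")]
    (group,) = group_blocks(blocks)
    assert [b.source_row for b in group.blocks] == [9, 5]


def test_undetermined_blocks_without_code_pool():
    blocks = [_block(row=0, status="Indéterminé", hpo=[HPO_OK]),
              _block(row=1, status="Indéterminé", hpo=[HPO_OK]),
              _block(row=2, orpha="65", status="Confirmé")]
    groups = {g.key: g for g in group_blocks(blocks)}
    assert len(groups[UNDETERMINED].blocks) == 2


# ---------------------------------------------------------------------------
# reconciliation

def test_older_value_survives_when_newer_empty():
    newer = _block(row=1, orpha="65", status="Confirmé",
                   date=dt.date(2023, 4, 6), **{"Latéralité": "Bilatérale"})
    older = _block(row=0, orpha="65", status="Probable",
                   date=dt.date(2020, 5, 1),
                   genes=[GeneEntry("CEP290", [VariantEntry("c.1A>G")])],
                   **{"Origine de l'ADN": "nucléaire"})
    (group,) = group_blocks([older, newer])
    merged = reconcile(group)
    assert merged.status == "Confirmé"  # newest wins
    assert merged.get("Origine de l'ADN") == "nucléaire"  # inherited
    assert merged.provenance["origine de l'adn"] == 0  # donor row recorded
    assert merged.genes[0].symbol == "CEP290"  # gene list inherited as a whole


def test_single_block_reconcile_is_identity():
    block = _block(row=3, orpha="65", status="Confirmé", hpo=[HPO_OK],
                   date=dt.date(2022, 2, 2), **{"Sévérité": "modérée"})
    (group,) = group_blocks([block])
    merged = reconcile(group)
    assert merged.status == block.status
    assert merged.hpo_terms == block.hpo_terms
    assert merged.assertion_date == block.assertion_date
    assert merged.clinical_fields == {"Sévérité": "modérée"}


def test_hpo_list_replaced_not_unioned():
    newer = _block(row=1, orpha="65", status="Confirmé", hpo=["HP:0000639"],
                   date=dt.date(2023, 1, 1))
    older = _block(row=0, orpha="65", status="Probable",
                   hpo=[HPO_OK, "HP:0000618"], date=dt.date(2020, 1, 1))
    merged = reconcile(group_blocks([older, newer])[0])
    assert merged.hpo_terms == ["HP:0000639"]


_FIELDS = ["F1", "F2", "F3", "F4", "F5", "F6"]


@st.composite
def _small_groups(draw):
    n = draw(st.integers(1, 3))
    dates = st.sampled_from([None, dt.date(2020, 1, 1), dt.date(2021, 6, 1)])
    blocks = []
    for row in range(n):
        fields = {f: draw(st.sampled_from(["", f"v{row}"])) for f in _FIELDS}
        fields = {k: v for k, v in fields.items() if v}
        blocks.append(_block(row=row, orpha="65", status="Confirmé",
                             date=draw(dates), **fields))
    return blocks


@settings(derandomize=True, max_examples=150)
@given(_small_groups())
def test_reconcile_matches_latest_nonempty_oracle(blocks):
    """Field-level merge equals a brute-force 'latest non-empty wins' oracle."""
    (group,) = group_blocks(blocks)
    merged = reconcile(group)
    order = sorted(blocks, key=lambda b: (b.assertion_date or dt.date.min,
                                          b.source_row), reverse=True)
    for field in _FIELDS:
        expected = next((b.clinical_fields[field] for b in order
                         if b.clinical_fields.get(field)), "")
        assert merged.get(field) == expected
        if expected:  # provenance points at the real donor
            donor = next(b for b in order if b.clinical_fields.get(field))
            assert merged.provenance[field.lower()] == donor.source_row


@settings(derandomize=True, max_examples=100)
@given(_small_groups(), st.permutations(range(3)))
def test_reconcile_is_order_insensitive(blocks, perm):
    shuffled = [blocks[i] for i in perm if i < len(blocks)]
    a = reconcile(group_blocks(blocks)[0])
    b = reconcile(group_blocks(shuffled)[0])
    assert a == b


# ---------------------------------------------------------------------------
# diagnosis selection

def _decisions(mapping, terms, blocks):
    return [assess_block(b, mapping.allowed_orpha, terms) for b in blocks]


def test_two_eligible_diseases_both_kept(mapping, terms):
    blocks = [_block(row=0, orpha="ORPHA:65", status="Confirmé",
                     date=dt.date(2020, 1, 1)),
              _block(row=1, orpha="ORPHA:77", status="Confirmé",
                     date=dt.date(2022, 1, 1))]
    selected, overflow = select_diagnoses(group_blocks(blocks),
                                          _decisions(mapping, terms, blocks))
    assert [g.key for g in selected] == ["ORPHA:77", "ORPHA:65"]
    assert not overflow


def test_ineligible_group_dropped(mapping, terms):
    blocks = [_block(row=0, orpha="ORPHA:65", status="Confirmé",
                     date=dt.date(2020, 1, 1)),
              _block(row=1, orpha=VALID_NOT_ALLOWED, status="Confirmé",
                     date=dt.date(2022, 1, 1))]
    selected, _ = select_diagnoses(group_blocks(blocks),
                                   _decisions(mapping, terms, blocks))
    assert [g.key for g in selected] == ["ORPHA:65"]


def test_three_eligible_keeps_two_most_recent(mapping, terms):
    blocks = [_block(row=i, orpha=o, status="Confirmé",
                     date=dt.date(2020 + i, 1, 1))
              for i, o in enumerate(["ORPHA:65", "ORPHA:77", "ORPHA:791"])]
    selected, overflow = select_diagnoses(group_blocks(blocks),
                                          _decisions(mapping, terms, blocks))
    assert [g.key for g in selected] == ["ORPHA:791", "ORPHA:77"]
    assert overflow


# ---------------------------------------------------------------------------
# mapping application

def test_direct_value_map(mapping):
    rule = mapping.rule_for_target("adm_patient_MR")
    assert apply_direct("Affected", rule) == "1"
    assert apply_direct("Not affected", rule) == "0"


def test_direct_without_value_map_passes_through(mapping):
    rule = mapping.rule_for_target("dia_dna_origin")
    assert apply_direct("nucléaire", rule) == "nucléaire"


def _ctx(birth=dt.date(2000, 1, 10), diagnosis=None):
    return InferenceContext(
        identity=Identity("Dupont", "Léa", birth),
        administrative={}, diagnosis=diagnosis)


def test_inferred_age_at_diagnosis(mapping, terms):
    block = _block(row=0, orpha="65", status="Confirmé",
                   date=dt.date(2023, 4, 6))
    merged = reconcile(group_blocks([block])[0])
    rule = mapping.rule_for_target("dia_age_at_diagnosis")
    assert apply_inferred(_ctx(diagnosis=merged), rule) == "23"


def test_inferred_default_when_input_missing(mapping):
    block = _block(row=0, orpha="65", status="Confirmé")  # no assertion date
    merged = reconcile(group_blocks([block])[0])
    rule = mapping.rule_for_target("dia_age_at_diagnosis")
    assert apply_inferred(_ctx(diagnosis=merged), rule) == rule.default_value


def test_inferred_active_unless_closed(mapping):
    rule = mapping.rule_for_target("status_active")
    assert apply_inferred(_ctx(), rule) == "active"
    ctx = InferenceContext(identity=Identity("X", "Y", None),
                           administrative={"Date de fermeture du dossier": "2020-01-01"})
    assert apply_inferred(ctx, rule) == "closed"


# ---------------------------------------------------------------------------
# genetic flattening

def test_flatten_counts_populated_slots(mapping):
    genes = [
        GeneEntry("ABCA4", [VariantEntry("c.1A>G"), VariantEntry("c.2C>T")]),
        GeneEntry("CEP290", [VariantEntry("c.9del")]),
    ]
    slots, warnings = flatten_genetics(genes, mapping)
    populated = {k: v for k, v in slots.items() if v}
    # 2 symbols + 3 variant descriptions, nothing else set
    assert populated == {
        "gene1_symbol": "ABCA4",
        "gene1_variant1_description": "c.1A>G",
        "gene1_variant2_description": "c.2C>T",
        "gene2_symbol": "CEP290",
        "gene2_variant1_description": "c.9del",
    }
    assert warnings == []


def test_flatten_truncates_beyond_three(mapping):
    genes = [GeneEntry(f"G{i}".replace("G0", "PAX6")) for i in range(4)]
    slots, warnings = flatten_genetics(genes, mapping)
    assert slots["gene3_symbol"] and "gene4_symbol" not in slots
    assert any(w.startswith("truncated_genes") for w in warnings)


@st.composite
def _genetics(draw):
    n_genes = draw(st.integers(0, 3))
    genes = []
    for i in range(n_genes):
        n_var = draw(st.integers(0, 3))
        variants = [
            VariantEntry(description=f"c.{i}{j}A>G",
                         classification=draw(st.sampled_from(["", "Pathogène"])),
                         zygosity=draw(st.sampled_from(["", "Homozygote"])))
            for j in range(n_var)
        ]
        genes.append(GeneEntry(symbol=f"GENE{i}", variants=variants,
                               attributes=draw(st.fixed_dictionaries(
                                   {}, optional={"transmission": st.just("AR")}))))
    return genes


@settings(derandomize=True, max_examples=100)
@given(_genetics())
def test_flatten_unflatten_round_trip(mapping, genes):
    slots, _ = flatten_genetics(genes, mapping)
    assert unflatten_genetics(slots, mapping) == genes


# ---------------------------------------------------------------------------
# validation and full transform

def _patient(blocks, pid="P1"):
    return PatientRecord(bamara_id=pid,
                         identity=Identity("Dupont", "Léa", dt.date(2000, 1, 10)),
                         administrative={}, blocks=blocks)


def test_invalid_hpo_blocks_whole_patient(mapping, terms):
    block = _block(row=0, orpha="ORPHA:65", status="Confirmé",
                   hpo=[HPO_BAD], date=dt.date(2022, 1, 1))
    result = transform_patient(_patient([block]), mapping, terms)
    assert not result.excluded
    assert result.record.validation_errors == \
        [f"main.dia_hpo_terms:invalid_code:{HPO_BAD}:HPO"]
    assert not result.record.importable


def test_valid_record_has_no_errors(mapping, terms):
    block = _block(row=0, orpha="ORPHA:65", status="Confirmé",
                   hpo=[HPO_OK], date=dt.date(2022, 1, 1))
    result = transform_patient(_patient([block]), mapping, terms)
    assert result.record.validation_errors == []


def test_validation_reports_all_errors(mapping, terms):
    block = _block(row=0, orpha="ORPHA:65", status="Confirmé",
                   hpo=[HPO_BAD],
                   genes=[GeneEntry("NOTAGENE", [VariantEntry("c.1A>G")])],
                   date=dt.date(2022, 1, 1))
    result = transform_patient(_patient([block]), mapping, terms)
    assert len(result.record.validation_errors) == 2  # no short-circuit


def test_zero_blocks_excluded(mapping, terms):
    result = transform_patient(_patient([]), mapping, terms)
    assert result.excluded
    assert result.exclusion_reasons == ["no_diagnostic_block"]


def test_merged_diagnosis_matches_hand_merge(mapping, terms):
    """Two staggered blocks for one disease: the transform output carries the
    newest status/date and the inherited older field, with provenance."""
    older = _block(row=0, orpha="65", status="Probable",
                   date=dt.date(2020, 5, 1),
                   **{"Origine de l'ADN": "nucléaire"})
    newer = _block(row=1, orpha="ORPHA:65", status="Confirmé",
                   hpo=[HPO_OK], date=dt.date(2023, 4, 6))
    result = transform_patient(_patient([older, newer]), mapping, terms)
    diag = result.record.main_diagnosis
    assert diag.fields["dia_status"] == "confirmed"
    assert diag.fields["dia_orpha_code"] == "ORPHA:65"
    assert diag.fields["dia_assertion_date"] == "2023-04-06"
    assert diag.fields["dia_dna_origin"] == "nucléaire"
    assert diag.provenance["dia_dna_origin"] == 0
    assert diag.provenance["dia_status"] == 1
    assert diag.fields["dia_n_source_blocks"] == "2"
    assert result.record.additional_diagnosis is None
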
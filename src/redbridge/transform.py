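"""Business rules turning source patient records into validated target records.

Four rule families operate in sequence, each implemented as a discrete
function so the audit report can show every decision:

1. *Eligibility* (:func:`assess_block`) — a diagnostic block enters the
   import either with status Confirmed/Probable and an allowed ORPHA code,
   or with status Undetermined and at least one valid phenotype (HPO) term
   (in which case the ORPHA code is not required to be on the allowed list).
2. *Block reconciliation* (:func:`group_blocks` / :func:`reconcile`) — blocks
   describing the same disease are merged most-recent-first: newer values
   replace older ones, while older values survive when no newer information
   exists.  Field-level provenance records the donor row.
3. *Polydiagnostic handling* (:func:`select_diagnoses`) — each eligible
   disease becomes its own diagnosis entry; the target schema caps a record
   at one main plus one additional diagnosis.
4. *Mapping and validation* (:func:`apply_direct` / :func:`apply_inferred` /
   :func:`flatten_genetics` / :func:`validate`) — configured value
   translations, derived calculations with defaults, genetic flattening into
   3 genes x 3 variants slots, and terminology checks.  Any invalid code in a
   mapped field blocks the whole patient's import.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

from ._text import fold_header
from .inference import INFERENCES, InferenceContext
from .mapping import MappingConfig, MappingRule
from .records import (DiagnosticBlock, GeneEntry, Identity, PatientRecord,
                      VariantEntry, normalize_status)
from .schema import MAX_GENES, MAX_VARIANTS
from .terminology import TerminologySet, is_valid, normalize_code

log = logging.getLogger("redbridge")

UNDETERMINED = "UNDETERMINED"
ELIGIBLE_STATUSES = ("confirmed", "probable")

# targets with dedicated wiring into the merged-diagnosis core fields
_CORE_DIAGNOSIS_TARGETS = {
    "dia_orpha_code", "dia_status", "dia_hpo_terms", "dia_assertion_date",
}


# ---------------------------------------------------------------------------
# eligibility

@dataclass(frozen=True)
class EligibilityDecision:
    bamara_id: str
    source_row: int
    eligible: bool
    pathway: str  # confirmed_probable | undetermined_hpo | none
    reason: str  # coded reason when ineligible, "" otherwise


def assess_block(
    block: DiagnosticBlock,
    allowed: set[str],
    terms: dict[str, TerminologySet],
    bamara_id: str = "",
) -> EligibilityDecision:
    """Decide whether one diagnostic block qualifies for import."""
    status = block.status_normalized
    orpha = block.orpha_normalized
    valid_hpo = [t for t in block.hpo_terms if is_valid(t, terms["HPO"])]

    if status == "undetermined":
        if valid_hpo:
            return EligibilityDecision(bamara_id, block.source_row, True,
                                       "undetermined_hpo", "")
        return EligibilityDecision(bamara_id, block.source_row, False, "none",
                                   "undetermined_no_valid_hpo")
    if status in ELIGIBLE_STATUSES:
        if not orpha:
            return EligibilityDecision(bamara_id, block.source_row, False,
                                       "none", "missing_orpha")
        if not is_valid(orpha, terms["ORPHA"]):
            return EligibilityDecision(bamara_id, block.source_row, False,
                                       "none", "invalid_orpha")
        if orpha not in allowed:
            return EligibilityDecision(bamara_id, block.source_row, False,
                                       "none", "orpha_not_allowed")
        return EligibilityDecision(bamara_id, block.source_row, True,
                                   "confirmed_probable", "")
    return EligibilityDecision(bamara_id, block.source_row, False, "none",
                               "status_not_eligible")


# ---------------------------------------------------------------------------
# grouping and reconciliation

def _recency_key(block: DiagnosticBlock) -> tuple:
    # most recent first: later assertion date, then later export row
    # (absent dates sort oldest)
    date = block.assertion_date or dt.date.min
    return (date, block.source_row)


@dataclass
class DiseaseGroup:
    key: str  # normalized ORPHA code, UNDETERMINED, or NONE:<row>
    blocks: list[DiagnosticBlock]  # most recent first

    def __post_init__(self) -> None:
        self.blocks.sort(key=_recency_key, reverse=True)


def group_blocks(blocks: list[DiagnosticBlock]) -> list[DiseaseGroup]:
    """Partition a patient's blocks by disease.

    Blocks sharing a normalized ORPHA code form one group.  Undetermined
    blocks without a code pool into a single per-patient UNDETERMINED group
    (one unresolved diagnostic journey); any other code-less block becomes a
    singleton group (it can never be selected, but stays auditable).
    """
    grouped: dict[str, list[DiagnosticBlock]] = {}
    order: list[str] = []
    for block in blocks:
        orpha = block.orpha_normalized
        if orpha:
            key = orpha
        elif block.status_normalized == "undetermined":
            key = UNDETERMINED
        else:
            key = f"NONE:{block.source_row}"
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(block)
    return [DiseaseGroup(key=k, blocks=grouped[k]) for k in order]


@dataclass
class MergedDiagnosis:
    """Field-level merge of one disease group, before mapping."""

    key: str
    orpha_code: str  # normalized, "" for the UNDETERMINED group
    status: str  # verbatim winner
    hpo_terms: list[str]
    assertion_date: dt.date | None
    genes: list[GeneEntry]
    clinical_fields: dict[str, str]  # source header -> value
    provenance: dict[str, int]  # field/header -> donor source_row
    n_source_blocks: int

    @property
    def status_normalized(self) -> str:
        return normalize_status(self.status)

    def get(self, header: str) -> str:
        folded = fold_header(header)
        for k, v in self.clinical_fields.items():
            if fold_header(k) == folded:
                return v
        return ""


def reconcile(group: DiseaseGroup) -> MergedDiagnosis:
    """Merge a disease group most-recent-first.

    The most recent block seeds the result; every field still empty is then
    filled from the next most recent block holding a non-empty value, so
    newer values replace older ones and older values survive only where no
    newer information exists.  The phenotype term list and the gene list are
    replaced as a whole, never unioned, and inherited only when the newer
    list is empty.  Provenance records each field's donor row.
    """
    if not group.blocks:
        raise ValueError("cannot reconcile an empty group")
    provenance: dict[str, int] = {}
    clinical: dict[str, str] = {}
    status = ""
    hpo: list[str] = []
    genes: list[GeneEntry] = []
    date: dt.date | None = None
    orpha = ""

    for block in group.blocks:  # most recent first
        for header, value in block.clinical_fields.items():
            folded = fold_header(header)
            if value and folded not in provenance:
                clinical[header] = value
                provenance[folded] = block.source_row
        if block.status and "@status" not in provenance:
            status = block.status
            provenance["@status"] = block.source_row
        if block.hpo_terms and "@hpo" not in provenance:
            hpo = list(block.hpo_terms)
            provenance["@hpo"] = block.source_row
        if block.genes and "@genes" not in provenance:
            genes = block.genes
            provenance["@genes"] = block.source_row
        if block.assertion_date and "@date" not in provenance:
            date = block.assertion_date
            provenance["@date"] = block.source_row
        if block.orpha_normalized and not orpha:
            orpha = block.orpha_normalized

    return MergedDiagnosis(
        key=group.key,
        orpha_code="" if group.key == UNDETERMINED else orpha,
        status=status,
        hpo_terms=hpo,
        assertion_date=date,
        genes=genes,
        clinical_fields=clinical,
        provenance=provenance,
        n_source_blocks=len(group.blocks),
    )


def select_diagnoses(
    groups: list[DiseaseGroup], decisions: list[EligibilityDecision]
) -> tuple[list[DiseaseGroup], bool]:
    """Keep only groups containing at least one eligible block, ordered by the
    recency of their best block; at most two survive (main + additional).

    Returns (selected groups, overflow flag)."""
    eligible_rows = {d.source_row for d in decisions if d.eligible}
    survivors = [g for g in groups if any(b.source_row in eligible_rows
                                          for b in g.blocks)]
    survivors.sort(key=lambda g: _recency_key(g.blocks[0]), reverse=True)
    overflow = len(survivors) > 2
    if overflow:
        log.warning("more than two eligible diseases; keeping the two most recent")
    return survivors[:2], overflow


# ---------------------------------------------------------------------------
# mapping application

def apply_direct(value: str, rule: MappingRule) -> str:
    """Translate a source value through a direct rule's value map.

    A value-map hit returns the mapped value; a rule without a value map
    passes the source value through verbatim; a miss also passes through
    verbatim (terminology-bound misses are caught by :func:`validate`)."""
    if not value:
        return ""
    if rule.value_map:
        return rule.value_map.get(value, value)
    return value


def apply_inferred(ctx: InferenceContext, rule: MappingRule) -> str:
    """Dispatch to the registered inference; missing/inconsistent inputs fall
    back to the rule's configured default value."""
    fn = INFERENCES[rule.inference_id]
    result = fn(ctx)
    return rule.default_value if result is None else result


def flatten_genetics(
    genes: list[GeneEntry], config: MappingConfig
) -> tuple[dict[str, str], list[str]]:
    """Flatten gene/variant structure into single-level slots.

    Gene *i* (1-based, source order) fills ``gene{i}_<family>`` slots; its
    variant *j* fills ``gene{i}_variant{j}_<family>`` slots.  More than 3
    genes, or 3 variants per gene, are truncated in source order with a
    warning.  Unfilled slots are empty strings.  Returns (slots, warnings).
    """
    warnings: list[str] = []
    gene_fams = [r.family for r in config.rules_in_scope("gene")]
    var_fams = [r.family for r in config.rules_in_scope("variant")]
    slots: dict[str, str] = {}
    for i in range(1, MAX_GENES + 1):
        for fam in gene_fams:
            slots[f"gene{i}_{fam}"] = ""
        for j in range(1, MAX_VARIANTS + 1):
            for fam in var_fams:
                slots[f"gene{i}_variant{j}_{fam}"] = ""
    if len(genes) > MAX_GENES:
        warnings.append(f"truncated_genes:{len(genes)}")
    for i, gene in enumerate(genes[:MAX_GENES], start=1):
        for fam in gene_fams:
            slots[f"gene{i}_{fam}"] = gene.get(fam)
        if len(gene.variants) > MAX_VARIANTS:
            warnings.append(f"truncated_variants:{gene.symbol}:{len(gene.variants)}")
        for j, variant in enumerate(gene.variants[:MAX_VARIANTS], start=1):
            for fam in var_fams:
                slots[f"gene{i}_variant{j}_{fam}"] = variant.get(fam)
    return slots, warnings


def unflatten_genetics(
    slots: dict[str, str], config: MappingConfig
) -> list[GeneEntry]:
    """Inverse of :func:`flatten_genetics` on the bounded 3x3 domain."""
    gene_fams = [r.family for r in config.rules_in_scope("gene")]
    var_fams = [r.family for r in config.rules_in_scope("variant")]
    genes: list[GeneEntry] = []
    for i in range(1, MAX_GENES + 1):
        symbol = slots.get(f"gene{i}_symbol", "")
        if not symbol:
            continue
        attrs = {f: slots.get(f"gene{i}_{f}", "") for f in gene_fams
                 if f != "symbol" and slots.get(f"gene{i}_{f}", "")}
        gene = GeneEntry(symbol=symbol, attributes=attrs)
        for j in range(1, MAX_VARIANTS + 1):
            desc = slots.get(f"gene{i}_variant{j}_description", "")
            if not desc:
                continue
            core = {"description", "classification", "zygosity"}
            extra = {f: slots.get(f"gene{i}_variant{j}_{f}", "")
                     for f in var_fams
                     if f not in core and slots.get(f"gene{i}_variant{j}_{f}", "")}
            gene.variants.append(VariantEntry(
                description=desc,
                classification=slots.get(f"gene{i}_variant{j}_classification", ""),
                zygosity=slots.get(f"gene{i}_variant{j}_zygosity", ""),
                attributes=extra,
            ))
        genes.append(gene)
    return genes


# ---------------------------------------------------------------------------
# target record assembly

@dataclass
class FreddDiagnosis:
    orpha_code: str  # normalized or ""
    status: str  # normalized status
    hpo_terms: list[str]
    fields: dict[str, str]  # target_field -> value (diagnosis-scope rules)
    flattened_genetics: dict[str, str]  # slot -> value
    provenance: dict[str, int]  # target_field -> donor source_row
    passthrough: dict[str, str] = field(default_factory=dict)  # unmapped headers
    pathway: str = ""
    n_source_blocks: int = 1
    orpha_in_allowed: bool = False
    has_gene_variant: bool = False


@dataclass
class FreddRecord:
    bamara_id: str
    identity: Identity
    administrative: dict[str, str]  # target_field -> value
    main_diagnosis: FreddDiagnosis
    additional_diagnosis: FreddDiagnosis | None = None
    validation_errors: list[str] = field(default_factory=list)
    review_flags: list[str] = field(default_factory=list)

    @property
    def importable(self) -> bool:
        return not self.validation_errors

    def diagnoses(self) -> list[tuple[str, FreddDiagnosis]]:
        out = [("main", self.main_diagnosis)]
        if self.additional_diagnosis is not None:
            out.append(("add", self.additional_diagnosis))
        return out


@dataclass
class TransformResult:
    bamara_id: str
    record: FreddRecord | None  # None when excluded by eligibility
    exclusion_reasons: list[str]
    decisions: list[EligibilityDecision]
    n_blocks: int
    n_disease_groups: int
    overflow: bool = False
    retained_rows: dict[str, int] = field(default_factory=dict)  # diag slot -> seed row

    @property
    def excluded(self) -> bool:
        return self.record is None


def _build_diagnosis(
    merged: MergedDiagnosis,
    record: PatientRecord,
    config: MappingConfig,
    rank: int,
    n_diagnoses: int,
    pathway: str,
    allowed: set[str],
) -> FreddDiagnosis:
    fields: dict[str, str] = {}
    provenance: dict[str, int] = {}
    ctx = InferenceContext(
        identity=record.identity,
        administrative=record.administrative,
        diagnosis=merged,
        diagnosis_rank=rank,
        n_diagnoses=n_diagnoses,
    )
    has_gv = any(g.variants for g in merged.genes)
    for rule in config.rules_in_scope("diagnosis"):
        target = rule.target_field
        if target in _CORE_DIAGNOSIS_TARGETS:
            if target == "dia_orpha_code":
                value, prov = merged.orpha_code, "@orpha"
            elif target == "dia_status":
                value, prov = apply_direct(merged.status, rule), "@status"
            elif target == "dia_hpo_terms":
                value, prov = ";".join(merged.hpo_terms), "@hpo"
            else:  # dia_assertion_date
                value = merged.assertion_date.isoformat() if merged.assertion_date else ""
                prov = "@date"
            fields[target] = value
            if prov in merged.provenance:
                provenance[target] = merged.provenance[prov]
        elif rule.kind == "direct":
            raw = merged.get(rule.source_label)
            fields[target] = apply_direct(raw, rule)
            folded = fold_header(rule.source_label)
            if folded in merged.provenance:
                provenance[target] = merged.provenance[folded]
        elif rule.kind == "inferred":
            fields[target] = apply_inferred(ctx, rule)
        elif rule.kind == "reconstructed":
            # diagnosis-scope genetic summary
            fields[target] = "positif" if has_gv else rule.default_value

    slots, warnings = flatten_genetics(merged.genes, config)
    if "@genes" in merged.provenance:
        for slot, value in slots.items():
            if value:
                provenance[slot] = merged.provenance["@genes"]

    mapped_headers = {fold_header(r.source_label) for r in config.rules}
    passthrough = {
        h: v for h, v in merged.clinical_fields.items()
        if v and fold_header(h) not in mapped_headers
    }

    diag = FreddDiagnosis(
        orpha_code=merged.orpha_code,
        status=merged.status_normalized,
        hpo_terms=list(merged.hpo_terms),
        fields=fields,
        flattened_genetics=slots,
        provenance=provenance,
        passthrough=passthrough,
        pathway=pathway,
        n_source_blocks=merged.n_source_blocks,
        orpha_in_allowed=bool(merged.orpha_code) and merged.orpha_code in allowed,
        has_gene_variant=has_gv,
    )
    diag.review_warnings = warnings  # type: ignore[attr-defined]
    return diag


def validate(
    record: FreddRecord,
    terms: dict[str, TerminologySet],
    config: MappingConfig,
) -> FreddRecord:
    """Check every terminology-bound mapped field; append coded errors.

    All fields are checked (no short-circuit); any error blocks the whole
    patient's import.
    """
    bound = {r.target_field: r.terminology_system
             for r in config.rules if r.terminology_system}
    for target, system in bound.items():
        rule = config.rule_for_target(target)
        if rule.scope == "patient":
            _check_codes(record.validation_errors, "patient", target,
                         record.administrative.get(target, ""), terms[system])
    for slot_name, diag in record.diagnoses():
        for target, system in bound.items():
            rule = config.rule_for_target(target)
            if rule.scope == "diagnosis":
                _check_codes(record.validation_errors, slot_name, target,
                             diag.fields.get(target, ""), terms[system])
            elif rule.scope == "gene":
                for i in range(1, MAX_GENES + 1):
                    _check_codes(record.validation_errors, slot_name,
                                 f"gene{i}_{rule.family}",
                                 diag.flattened_genetics.get(f"gene{i}_{rule.family}", ""),
                                 terms[system])
    return record


def _check_codes(errors: list[str], slot: str, target: str, value: str,
                 tset: TerminologySet) -> None:
    if not value:
        return
    for code in value.split(";"):
        code = code.strip()
        if code and not is_valid(code, tset):
            errors.append(f"{slot}.{target}:invalid_code:{code}:{tset.system}")


def transform_patient(
    record: PatientRecord,
    config: MappingConfig,
    terms: dict[str, TerminologySet],
) -> TransformResult:
    """Full transformation of one patient: eligibility, grouping,
    reconciliation, diagnosis selection, mapping, flattening, validation."""
    if not record.blocks:
        return TransformResult(record.bamara_id, None, ["no_diagnostic_block"],
                               [], 0, 0)

    decisions = [assess_block(b, config.allowed_orpha, terms, record.bamara_id)
                 for b in record.blocks]
    groups = group_blocks(record.blocks)
    selected, overflow = select_diagnoses(groups, decisions)

    if not selected:
        reasons = sorted({d.reason for d in decisions if d.reason})
        return TransformResult(record.bamara_id, None, reasons, decisions,
                               len(record.blocks), len(groups))

    eligible_rows = {d.source_row: d.pathway for d in decisions if d.eligible}

    def group_pathway(g: DiseaseGroup) -> str:
        for b in g.blocks:  # most recent eligible block decides the pathway
            if b.source_row in eligible_rows:
                return eligible_rows[b.source_row]
        return "none"

    diagnoses: list[FreddDiagnosis] = []
    retained: dict[str, int] = {}
    for rank, group in enumerate(selected, start=1):
        merged = reconcile(group)
        diagnoses.append(
            _build_diagnosis(merged, record, config, rank, len(selected),
                             group_pathway(group), config.allowed_orpha)
        )
        slot = "main" if rank == 1 else "add"
        retained[slot] = group.blocks[0].source_row

    administrative: dict[str, str] = {}
    ctx = InferenceContext(
        identity=record.identity,
        administrative=record.administrative,
        diagnosis=None,
        n_diagnoses=len(selected),
    )
    admin_folded = {fold_header(k): v for k, v in record.administrative.items()}
    for rule in config.rules_in_scope("patient"):
        if rule.kind == "direct":
            raw = admin_folded.get(fold_header(rule.source_label), "")
            administrative[rule.target_field] = apply_direct(raw, rule)
        else:
            administrative[rule.target_field] = apply_inferred(ctx, rule)

    fredd = FreddRecord(
        bamara_id=record.bamara_id,
        identity=record.identity,
        administrative=administrative,
        main_diagnosis=diagnoses[0],
        additional_diagnosis=diagnoses[1] if len(diagnoses) > 1 else None,
    )
    if overflow:
        fredd.review_flags.append("diagnosis_overflow")
    for _, diag in fredd.diagnoses():
        fredd.review_flags.extend(getattr(diag, "review_warnings", []))
        fredd.review_flags.extend(f"passthrough:{h}" for h in diag.passthrough)

    validate(fredd, terms, config)
    return TransformResult(record.bamara_id, fredd, [], decisions,
                           len(record.blocks), len(groups), overflow, retained)
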
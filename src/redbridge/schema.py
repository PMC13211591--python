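"""Target questionnaire schema: field inventory and CSV template columns.

The target record is single-level: patient-scope fields plus two diagnosis
slots (``main_`` / ``add_`` prefixes), each carrying the diagnosis-scope
fields and the flattened genetic slots (3 genes x 3 variants).  The column
inventory is derived from the mapping configuration so that configuration
and schema cannot drift apart.
"""

from __future__ import annotations

from .mapping import MappingConfig

MAX_GENES = 3
MAX_VARIANTS = 3

IDENTITY_COLUMNS = ["bamara_id", "surname", "given_name", "birth_date"]
DIAGNOSIS_PREFIXES = ("main_", "add_")

# fixed order of slot families inside one diagnosis, taken from config order


def gene_slot_fields(config: MappingConfig) -> list[str]:
    """Flattened genetic slot names for one diagnosis, in template order:
    gene1 fields, gene1_variant1..3 fields, gene2 fields, ..."""
    gene_fams = [r.family for r in config.rules_in_scope("gene")]
    var_fams = [r.family for r in config.rules_in_scope("variant")]
    out: list[str] = []
    for i in range(1, MAX_GENES + 1):
        out.extend(f"gene{i}_{fam}" for fam in gene_fams)
        for j in range(1, MAX_VARIANTS + 1):
            out.extend(f"gene{i}_variant{j}_{fam}" for fam in var_fams)
    return out


def diagnosis_fields(config: MappingConfig) -> list[str]:
    """Per-diagnosis fields (unprefixed): mapped diagnosis-scope targets,
    then the flattened genetic slots."""
    fields = [r.target_field for r in config.rules_in_scope("diagnosis")]
    return fields + gene_slot_fields(config)


def patient_fields(config: MappingConfig) -> list[str]:
    return [r.target_field for r in config.rules_in_scope("patient")]


def template_columns(config: MappingConfig) -> list[str]:
    """Full CSV template column order."""
    cols = list(IDENTITY_COLUMNS) + patient_fields(config)
    for prefix in DIAGNOSIS_PREFIXES:
        cols.extend(prefix + f for f in diagnosis_fields(config))
    return cols


def terminology_bound_fields(config: MappingConfig) -> dict[str, str]:
    """target_field -> system for every terminology-bound mapped field."""
    return {
        r.target_field: r.terminology_system
        for r in config.rules
        if r.terminology_system
    }
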
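"""Externalized source-to-target variable mapping and allowed-ORPHA list.

All transformation knowledge lives in two hand-editable files, not in code:

* ``mapping.csv`` — one row per rule: a natural-language source column label,
  a target-schema field, a kind (``direct`` / ``inferred`` /
  ``reconstructed``), an optional value map, an optional default, an optional
  terminology binding, and (for inferred rules) the identifier of a
  registered inference function.
* ``allowed_orpha.txt`` — the ORPHA codes a confirmed/probable diagnosis must
  carry to be eligible; one code per line, ``#`` comments.

The reference configuration shipped under ``redbridge/data`` holds 54 direct,
17 inferred and 12 reconstructed rules over 83 unique source labels.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

from ._text import fold_header
from .terminology import SYSTEMS, normalize_code

KINDS = ("direct", "inferred", "reconstructed")


class MappingError(ValueError):
    """Schema or integrity violation in the mapping configuration."""


@dataclass(frozen=True)
class MappingRule:
    source_label: str
    target_field: str
    kind: str
    value_map: dict[str, str] = field(default_factory=dict)
    default_value: str = ""
    terminology_system: str = ""
    inference_id: str = ""

    @property
    def scope(self) -> str:
        """``patient`` | ``diagnosis`` | ``gene`` | ``variant``, derived from
        the target-field prefix convention of the target schema."""
        t = self.target_field
        if t.startswith(("adm_", "status_")):
            return "patient"
        if t.startswith("gen_gene_"):
            return "gene"
        if t.startswith("gen_variant_"):
            return "variant"
        return "diagnosis"

    @property
    def family(self) -> str:
        """Slot-family name for gene/variant-scope rules (e.g. ``symbol``)."""
        for prefix in ("gen_gene_", "gen_variant_"):
            if self.target_field.startswith(prefix):
                return self.target_field[len(prefix):]
        return ""


@dataclass
class MappingConfig:
    rules: list[MappingRule]
    allowed_orpha: set[str]

    def __post_init__(self) -> None:
        self._by_header = {fold_header(r.source_label): r for r in self.rules}
        self._by_target = {r.target_field: r for r in self.rules}

    def counts(self) -> dict[str, int]:
        out = {k: 0 for k in KINDS}
        for r in self.rules:
            out[r.kind] += 1
        return out

    def rule_for_target(self, target_field: str) -> MappingRule | None:
        return self._by_target.get(target_field)

    def rules_in_scope(self, scope: str) -> list[MappingRule]:
        return [r for r in self.rules if r.scope == scope]


def _parse_value_map(raw: str) -> dict[str, str]:
    # "Affected=1;Not affected=0" -> {"Affected": "1", "Not affected": "0"}
    out: dict[str, str] = {}
    for pair in raw.split(";"):
        pair = pair.strip()
        if not pair:
            continue
        if "=" not in pair:
            raise MappingError(f"value_map entry {pair!r} lacks '='")
        src, dst = pair.split("=", 1)
        out[src.strip()] = dst.strip()
    return out


def _serialize_value_map(vmap: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in vmap.items())


def load_rules(path: str | Path) -> list[MappingRule]:
    """Read mapping.csv, validating each row; errors name the rule index."""
    rules: list[MappingRule] = []
    seen_targets: set[str] = set()
    seen_labels: set[str] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"source_label", "target_field", "kind"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise MappingError(f"{path}: missing required columns {sorted(required)}")
        for i, row in enumerate(reader, start=1):
            kind = (row.get("kind") or "").strip()
            if kind not in KINDS:
                raise MappingError(f"{path} rule {i}: unknown kind {kind!r}")
            target = (row.get("target_field") or "").strip()
            label = (row.get("source_label") or "").strip()
            if not target or not label:
                raise MappingError(f"{path} rule {i}: empty source_label/target_field")
            if target in seen_targets:
                raise MappingError(
                    f"{path} rule {i}: duplicate target_field {target!r}"
                )
            folded = fold_header(label)
            if folded in seen_labels:
                raise MappingError(
                    f"{path} rule {i}: duplicate source_label {label!r}"
                )
            system = (row.get("terminology_system") or "").strip()
            if system and system not in SYSTEMS:
                raise MappingError(
                    f"{path} rule {i}: unknown terminology system {system!r}"
                )
            inference_id = (row.get("inference_id") or "").strip()
            if kind == "inferred" and not inference_id:
                raise MappingError(f"{path} rule {i}: inferred rule lacks inference_id")
            if kind == "direct" and inference_id:
                raise MappingError(f"{path} rule {i}: direct rule carries inference_id")
            rules.append(
                MappingRule(
                    source_label=label,
                    target_field=target,
                    kind=kind,
                    value_map=_parse_value_map(row.get("value_map") or ""),
                    default_value=(row.get("default_value") or "").strip(),
                    terminology_system=system,
                    inference_id=inference_id,
                )
            )
            seen_targets.add(target)
            seen_labels.add(folded)
    return rules


def load_allowed_orpha(path: str | Path) -> set[str]:
    allowed: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            code = line.split("#", 1)[0].strip()
            if code:
                allowed.add(normalize_code(code, "ORPHA"))
    if not allowed:
        raise MappingError(f"{path}: allowed-ORPHA list is empty")
    return allowed


def load_mapping(rules_path: str | Path, allowed_path: str | Path) -> MappingConfig:
    """Load and validate the full mapping configuration."""
    return MappingConfig(
        rules=load_rules(rules_path), allowed_orpha=load_allowed_orpha(allowed_path)
    )


def rule_for(source_label: str, config: MappingConfig) -> MappingRule | None:
    """Exact lookup after header normalization (trim / whitespace / case /
    accent / apostrophe folding); ``None`` signals pass-through behaviour."""
    return config._by_header.get(fold_header(source_label))


def save_mapping(config: MappingConfig, rules_path: str | Path,
                 allowed_path: str | Path) -> None:
    """Serialize a config back to its two files (load∘save∘load is identity)."""
    with open(rules_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source_label", "target_field", "kind", "value_map",
                    "default_value", "terminology_system", "inference_id"])
        for r in config.rules:
            w.writerow([r.source_label, r.target_field, r.kind,
                        _serialize_value_map(r.value_map), r.default_value,
                        r.terminology_system, r.inference_id])
    with open(allowed_path, "w", encoding="utf-8") as fh:
        for code in sorted(config.allowed_orpha):
            fh.write(code + "\n")


def packaged_data_dir() -> Path:
    """Directory of the reference configuration shipped with the package."""
    return Path(importlib.resources.files("redbridge") / "data")


def load_reference_mapping() -> MappingConfig:
    data = packaged_data_dir()
    return load_mapping(data / "mapping.csv", data / "allowed_orpha.txt")
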
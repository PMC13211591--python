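"""Reading of multi-sheet source-registry exports.

The source system exports one workbook per center, one worksheet per clinical
domain, rows keyed by a local patient identifier; headers are natural-language
French labels and values are free text.  A directory of per-sheet CSV files
is accepted as an equivalent dialect of the workbook (same manifest, one file
per sheet named ``<sheet>.csv``), which keeps tests and large synthetic runs
format-light.

A ``sheets.yaml`` manifest declares each sheet's role and key columns; the
synthetic generator writes and this reader reads through the same manifest.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._text import fold_header
from .mapping import packaged_data_dir
from .records import DiagnosticBlock, GeneEntry, Identity, PatientRecord, VariantEntry
from .terminology import normalize_code

log = logging.getLogger("redbridge")


class ExportFormatError(ValueError):
    """Fatal structural problem (missing sheet or identifier column)."""


@dataclass
class SheetSpec:
    name: str
    role: str
    id_column: str
    identity: dict[str, str] = field(default_factory=dict)
    orpha_column: str = ""
    status_column: str = ""
    hpo_column: str = ""
    date_column: str = ""
    gene_level: dict[str, str] = field(default_factory=dict)
    variant_level: dict[str, str] = field(default_factory=dict)


@dataclass
class SheetManifest:
    sheets: list[SheetSpec]

    def by_role(self, role: str) -> list[SheetSpec]:
        return [s for s in self.sheets if s.role == role]


def load_manifest(path: str | Path | None = None) -> SheetManifest:
    if path is None:
        path = packaged_data_dir() / "sheets.yaml"
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    sheets = [SheetSpec(**entry) for entry in raw["sheets"]]
    roles = {s.role for s in sheets}
    if "administrative" not in roles or "diagnosis" not in roles:
        raise ExportFormatError(f"{path}: manifest needs administrative and diagnosis sheets")
    return SheetManifest(sheets=sheets)


def parse_date(raw: str) -> dt.date | None:
    """Parse ISO (YYYY-MM-DD) or French (DD/MM/YYYY) dates; else None + warning."""
    raw = (raw or "").strip()
    if not raw:
        return None
    for fmt in ("%Y-%m-%d", "%d/%m/%Y"):
        try:
            return dt.datetime.strptime(raw, fmt).date()
        except ValueError:
            continue
    log.warning("unparseable date %r ignored", raw)
    return None


def _split_multivalue(raw: str) -> list[str]:
    # several codes may share one cell; split on ";" then ","
    parts: list[str] = []
    for chunk in (raw or "").split(";"):
        parts.extend(p.strip() for p in chunk.split(","))
    return [p for p in parts if p]


def _read_sheet_rows(path: Path, sheet: SheetSpec) -> list[dict[str, str]]:
    """Rows of one sheet as header->trimmed-value dicts (empty cells -> "")."""
    if path.is_dir():
        fpath = path / f"{sheet.name}.csv"
        if not fpath.exists():
            raise ExportFormatError(f"missing sheet file {fpath}")
        with open(fpath, encoding="utf-8", newline="") as fh:
            rows = [
                {k: (v or "").strip() for k, v in row.items() if k is not None}
                for row in csv.DictReader(fh)
            ]
    else:
        import openpyxl

        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        if sheet.name not in wb.sheetnames:
            raise ExportFormatError(f"{path}: missing worksheet {sheet.name!r}")
        ws = wb[sheet.name]
        it = ws.iter_rows(values_only=True)
        header = [str(h).strip() if h is not None else "" for h in next(it, [])]
        rows = []
        for raw in it:
            row = {
                header[i]: (str(v).strip() if v is not None else "")
                for i, v in enumerate(raw)
                if i < len(header) and header[i]
            }
            if any(row.values()):
                rows.append(row)
        wb.close()
    if rows and sheet.id_column not in rows[0]:
        raise ExportFormatError(
            f"sheet {sheet.name!r}: identifier column {sheet.id_column!r} not found"
        )
    return rows


@dataclass
class ReadStats:
    per_sheet_rows: dict[str, int] = field(default_factory=dict)
    orphan_rows: list[tuple[str, str, int]] = field(default_factory=list)  # sheet, id, row


def read_export(
    path: str | Path,
    manifest: SheetManifest | None = None,
    stats: ReadStats | None = None,
) -> list[PatientRecord]:
    """Assemble one :class:`PatientRecord` per distinct local identifier.

    Rows of diagnosis-role sheets become :class:`DiagnosticBlock`s ordered by
    their row index; genetics-role rows attach gene/variant entries to the
    first block sharing their ORPHA code.  Rows whose identifier never
    appears in an administrative sheet are reported as orphans and dropped.
    """
    path = Path(path)
    manifest = manifest or load_manifest()
    stats = stats if stats is not None else ReadStats()

    records: dict[str, PatientRecord] = {}

    for sheet in manifest.by_role("administrative"):
        rows = _read_sheet_rows(path, sheet)
        stats.per_sheet_rows[sheet.name] = len(rows)
        for row in rows:
            pid = row.get(sheet.id_column, "")
            if not pid:
                continue
            identity = Identity(
                surname=row.get(sheet.identity.get("surname", ""), ""),
                given_name=row.get(sheet.identity.get("given_name", ""), ""),
                birth_date=parse_date(row.get(sheet.identity.get("birth_date", ""), "")),
            )
            admin = {
                k: v
                for k, v in row.items()
                if k != sheet.id_column and k not in sheet.identity.values()
            }
            records[pid] = PatientRecord(bamara_id=pid, identity=identity,
                                         administrative=admin)

    for sheet in manifest.by_role("administrative_extra"):
        rows = _read_sheet_rows(path, sheet)
        stats.per_sheet_rows[sheet.name] = len(rows)
        for i, row in enumerate(rows):
            pid = row.get(sheet.id_column, "")
            rec = records.get(pid)
            if rec is None:
                log.warning("orphan row %d in sheet %s (id %s)", i, sheet.name, pid)
                stats.orphan_rows.append((sheet.name, pid, i))
                continue
            for k, v in row.items():
                if k != sheet.id_column and v:
                    rec.administrative.setdefault(k, v)

    for sheet in manifest.by_role("diagnosis"):
        rows = _read_sheet_rows(path, sheet)
        stats.per_sheet_rows[sheet.name] = len(rows)
        special = {sheet.id_column, sheet.orpha_column, sheet.status_column,
                   sheet.hpo_column, sheet.date_column}
        for i, row in enumerate(rows):
            pid = row.get(sheet.id_column, "")
            rec = records.get(pid)
            if rec is None:
                log.warning("orphan diagnosis row %d (id %s)", i, pid)
                stats.orphan_rows.append((sheet.name, pid, i))
                continue
            block = DiagnosticBlock(
                source_row=i,
                orpha_code=row.get(sheet.orpha_column, ""),
                status=row.get(sheet.status_column, ""),
                hpo_terms=_split_multivalue(row.get(sheet.hpo_column, "")),
                assertion_date=parse_date(row.get(sheet.date_column, "")),
                clinical_fields={k: v for k, v in row.items() if k not in special},
            )
            rec.blocks.append(block)

    for sheet in manifest.by_role("genetics"):
        rows = _read_sheet_rows(path, sheet)
        stats.per_sheet_rows[sheet.name] = len(rows)
        gene_cols = {fold_header(h): fam for h, fam in sheet.gene_level.items()}
        var_cols = {fold_header(h): fam for h, fam in sheet.variant_level.items()}
        for i, row in enumerate(rows):
            pid = row.get(sheet.id_column, "")
            rec = records.get(pid)
            if rec is None:
                log.warning("orphan genetics row %d (id %s)", i, pid)
                stats.orphan_rows.append((sheet.name, pid, i))
                continue
            block = _match_block(rec, row.get(sheet.orpha_column, ""))
            if block is None:
                stats.orphan_rows.append((sheet.name, pid, i))
                continue
            _attach_genetics(block, row, gene_cols, var_cols)

    out = list(records.values())
    for rec in out:
        rec.blocks.sort(key=lambda b: b.source_row)
    log.info("read %d patients from %s", len(out), path)
    return out


def _match_block(rec: PatientRecord, orpha: str) -> DiagnosticBlock | None:
    """First block sharing the genetics row's ORPHA code; if the row carries
    no code, the patient's first block (genetics without a diagnosis context
    are rare and a block is still the only anchor available)."""
    if not rec.blocks:
        return None
    if not orpha:
        return rec.blocks[0]
    norm = normalize_code(orpha, "ORPHA")
    for block in rec.blocks:
        if block.orpha_normalized == norm:
            return block
    return None


def _attach_genetics(
    block: DiagnosticBlock,
    row: dict[str, str],
    gene_cols: dict[str, str],
    var_cols: dict[str, str],
) -> None:
    values_gene: dict[str, str] = {}
    values_var: dict[str, str] = {}
    for header, value in row.items():
        folded = fold_header(header)
        if folded in gene_cols and value:
            values_gene[gene_cols[folded]] = value
        elif folded in var_cols and value:
            values_var[var_cols[folded]] = value
    symbol = values_gene.pop("symbol", "")
    if not symbol:
        return
    gene = next((g for g in block.genes if g.symbol == symbol), None)
    if gene is None:
        gene = GeneEntry(symbol=symbol, attributes=values_gene)
        block.genes.append(gene)
    else:
        for k, v in values_gene.items():
            gene.attributes.setdefault(k, v)
    description = values_var.pop("description", "")
    if description:
        gene.variants.append(
            VariantEntry(
                description=description,
                classification=values_var.pop("classification", ""),
                zygosity=values_var.pop("zygosity", ""),
                attributes=values_var,
            )
        )
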
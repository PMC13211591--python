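"""Seeded generator of messy source-registry exports with ground truth.

A :class:`CohortSpec` declares the cohort composition as strata of patient
profiles (eligibility pathway, block multiplicity, disease multiplicity,
genetics, invalid-code injection).  :func:`generate` writes an export in the
same dialects the reader accepts (CSV-per-sheet directory or XLSX workbook)
plus a ground-truth *sidecar* stating every patient's intended pipeline
outcome.  The sidecar is emitted at generation time, never re-derived from
the pipeline, so end-to-end tests are oracle-based.

Messiness emulates real exports: accented and compound names, mixed case,
two date dialects, bare vs prefixed disease codes, stray whitespace.  The
generator deliberately does not model disease prevalence or national
identifier formats — cohort composition is declarative, not statistical.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .mapping import load_reference_mapping, packaged_data_dir
from .terminology import load_all

PROFILES = (
    "ineligible_bad_status", "ineligible_missing_orpha",
    "ineligible_orpha_not_allowed", "ineligible_undetermined_no_hpo",
    "ineligible_no_blocks", "multiblock_single_disease", "two_eligible_reds",
    "multidisease_one_eligible", "undetermined_nonallowed_orpha",
    "invalid_hpo", "plain_eligible",
)

SURNAMES = [
    "Dupont", "Lefèvre", "Martín", "Bernard", "Müller", "Moreau", "García",
    "Rousseau", "Lévêque", "Fontaine", "Chevalier", "Bénard", "Leroy",
    "D'Angelo", "Girard", "Noël", "Pérez", "Schmitt", "Hoarau", "Payet",
    "Weiß", "Ferré", "Lambert", "Caron", "Rivière", "Berger", "Français",
    "Ōtsuka", "N'Diaye", "Østergaard",
]
GIVEN_NAMES = [
    "Marie-Anne", "Jean-Pierre", "Léa", "Noël", "Aurélie", "François",
    "Chloé", "Benoît", "Anaïs", "Loïc", "Marie Claire", "Jérôme",
    "Léa-Noëlle", "Cédric", "Maëlys", "Étienne", "Inès", "Raphaël",
    "Océane", "Gaël", "Amélie", "Timothée", "Zoé", "Pierre-Louis",
    "Eugénie", "Théo", "Salomé", "Andréa", "Frédéric", "Joséphine",
]
VARIANT_SHAPES = ["c.{}A>G", "c.{}del", "c.{}C>T", "c.{}dup", "c.{}G>A"]
BAD_STATUSES = ["En cours d'évaluation", "Suspecté", "Non renseigné", "Exclu"]
DNA_ORIGINS = ["nucléaire", "mitochondrial", "Nucléaire "]
INVALID_HPO = ["HP:9999999", "HP:8888888", "HP:7777777"]
INVALID_ORPHA = ["ORPHA:999999", "ORPHA:888888"]


class SpecError(ValueError):
    pass


@dataclass
class Stratum:
    count: int
    profile: str
    genetics: bool = False
    reimport: bool = False

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise SpecError(f"unknown profile {self.profile!r}")
        if self.count < 0:
            raise SpecError("stratum count must be >= 0")


@dataclass
class CohortSpec:
    n_patients: int
    seed: int
    strata: list[Stratum]
    name: str = "cohort"

    def __post_init__(self) -> None:
        total = sum(s.count for s in self.strata)
        if total != self.n_patients:
            raise SpecError(
                f"stratum counts sum to {total}, expected {self.n_patients}"
            )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_patients": self.n_patients,
            "seed": self.seed,
            "strata": [vars(s) for s in self.strata],
        }


def load_cohort_spec(path: str | Path, seed: int) -> CohortSpec:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    strata = [
        Stratum(count=e["count"], profile=e["profile"],
                genetics=e.get("genetics", False),
                reimport=e.get("reimport", False))
        for e in raw["strata"]
    ]
    return CohortSpec(
        n_patients=sum(s.count for s in strata),
        seed=seed,
        strata=strata,
        name=raw.get("name", Path(path).stem),
    )


def cargo_like(seed: int) -> CohortSpec:
    """The packaged 1000-patient validation cohort specification."""
    return load_cohort_spec(
        packaged_data_dir() / "cohorts" / "cargo1000.yaml", seed
    )


def scale_series(base: CohortSpec, sizes: list[int]) -> list[CohortSpec]:
    """Proportionally scaled copies of a spec (rounded, residual assigned to
    the largest stratum); stratum counts sum exactly to each size."""
    specs = []
    for size in sizes:
        if size <= 0:
            raise SpecError("sizes must be positive")
        counts = [round(s.count * size / base.n_patients) for s in base.strata]
        largest = max(range(len(counts)), key=lambda i: base.strata[i].count)
        counts[largest] += size - sum(counts)
        if counts[largest] < 0:
            raise SpecError(f"cannot scale spec to size {size}")
        specs.append(CohortSpec(
            n_patients=size,
            seed=base.seed,
            strata=[Stratum(count=c, profile=s.profile, genetics=s.genetics,
                            reimport=s.reimport)
                    for c, s in zip(counts, base.strata)],
            name=f"{base.name}-n{size}",
        ))
    return specs


# ---------------------------------------------------------------------------
# generation

@dataclass
class _Pools:
    allowed: list[str]
    non_allowed: list[str]  # valid in the terminology, absent from allowed
    orpha_labels: dict[str, str]
    hpo: list[str]
    genes: list[str]


def _load_pools() -> _Pools:
    terms = load_all(packaged_data_dir() / "terminology")
    allowed = load_reference_mapping().allowed_orpha
    all_orpha = sorted(terms["ORPHA"].entries)
    return _Pools(
        allowed=sorted(allowed),
        non_allowed=[c for c in all_orpha if c not in allowed],
        orpha_labels=terms["ORPHA"].entries,
        hpo=sorted(terms["HPO"].entries),
        genes=sorted(terms["GENE"].entries),
    )


def _messy_date(rng: random.Random, date: dt.date) -> str:
    return date.isoformat() if rng.random() < 0.5 else date.strftime("%d/%m/%Y")


def _messy_orpha(rng: random.Random, code: str) -> str:
    # code arrives normalized "ORPHA:123"; emit heterogeneous spellings
    digits = code.split(":", 1)[1]
    return rng.choice([code, digits, code.lower(), f" {code}"])


def _messy_case(rng: random.Random, text: str) -> str:
    return rng.choice([text, text.upper(), text.lower(), text + " "])


def _status(rng: random.Random, canonical: str) -> str:
    forms = {
        "confirmed": ["Confirmé", "confirmé", "CONFIRMÉ", "Confirmed"],
        "probable": ["Probable", "probable", "PROBABLE"],
        "undetermined": ["Indéterminé", "indéterminé", "INDÉTERMINÉ"],
    }
    return rng.choice(forms[canonical])


@dataclass
class _Patient:
    stratum: Stratum
    surname: str = ""
    given_name: str = ""
    birth_date: dt.date | None = None
    admin: dict = field(default_factory=dict)
    care: dict = field(default_factory=dict)
    diag_rows: list[dict] = field(default_factory=list)
    gen_rows: list[dict] = field(default_factory=list)
    truth: dict = field(default_factory=dict)
    bamara_id: str = ""


def _make_patient(rng: random.Random, stratum: Stratum, pools: _Pools,
                  birth_offset: int) -> _Patient:
    p = _Patient(stratum=stratum)
    p.surname = rng.choice(SURNAMES)
    p.given_name = rng.choice(GIVEN_NAMES)
    p.birth_date = dt.date(1935, 1, 1) + dt.timedelta(days=birth_offset)
    p.admin = {
        "Sexe": rng.choice(["Masculin", "Féminin"]),
        "Code postal": f"{rng.randint(1, 95):02d}{rng.randint(0, 999):03d}",
        "Statut vital": "Vivant",
        "Prise en charge MR": rng.choice(["Affected", "Not affected"]),
        "Consentement recherche": rng.choice(["Oui", "Non"]),
    }
    p.care = {
        "Médecin référent": f"Dr {rng.choice(SURNAMES)}",
        "Centre de suivi": "Centre de référence maladies rares oculaires",
        "Statut du dossier": rng.choice(["Validé", "En cours"]),
        "Date de première consultation": _messy_date(
            rng, dt.date(2010, 1, 1) + dt.timedelta(days=rng.randint(0, 4000))),
        "Commentaire libre": rng.choice(
            ["", "Suivi annuel", "Adressé par le CHU", "Données à compléter"]),
    }
    builder = _BUILDERS[stratum.profile]
    builder(rng, p, pools)
    p.truth.setdefault("n_blocks", len(p.diag_rows))
    p.truth.setdefault("genetics", stratum.genetics)
    p.truth["reimport"] = stratum.reimport
    p.truth["stratum"] = stratum.profile
    return p


def _dates(rng: random.Random, n: int) -> list[dt.date]:
    """n strictly increasing assertion dates."""
    base = dt.date(2015, 1, 1) + dt.timedelta(days=rng.randint(0, 2000))
    offsets = sorted(rng.sample(range(1, 1400), n))
    return [base + dt.timedelta(days=o) for o in offsets]


def _diag_row(rng: random.Random, pools: _Pools, orpha: str = "",
              status: str = "", hpo: list[str] | None = None,
              date: dt.date | None = None, **clinical) -> dict:
    row = {
        "Code ORPHA": _messy_orpha(rng, orpha) if orpha else "",
        "Libellé diagnostic": pools.orpha_labels.get(orpha, ""),
        "Statut du diagnostic": status,
        "Signes HPO": rng.choice([";", ","]).join(hpo) if hpo else "",
        "Date d'assertion du diagnostic": _messy_date(rng, date) if date else "",
    }
    row.update(clinical)
    return row


def _gen_rows(rng: random.Random, pools: _Pools, orpha: str,
              n_genes: int, n_variants: int) -> list[dict]:
    rows = []
    for gene in rng.sample(pools.genes, n_genes):
        for _ in range(n_variants):
            rows.append({
                "Code ORPHA": _messy_orpha(rng, orpha),
                "Gène": gene,
                "Mode de transmission": rng.choice(
                    ["Autosomique récessive", "Autosomique dominante", "Liée à l'X"]),
                "Méthode d'analyse génétique": rng.choice(
                    ["Panel NGS", "Exome", "Sanger"]),
                "Variant": rng.choice(VARIANT_SHAPES).format(rng.randint(10, 9000)),
                "Classification du variant": rng.choice(
                    ["Pathogène", "Probablement pathogène", "VUS"]),
                "Zygotie": rng.choice(["Hétérozygote", "Homozygote"]),
                "Transcrit de référence": f"NM_{rng.randint(1000, 999999):06d}.{rng.randint(1, 9)}",
            })
    return rows


# -- profile builders --------------------------------------------------------

def _b_bad_status(rng, p, pools):
    date = _dates(rng, 1)[0]
    p.diag_rows = [_diag_row(rng, pools, orpha=rng.choice(pools.allowed),
                             status=rng.choice(BAD_STATUSES), date=date)]
    p.truth.update(outcome="filtered_out", reason="status_not_eligible",
                   n_disease_groups=1)


def _b_missing_orpha(rng, p, pools):
    date = _dates(rng, 1)[0]
    status = _status(rng, rng.choice(["confirmed", "probable"]))
    hpo = rng.sample(pools.hpo, rng.randint(0, 2))
    p.diag_rows = [_diag_row(rng, pools, status=status, hpo=hpo, date=date)]
    p.truth.update(outcome="filtered_out", reason="missing_orpha",
                   n_disease_groups=1)


def _b_orpha_not_allowed(rng, p, pools):
    date = _dates(rng, 1)[0]
    invalid = rng.random() < 0.3
    orpha = rng.choice(INVALID_ORPHA) if invalid else rng.choice(pools.non_allowed)
    p.diag_rows = [_diag_row(rng, pools, orpha=orpha,
                             status=_status(rng, "confirmed"), date=date)]
    p.truth.update(outcome="filtered_out",
                   reason="invalid_orpha" if invalid else "orpha_not_allowed",
                   n_disease_groups=1)


def _b_undetermined_no_hpo(rng, p, pools):
    date = _dates(rng, 1)[0]
    orpha = rng.choice(pools.allowed) if rng.random() < 0.5 else ""
    p.diag_rows = [_diag_row(rng, pools, orpha=orpha,
                             status=_status(rng, "undetermined"), date=date)]
    p.truth.update(outcome="filtered_out", reason="undetermined_no_valid_hpo",
                   n_disease_groups=1)


def _b_no_blocks(rng, p, pools):
    p.truth.update(outcome="filtered_out", reason="no_diagnostic_block",
                   n_disease_groups=0)


def _b_multiblock_single(rng, p, pools):
    orpha = rng.choice(pools.allowed)
    n = rng.choice([2, 2, 3])
    dates = _dates(rng, n)
    # older blocks carry fields the newest lacks, exercising inheritance
    p.diag_rows.append(_diag_row(
        rng, pools, orpha=orpha, status=_status(rng, "probable"),
        hpo=rng.sample(pools.hpo, 2), date=dates[0],
        **{"Origine de l'ADN": rng.choice(DNA_ORIGINS),
           "Date des premiers signes": _messy_date(
               rng, dates[0] - dt.timedelta(days=rng.randint(100, 3000)))},
    ))
    for d in dates[1:-1]:
        p.diag_rows.append(_diag_row(
            rng, pools, orpha=orpha, status=_status(rng, "probable"), date=d))
    p.diag_rows.append(_diag_row(
        rng, pools, orpha=orpha, status=_status(rng, "confirmed"),
        hpo=rng.sample(pools.hpo, rng.randint(1, 3)), date=dates[-1],
        **{"Latéralité": "Bilatérale"},
    ))
    if p.stratum.genetics:
        p.gen_rows = _gen_rows(rng, pools, orpha, rng.randint(1, 2),
                               rng.randint(1, 2))
    p.truth.update(outcome="created", pathway="confirmed_probable",
                   n_disease_groups=1, orpha_in_allowed=True, two_red=False)


def _b_two_reds(rng, p, pools):
    o1, o2 = rng.sample(pools.allowed, 2)
    d1, d2 = _dates(rng, 2)
    p.diag_rows = [
        _diag_row(rng, pools, orpha=o1, status=_status(rng, "confirmed"),
                  hpo=rng.sample(pools.hpo, 1), date=d1),
        _diag_row(rng, pools, orpha=o2, status=_status(rng, "confirmed"),
                  hpo=rng.sample(pools.hpo, 2), date=d2),
    ]
    if p.stratum.genetics:
        p.gen_rows = _gen_rows(rng, pools, o2, 1, rng.randint(1, 2))
    p.truth.update(outcome="created", pathway="confirmed_probable",
                   n_disease_groups=2, orpha_in_allowed=True, two_red=True)


def _b_multidisease_one_eligible(rng, p, pools):
    o1 = rng.choice(pools.allowed)
    d1, d2 = _dates(rng, 2)
    eligible = _diag_row(rng, pools, orpha=o1, status=_status(rng, "confirmed"),
                         hpo=rng.sample(pools.hpo, 1), date=d1)
    if rng.random() < 0.5:  # second disease rejected on its code
        other = _diag_row(rng, pools, orpha=rng.choice(pools.non_allowed),
                          status=_status(rng, "confirmed"), date=d2)
    else:  # rejected on its status
        o2 = rng.choice([c for c in pools.allowed if c != o1])
        other = _diag_row(rng, pools, orpha=o2,
                          status=rng.choice(BAD_STATUSES), date=d2)
    p.diag_rows = [eligible, other] if rng.random() < 0.5 else [other, eligible]
    p.truth.update(outcome="created", pathway="confirmed_probable",
                   n_disease_groups=2, orpha_in_allowed=True, two_red=False)


def _b_undetermined_nonallowed(rng, p, pools):
    date = _dates(rng, 1)[0]
    p.diag_rows = [_diag_row(
        rng, pools, orpha=rng.choice(pools.non_allowed),
        status=_status(rng, "undetermined"),
        hpo=rng.sample(pools.hpo, rng.randint(1, 3)), date=date)]
    p.truth.update(outcome="created", pathway="undetermined_hpo",
                   n_disease_groups=1, orpha_in_allowed=False, two_red=False)


def _b_invalid_hpo(rng, p, pools):
    date = _dates(rng, 1)[0]
    hpo = [rng.choice(pools.hpo), rng.choice(INVALID_HPO)]
    rng.shuffle(hpo)
    p.diag_rows = [_diag_row(rng, pools, orpha=rng.choice(pools.allowed),
                             status=_status(rng, "confirmed"), hpo=hpo,
                             date=date)]
    p.truth.update(outcome="validation_blocked", reason="invalid_hpo",
                   pathway="confirmed_probable", n_disease_groups=1,
                   orpha_in_allowed=True, two_red=False)


def _b_plain(rng, p, pools):
    orpha = rng.choice(pools.allowed)
    date = _dates(rng, 1)[0]
    hpo = rng.sample(pools.hpo, rng.randint(0, 2))
    extra = {}
    if rng.random() < 0.3:
        extra["Origine de l'ADN"] = rng.choice(DNA_ORIGINS)
    if rng.random() < 0.2:
        extra["Signe principal (HPO)"] = rng.choice(pools.hpo)
    p.diag_rows = [_diag_row(
        rng, pools, orpha=orpha,
        status=_status(rng, rng.choice(["confirmed", "confirmed", "probable"])),
        hpo=hpo, date=date, **extra)]
    if p.stratum.genetics:
        p.gen_rows = _gen_rows(rng, pools, orpha, rng.randint(1, 3),
                               rng.randint(1, 3))
    p.truth.update(outcome="created", pathway="confirmed_probable",
                   n_disease_groups=1, orpha_in_allowed=True, two_red=False)


_BUILDERS = {
    "ineligible_bad_status": _b_bad_status,
    "ineligible_missing_orpha": _b_missing_orpha,
    "ineligible_orpha_not_allowed": _b_orpha_not_allowed,
    "ineligible_undetermined_no_hpo": _b_undetermined_no_hpo,
    "ineligible_no_blocks": _b_no_blocks,
    "multiblock_single_disease": _b_multiblock_single,
    "two_eligible_reds": _b_two_reds,
    "multidisease_one_eligible": _b_multidisease_one_eligible,
    "undetermined_nonallowed_orpha": _b_undetermined_nonallowed,
    "invalid_hpo": _b_invalid_hpo,
    "plain_eligible": _b_plain,
}

ADMIN_COLUMNS = ["ID BaMaRa", "Nom", "Prénom", "Date de naissance", "Sexe",
                 "Code postal", "Statut vital", "Prise en charge MR",
                 "Consentement recherche"]
CARE_COLUMNS = ["ID BaMaRa", "Médecin référent", "Centre de suivi",
                "Statut du dossier", "Date de première consultation",
                "Commentaire libre"]
DIAG_COLUMNS = ["ID BaMaRa", "Code ORPHA", "Libellé diagnostic",
                "Statut du diagnostic", "Signes HPO",
                "Date d'assertion du diagnostic", "Origine de l'ADN",
                "Date des premiers signes", "Latéralité",
                "Signe principal (HPO)"]
GEN_COLUMNS = ["ID BaMaRa", "Code ORPHA", "Gène", "Mode de transmission",
               "Méthode d'analyse génétique", "Variant",
               "Classification du variant", "Zygotie",
               "Transcrit de référence"]


def generate(spec: CohortSpec, out_dir: str | Path,
             fmt: str = "csv") -> tuple[Path, Path]:
    """Write the export (CSV-per-sheet directory or one XLSX workbook) and
    the ground-truth sidecar; returns (export_path, sidecar_path).

    Deterministic for a given (spec, seed): identical content across runs.
    """
    if fmt not in ("csv", "xlsx"):
        raise SpecError(f"unknown format {fmt!r}")
    rng = random.Random(spec.seed)
    pools = _load_pools()

    birth_offsets = rng.sample(range(0, 32000), spec.n_patients)
    patients: list[_Patient] = []
    for stratum in spec.strata:
        for _ in range(stratum.count):
            patients.append(_make_patient(rng, stratum, pools,
                                          birth_offsets[len(patients)]))
    rng.shuffle(patients)
    for i, p in enumerate(patients, start=1):
        p.bamara_id = f"F-{i:04d}"

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sheets = _assemble_sheets(rng, patients)
    if fmt == "csv":
        export_path = out_dir / f"{spec.name}_export"
        export_path.mkdir(exist_ok=True)
        for name, (cols, rows) in sheets.items():
            with open(export_path / f"{name}.csv", "w", encoding="utf-8",
                      newline="") as fh:
                w = csv.DictWriter(fh, fieldnames=cols)
                w.writeheader()
                w.writerows(rows)
    else:
        import openpyxl

        wb = openpyxl.Workbook()
        wb.remove(wb.active)
        for name, (cols, rows) in sheets.items():
            ws = wb.create_sheet(title=name)
            ws.append(cols)
            for row in rows:
                ws.append([row.get(c, "") for c in cols])
        export_path = out_dir / f"{spec.name}_export.xlsx"
        wb.save(export_path)

    sidecar = {
        "spec": spec.to_dict(),
        "tallies": _tallies(patients),
        "patients": {p.bamara_id: p.truth for p in patients},
    }
    sidecar_path = out_dir / f"{spec.name}_truth.json"
    sidecar_path.write_text(
        json.dumps(sidecar, ensure_ascii=False, indent=1, sort_keys=True),
        encoding="utf-8",
    )
    return export_path, sidecar_path


def _assemble_sheets(rng: random.Random, patients: list[_Patient]) -> dict:
    admin_rows, care_rows, diag_rows, gen_rows = [], [], [], []
    for p in patients:
        admin_rows.append({
            "ID BaMaRa": p.bamara_id,
            "Nom": _messy_case(rng, p.surname),
            "Prénom": p.given_name,
            "Date de naissance": _messy_date(rng, p.birth_date),
            **p.admin,
        })
        care_rows.append({"ID BaMaRa": p.bamara_id, **p.care})
        for row in p.diag_rows:
            diag_rows.append({"ID BaMaRa": p.bamara_id, **row})
        for row in p.gen_rows:
            gen_rows.append({"ID BaMaRa": p.bamara_id, **row})
    return {
        "Identité": (ADMIN_COLUMNS, admin_rows),
        "Prise en charge": (CARE_COLUMNS, care_rows),
        "Diagnostic": (DIAG_COLUMNS, diag_rows),
        "Génétique": (GEN_COLUMNS, gen_rows),
    }


def _tallies(patients: list[_Patient]) -> dict:
    created = [p for p in patients if p.truth["outcome"] == "created"]
    return {
        "total": len(patients),
        "filtered_out": sum(1 for p in patients
                            if p.truth["outcome"] == "filtered_out"),
        "eligible": sum(1 for p in patients
                        if p.truth["outcome"] != "filtered_out"),
        "validation_blocked": sum(
            1 for p in patients if p.truth["outcome"] == "validation_blocked"),
        "created": len(created),
        "imported_multi_block": sum(
            1 for p in created if p.truth["n_blocks"] >= 2),
        "imported_multi_block_single_disease": sum(
            1 for p in created
            if p.truth["n_blocks"] >= 2 and p.truth["n_disease_groups"] == 1),
        "imported_multi_disease": sum(
            1 for p in created if p.truth["n_disease_groups"] >= 2),
        "imported_two_diagnoses": sum(
            1 for p in created if p.truth.get("two_red")),
        "imported_undetermined_nonallowed_orpha": sum(
            1 for p in created
            if p.truth.get("pathway") == "undetermined_hpo"
            and p.truth.get("orpha_in_allowed") is False),
        "imported_with_gene_variant": sum(
            1 for p in created if p.truth["genetics"]),
        "reimport_ids": sorted(p.bamara_id for p in patients
                               if p.truth["reimport"]),
    }
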
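# Methods

This note documents the pipeline's rules, parameters and design choices at
the level a maintainer or auditor needs; the README gives the overview.

## Source model

A source export is one workbook (or an equivalent CSV-per-sheet directory),
one worksheet per clinical domain, rows keyed by a local patient
identifier. Headers are natural-language labels; values are free text with
accents, compound names, mixed case and two date dialects (ISO
`YYYY-MM-DD` and French `DD/MM/YYYY`). A patient may carry several
*diagnostic blocks* — successive dated entries for the same or different
diseases — because data entry accumulates rather than updates.

Ingestion preserves values verbatim (whitespace-trimmed only). All
matching — header lookup, status vocabulary, code comparison, identity
comparison — happens in normalization layers, so the audit trail can always
show the exact source string. Header normalization: trim, collapse internal
whitespace, case-fold, accent-fold, unify apostrophe variants. Name
normalization adds hyphen/apostrophe → space so compound names compare
equal. Multi-valued cells split on `;` then `,`. Unparseable dates become
absent values with a logged warning.

A `sheets.yaml` manifest maps sheet names to roles (administrative,
administrative-extra, diagnosis, genetics) and key columns; the generator
and the reader share it, so a center-specific dialect is a config edit, not
a code change. Genetics-sheet rows attach to the first diagnostic block
sharing their ORPHA code (one gene row per variant; rows grouped by gene
symbol in order of appearance).

## Business rules

**Eligibility** (per block): status Confirmed/Probable requires an ORPHA
code that is present, valid in the terminology, and on the configured
allowed list; status Undetermined requires ≥1 HPO term valid in the
terminology and places no requirement on the ORPHA code. Everything else is
ineligible with a coded reason (`missing_orpha`, `invalid_orpha`,
`orpha_not_allowed`, `undetermined_no_valid_hpo`, `status_not_eligible`).
A patient with no eligible block is excluded (`filtered_out`).

**Recency order**: assertion date descending, then source-row descending.
Equal or absent dates therefore resolve to "later row in the export is more
recent" — a deterministic, auditable tie-break for a quantity the source
does not disambiguate.

**Grouping**: blocks sharing a normalized ORPHA code form one disease
group. Undetermined blocks without a code pool into a single per-patient
group (they describe one unresolved diagnostic journey) and are flagged in
the report; any other code-less block stays a singleton group so that it
remains visible in the audit without ever being selectable.

**Reconciliation**: the most recent block seeds the merged diagnosis; each
still-empty field fills from the next most recent block holding a non-empty
value. The HPO list and the gene list are replaced as wholes — consistent
with "newer values replace older ones" — and inherited only when the newer
list is empty; unioning lists entered at different times would fabricate a
clinical state never observed. Provenance records each field's donor row;
reconciliation on a single block is the identity, and the merge is
insensitive to input order.

**Polydiagnostic selection**: groups with ≥1 eligible block survive,
ordered by their best block's recency; the first becomes the main
diagnosis, the second the additional one. More than two eligible diseases
exceed the target schema's capacity: the two most recent are kept and an
overflow warning emitted.

**Validation**: every terminology-bound mapped field (disease code,
phenotype-term fields, gene-symbol slots) is checked exhaustively — no
short-circuit — and any invalid code blocks the entire patient. Field-level
dropping was rejected: a partially imported questionnaire silently
misrepresents the patient, whereas a blocked one is listed for correction.

**Duplicate prevention**: exact match on normalized surname AND normalized
given name AND calendar-exact birth date against the registry's profile
snapshot, fetched before any write; a fetch failure aborts the run (never
import blind). No phonetic/fuzzy matching and no date tolerance: in this
governance model a false negative costs a manual review, a false positive
silently merges two patients.

## Mapping configuration

`mapping.csv` holds 83 rules (54 direct, 17 inferred, 12 reconstructed)
over 83 unique source labels; `allowed_orpha.txt` lists the admissible
disease codes. Both are plain text for hand-editing by data managers. Rule
scope (patient / diagnosis / gene-level / variant-level) derives from the
target-field prefix (`adm_`/`status_`, `dia_`, `gen_gene_`,
`gen_variant_`), so the CSV needs no extra column. 18 of the direct rules
are terminology-bound. Unmapped source headers pass through unchanged and
are flagged for review, never silently dropped.

Inferred rules dispatch to 17 registered inference functions — date
arithmetic (ages in whole years, year extraction, day deltas),
presence-derived booleans, counts, and constant defaults. Unknown
inference identifiers fail at configuration load, not mid-run. A missing or
inconsistent input yields the rule's configured default.

Genetic flattening writes gene *i* (source order, 1-based) into
`gene{i}_<family>` slots and variant *j* of gene *i* into
`gene{i}_variant{j}_<family>` slots, truncating beyond 3×3 with a warning;
the operation is invertible on the bounded domain, which the tests exercise
as a round trip.

## Loading, registry mock, audit

Two import routes: a fixed-column CSV template (column order derived from
the configuration, identity first, then patient-scope fields, then the
main/additional diagnosis groups) and an API route that wraps each record
as a simplified FHIR-style bundle — one Patient resource (the only place
identity appears) and one QuestionnaireResponse keyed by target field.
Submission is sequential (profile, then questionnaire) with configurable
pacing (default 0 s) and retries (default 3); a questionnaire failure after
profile creation records the orphan profile id for remediation. The
registry is an in-process mock honouring the real platform's contract —
token-scoped center workspaces, profiles-only visibility before import —
with optional JSON state persistence so separate runs share state, and
failure injection for retry tests. Real connectivity and credential
encryption are out of scope.

Every run produces a JSON + text audit report: per-patient outcome
(`created` / `duplicate_skipped` / `filtered_out` / `validation_blocked` /
`transport_failed`, exactly one each), retained blocks and inherited-field
donors for multi-block patients, polydiagnostic detections, duplicate
events, configuration fingerprints and the tool version. Outcome
conservation (the five outcomes partition the input) is asserted on every
run and re-checked by `check_report_schema`.

## Synthetic cohorts and what they show

The generator builds cohorts from declarative strata, each stratum fixing a
patient profile: eligibility pathway, block/disease multiplicity, genetics
presence, invalid-code injection, reimport flagging. Identity messiness
(accented and compound names from a bundled list, case variants, mixed date
dialects, bare vs prefixed codes) exercises the normalization layers. A
ground-truth sidecar with each patient's intended outcome is emitted at
generation time — never re-derived from the pipeline — so end-to-end tests
compare against an independent oracle.

The packaged 1000-patient cohort (`cargo1000.yaml`) fixes one consistent
joint stratum assignment reproducing the validation marginals: 352
ineligible (100 ineligible status, 80 missing code, 90 non-allowed or
invalid code under Confirmed, 50 Undetermined without phenotype terms, 32
without any block), 70 multi-block single-disease (25 with genetics), 7
with two eligible diseases (all with genetics), 18 multi-disease with one
eligible group, 9 Undetermined-pathway patients with a valid but
non-allowed code, 7 eligible patients carrying an invalid phenotype code,
97 plain with genetics and 440 plain without (10 flagged for the reimport
test). Counts are structural, so they hold under any seed; the seed varies
identities, codes, dates and ordering. The real cohort's joint distribution
is unknown; only the marginals are modelled.

What passing tests do *not* show about real data: the generator emits a
single export dialect family, does not model disease prevalence, national
identifier formats, truly malformed rows (beyond orphan rows and bad
dates), or inconsistencies between sheets, and its strata are disjoint by
construction. Scaled runs (10–5000 patients via proportional stratum
scaling, residual to the largest stratum) back a completion smoke test
only; no wall-clock claims are made. Default problem sizes in the suite —
the 1000-patient cohort once per session, 120-patient cohorts for
multi-seed oracle checks, one 5000-patient smoke run — were chosen to keep
the suite fast while covering every stratum.

## Known limitations

Longitudinal re-import/update of existing patients is unsupported by
design (the target is cross-sectional). Ontology hierarchy traversal and
obsolete-code remapping are out of scope; fixture terminologies contain
only active terms, and whether deprecated codes should be rejected is left
open. The merge defines "most complete" implicitly through field-level
filling rather than whole-block selection; whether the HPO list should
union rather than replace across entries is a policy choice documented
above, not a settled fact of the source system.
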
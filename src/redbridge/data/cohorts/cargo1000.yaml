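# CARGO-like validation cohort: 1000 patients whose stratum composition
# mirrors the published validation counts of the source-to-target import
# (648 eligible / 352 filtered out / 7 blocked on an invalid phenotype code /
# 641 created; 95 multi-block = 70 single-disease + 25 multi-disease of which
# 7 keep two eligible diagnoses; 9 undetermined-pathway imports with a
# non-allowed ORPHA code; 129 imports with at least one gene + variant;
# a 10-patient subset flagged for the reimport test).
name: cargo1000
strata:
  - {count: 100, profile: ineligible_bad_status}
  - {count: 80, profile: ineligible_missing_orpha}
  - {count: 90, profile: ineligible_orpha_not_allowed}
  - {count: 50, profile: ineligible_undetermined_no_hpo}
  - {count: 32, profile: ineligible_no_blocks}
  - {count: 45, profile: multiblock_single_disease}
  - {count: 25, profile: multiblock_single_disease, genetics: true}
  - {count: 7, profile: two_eligible_reds, genetics: true}
  - {count: 18, profile: multidisease_one_eligible}
  - {count: 9, profile: undetermined_nonallowed_orpha}
  - {count: 7, profile: invalid_hpo}
  - {count: 97, profile: plain_eligible, genetics: true}
  - {count: 10, profile: plain_eligible, reimport: true}
  - {count: 430, profile: plain_eligible}
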
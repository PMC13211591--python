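# Sheet manifest: maps worksheet names of the source export to their role and
# key columns.  The synthetic generator and the reader share this file, so a
# center-specific export dialect only requires editing the manifest.
sheets:
  - name: "Identité"
    role: administrative
    id_column: "ID BaMaRa"
    identity:
      surname: "Nom"
      given_name: "Prénom"
      birth_date: "Date de naissance"
  - name: "Prise en charge"
    role: administrative_extra
    id_column: "ID BaMaRa"
  - name: "Diagnostic"
    role: diagnosis
    id_column: "ID BaMaRa"
    orpha_column: "Code ORPHA"
    status_column: "Statut du diagnostic"
    hpo_column: "Signes HPO"
    date_column: "Date d'assertion du diagnostic"
  - name: "Génétique"
    role: genetics
    id_column: "ID BaMaRa"
    orpha_column: "Code ORPHA"
    # column header -> canonical slot-family name; level decides whether the
    # value attaches to the gene or to the individual variant
    gene_level:
      "Gène": symbol
      "Mode de transmission": transmission
      "Méthode d'analyse génétique": method
    variant_level:
      "Variant": description
      "Classification du variant": classification
      "Zygotie": zygosity
      "Transcrit de référence": transcript
      "Position génomique": position
      "Conséquence protéique": protein
      "Statut de validation du variant": validation
      "Origine parentale": parental_origin
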
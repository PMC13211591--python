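source_label,target_field,kind,value_map,default_value,terminology_system,inference_id
Sexe,adm_sex,direct,Masculin=1;Féminin=2;Indéterminé=9,,,
Code postal,adm_postal_code,direct,,,,
Ville de naissance,adm_birth_city,direct,,,,
Pays de naissance,adm_birth_country,direct,,,,
Statut vital,adm_vital_status,direct,Vivant=1;Décédé=2,,,
Prise en charge MR,adm_patient_MR,direct,Affected=1;Not affected=0,,,
Consentement recherche,adm_research_consent,direct,Oui=1;Non=0,,,
Médecin référent,adm_referring_physician,direct,,,,
Statut du dossier,status_record,direct,Validé=validated;En cours=draft,,,
Centre de suivi,status_center,direct,,,,
Année de naissance,adm_birth_year,inferred,,,,year_of_birth
Indicateur de décès,adm_deceased_flag,inferred,,0,,deceased_flag
Dossier actif,status_active,inferred,,active,,active_unless_closed
Année de première consultation,status_first_visit_year,inferred,,,,year_of_first_visit
Polydiagnostic,status_polydiagnostic,inferred,,0,,is_polydiagnostic
Code ORPHA,dia_orpha_code,direct,,,ORPHA,
Libellé diagnostic,dia_orpha_label,direct,,,,
Statut du diagnostic,dia_status,direct,Confirmé=confirmed;Probable=probable;Indéterminé=undetermined,,,
Signes HPO,dia_hpo_terms,direct,,,HPO,
Date d'assertion du diagnostic,dia_assertion_date,direct,,,,
Origine de l'ADN,dia_dna_origin,direct,,,,
Date des premiers signes,dia_first_signs_date,direct,,,,
Latéralité,dia_laterality,direct,Bilatérale=both;Droite=right;Gauche=left,,,
Mode de découverte,dia_discovery_mode,direct,,,,
Contexte familial,dia_familial_context,direct,Familial=1;Sporadique=0,,,
Consanguinité,dia_consanguinity,direct,Oui=1;Non=0,,,
Évolution,dia_course,direct,,,,
Sévérité,dia_severity,direct,,,,
Commentaire diagnostic,dia_comment,direct,,,,
Diagnostic prénatal,dia_prenatal,direct,Oui=1;Non=0,,,
Conseil génétique,dia_genetic_counselling,direct,Oui=1;Non=0,,,
Protocole de recherche,dia_research_protocol,direct,,,,
Nom du protocole,dia_protocol_name,direct,,,,
Centre diagnostiqueur,dia_diagnosing_center,direct,,,,
Spécialité du diagnostiqueur,dia_diagnosing_specialty,direct,,,,
Acuité visuelle OD,dia_va_right,direct,,,,
Acuité visuelle OG,dia_va_left,direct,,,,
Pression intraoculaire OD,dia_iop_right,direct,,,,
Pression intraoculaire OG,dia_iop_left,direct,,,,
Traitement en cours,dia_current_treatment,direct,,,,
Port de correction,dia_corrective_lenses,direct,Oui=1;Non=0,,,
Antécédents ophtalmologiques,dia_ocular_history,direct,,,,
Signe principal (HPO),dia_sign_primary,direct,,,HPO,
Signe secondaire (HPO),dia_sign_secondary,direct,,,HPO,
Signe associé (HPO),dia_sign_associated,direct,,,HPO,
Atteinte rétinienne (HPO),dia_sign_retinal,direct,,,HPO,
Atteinte maculaire (HPO),dia_sign_macular,direct,,,HPO,
Atteinte cornéenne (HPO),dia_sign_corneal,direct,,,HPO,
Atteinte cristallinienne (HPO),dia_sign_lens,direct,,,HPO,
Atteinte du nerf optique (HPO),dia_sign_optic_nerve,direct,,,HPO,
Atteinte vitréenne (HPO),dia_sign_vitreous,direct,,,HPO,
Anomalie pupillaire (HPO),dia_sign_pupil,direct,,,HPO,
Anomalie de la réfraction (HPO),dia_sign_refraction,direct,,,HPO,
Trouble oculomoteur (HPO),dia_sign_oculomotor,direct,,,HPO,
Signe extraoculaire (HPO),dia_sign_extraocular,direct,,,HPO,
Signe neurologique (HPO),dia_sign_neurological,direct,,,HPO,
Signe auditif (HPO),dia_sign_auditory,direct,,,HPO,
Signe systémique (HPO),dia_sign_systemic,direct,,,HPO,
Électrorétinogramme,dia_erg_result,direct,,,,
Âge au diagnostic,dia_age_at_diagnosis,inferred,,,,age_at_diagnosis
Âge aux premiers signes,dia_age_at_first_signs,inferred,,,,age_at_first_signs
Présence de signes HPO,dia_has_hpo,inferred,,0,,has_hpo
Présence de données génétiques,dia_has_genetics,inferred,,0,,has_genetics
Nombre de blocs sources,dia_n_source_blocks,inferred,,1,,n_source_blocks
Rang du diagnostic,dia_rank,inferred,,1,,diagnosis_rank
Année du diagnostic,dia_year,inferred,,,,year_of_assertion
Délai signes-diagnostic (jours),dia_delay_signs_to_diagnosis_days,inferred,,,,delay_signs_to_diagnosis
Diagnostic confirmé génétiquement,dia_genetic_confirmed,inferred,,0,,genetically_confirmed
Nombre de signes HPO,dia_hpo_count,inferred,,0,,hpo_count
Nombre de gènes,dia_gene_count,inferred,,0,,gene_count
Suivi longitudinal,dia_followup_flag,inferred,,0,,constant_default
Gène,gen_gene_symbol,reconstructed,,,GENE,
Mode de transmission,gen_gene_transmission,reconstructed,,,,
Méthode d'analyse génétique,gen_gene_method,reconstructed,,,,
Variant,gen_variant_description,reconstructed,,,,
Classification du variant,gen_variant_classification,reconstructed,,,,
Zygotie,gen_variant_zygosity,reconstructed,,,,
Transcrit de référence,gen_variant_transcript,reconstructed,,,,
Position génomique,gen_variant_position,reconstructed,,,,
Conséquence protéique,gen_variant_protein,reconstructed,,,,
Statut de validation du variant,gen_variant_validation,reconstructed,,,,
Origine parentale,gen_variant_parental_origin,reconstructed,,,,
Résultat de l'analyse génétique,gen_result_summary,reconstructed,,négatif,,
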
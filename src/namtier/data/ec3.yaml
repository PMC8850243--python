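# Worked case study EC3: a preservative with non-specific (liver/kidney)
# toxicity (phenoxyethanol). Hazard-only: no exposure assessment was made,
# so the fixture carries no scenarios; the published use of the framework
# was to read suitable exposure categories (C, D, E for long-term use)
# off the boundary table. A single linear factor cannot map the published
# in vitro PoD range (171-557 µM) to the published in vivo PoD
# (1.9-3.1 mg/kg), so the tier-2 record stores the published mg/kg output
# directly with the concentrations noted. The published hazard tables show
# no classification for any endpoint; the STOT-RE entries are therefore
# carried as not_classified overrides over the naive banding.
# The published tier-2 DNEL (0.02-0.03 mg/kg) is rounded to 1 significant
# figure, the conventional one (3.6-6.5 mg/kg) to 2.
name: EC3
display_sigfigs: 1
dossier:
  schema_version: 1
  substance_id: EC3
  name: EC3 (phenoxyethanol) — tiered case study, hazard only
  identifiers:
    cas: "122-99-6"
  ttc:
    genotoxic_alert: false
    op_or_carbamate: false
    cramer_class: I
    in_ttc_domain: true
  pod_records:
    - endpoint: stot_re
      pod_type: NOEL
      value: [1.9, 3.1]
      units: mg/kg/day
      source_concentration: [171, 557]
      tier: tier2_invitro
      study_note: general toxicity, likely liver and/or kidney; in vitro PoD
        range 171-557 µM (major metabolite phenoxyacetic acid 217-359 µM);
        published IVIVE output stored directly
    - endpoint: stot_re
      pod_type: NOEL
      value: [360, 650]
      units: mg/kg/day
      tier: conventional
      study_note: 90-day rat study; increased liver weight, kidney and
        bladder effects, red blood cell decreases; NOAEL 369 (male) /
        652 (female) mg/kg
  overrides:
    - endpoint: stot_re
      tier: tier2_invitro
      category: not_classified
      note: published hazard table shows no STOT-RE classification; naive
        banding of the 1.9 mg/kg PoD lower bound gives category 1
    - endpoint: stot_re
      tier: conventional
      category: not_classified
      note: published hazard table shows no STOT-RE classification; naive
        banding of the 360 mg/kg PoD lower bound gives category 3
scenarios: null
expected:
  tier2_pod_mg_per_kg_day: [1.9, 3.1]
  dnels:
    tier2_invitro: [0.019, 0.031]
    conventional: [3.6, 6.5]
  dnel_display:
    tier2_invitro: {text: "0.02–0.03", sigfigs: 1}
    conventional: {text: "3.6–6.5", sigfigs: 2}
  endpoint_categories:
    tier2_invitro: {stot_re: not_classified}
    conventional: {stot_re: not_classified}
  suitable_long_term_exposure_categories: [C, D, E]
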
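# Worked case study EC1: a potent anti-androgenic fungicide (vinclozolin)
# assessed as an unknown through the tiered framework. Expected values are
# the published categories, DNELs and matrix verdicts used as the replay
# oracle; entries not derivable by banding are carried as expert overrides
# with provenance notes.
name: EC1
display_sigfigs: 2
dossier:
  schema_version: 1
  substance_id: EC1
  name: EC1 (vinclozolin) — tiered case study
  identifiers:
    cas: "50471-44-8"
  ttc:
    genotoxic_alert: false
    op_or_carbamate: false
    cramer_class: III
    in_ttc_domain: true
  pod_records:
    # Tier 2 — in vitro biological-activity panels + IVIVE (mg/kg outputs;
    # no in vitro concentrations were published for this substance)
    - endpoint: reproductive
      pod_type: NOEL
      value: 0.6
      units: mg/kg/day
      tier: tier2_invitro
      study_note: androgen receptor blockade (LOEL 2 mg/kg); male reproductive
        toxicity predicted; in vitro assays + IVIVE
    - endpoint: stot_re
      pod_type: NOEL
      value: 2
      units: mg/kg/day
      tier: tier2_invitro
      study_note: mitochondrial toxicity (LOEL 6 mg/kg); acute lethality and
        liver toxicity predicted; in vitro assays + IVIVE
    - endpoint: carcinogenicity
      pod_type: NOEL
      value: 2
      units: mg/kg/day
      tier: tier2_invitro
      study_note: CYP induction (LOEL 6 mg/kg); liver enlargement, potential
        carcinogenicity; in vitro assays + IVIVE
    - endpoint: carcinogenicity
      pod_type: NOEL
      value: 2
      units: mg/kg/day
      tier: tier2_invitro
      study_note: PPAR activation (LOEL 6 mg/kg); liver enlargement,
        peroxisomes, potential carcinogenicity; in vitro assays + IVIVE
    # Tier 3 — targeted in vivo
    - endpoint: reproductive
      pod_type: NOEL
      value: 25
      units: mg/kg/day
      tier: tier3_targeted_invivo
      study_note: Hershberger assay; anti-androgenic effects, NOEL read across
        to multigeneration outcome via the shared adverse outcome pathway
    - endpoint: stot_re
      pod_type: NOAEL
      value: 4
      units: mg/kg/day
      tier: tier3_targeted_invivo
      study_note: rat 90-day study; liver, adrenal and Leydig cell hypertrophy
    # Conventional plant-protection data package
    - endpoint: reproductive
      pod_type: NOAEL
      value: 2.5
      units: mg/kg/day
      tier: conventional
      study_note: rat multigeneration study; hypospadias and prostate-weight
        effects at 50 mg/kg, reduced sperm count at 100 mg/kg
    - endpoint: carcinogenicity
      pod_type: NOEL
      value: 2.7
      units: mg/kg/day
      tier: conventional
      study_note: rat long-term bioassay; Leydig cell and adrenal tumours
    - endpoint: carcinogenicity
      pod_type: NOEL
      value: 24
      units: mg/kg/day
      tier: conventional
      study_note: mouse long-term bioassay; liver tumours
    - endpoint: stot_re
      pod_type: NOEL
      value: 2.7
      units: mg/kg/day
      tier: conventional
      study_note: systemic (liver/adrenal) no-effect level from the rat
        long-term bioassay
  potency_assignments:
    - endpoint: carcinogenicity
      tier: tier3_targeted_invivo
      band: medium
      note: medium carcinogenic potency judged from CYP induction and
        anti-androgenicity modes of action
  overrides:
    - endpoint: carcinogenicity
      tier: tier2_invitro
      category: 1
      note: published tier-2 carcinogenicity category; naive banding of the
        2 mg/kg in vitro NOEL against the T25 limits gives category 2
    - endpoint: reproductive
      tier: conventional
      category: 2
      note: published conventional reproductive category (medium potency);
        naive ED10-surrogate banding of the 2.5 mg/kg NOAEL gives category 1
  dnel_overrides:
    - tier: conventional
      value: 0.024
      units: mg/kg/day
      note: published conventional DNEL, expert-assigned; derivation from the
        lowest published conventional NOAEL (2.5 mg/kg) would give 0.025
scenarios:
  schema_version: 1
  substance_id: EC1
  scenarios:
    - scenario_id: intermediate
      duration: long_term
      population: industrial workers
      steps:
        - exposure:
            dose: 2.0
            units: mg/kg/day
            route: dermal
            estimation_tier: tier1_screening
          hazard_tier: tier2_invitro
        - exposure:
            dose: 0.004
            units: mg/kg/day
            route: dermal
            estimation_tier: tier2_higher
          hazard_tier: tier2_invitro
        - exposure:
            dose: 0.004
            units: mg/kg/day
            route: dermal
            estimation_tier: tier2_higher
          hazard_tier: tier3_targeted_invivo
    - scenario_id: metal_working_fluid
      duration: long_term
      population: professional workers
      steps:
        - exposure:
            dose: 2.0
            units: mg/kg/day
            route: dermal
            estimation_tier: tier1_screening
          hazard_tier: tier2_invitro
        - exposure:
            dose: 0.002
            units: mg/kg/day
            route: dermal
            estimation_tier: tier2_higher
          hazard_tier: tier2_invitro
        - exposure:
            dose: 0.002
            units: mg/kg/day
            route: dermal
            estimation_tier: tier2_higher
          hazard_tier: tier3_targeted_invivo
    - scenario_id: hobby_glue
      duration: long_term
      population: consumers
      steps:
        - exposure:
            dose: 2.0
            units: mg/kg/day
            route: dermal
            estimation_tier: tier1_screening
          hazard_tier: tier2_invitro
        - exposure:
            dose: 0.05
            units: mg/kg/day
            route: dermal
            estimation_tier: tier2_higher
          hazard_tier: tier2_invitro
        - exposure:
            dose: 0.05
            units: mg/kg/day
            route: dermal
            estimation_tier: tier2_higher
          hazard_tier: tier3_targeted_invivo
expected:
  ttc_ug_per_kg_day: 1.5
  tier0_passes: false
  endpoint_categories:
    tier2_invitro: {stot_re: 1, reproductive: 1, carcinogenicity: 1}
    tier3_targeted_invivo: {stot_re: 1, reproductive: 2, carcinogenicity: 2}
    conventional: {stot_re: 1, reproductive: 2, carcinogenicity: 2}
  dnels:
    tier2_invitro: [0.006, 0.006]
    tier3_targeted_invivo: [0.04, 0.04]
    conventional: [0.024, 0.024]
  dnel_display:
    tier2_invitro: {text: "0.006", sigfigs: 2}
    tier3_targeted_invivo: {text: "0.04", sigfigs: 2}
    conventional: {text: "0.024", sigfigs: 2}
  trajectory:
    intermediate:
      - {exposure_category: B, hazard_category: 1, colour: red,
         verdict: unacceptable, recommendation: refine_exposure}
      - {exposure_category: D, hazard_category: 1, colour: amber,
         verdict: insufficient_confidence, recommendation: escalate_hazard_tier}
      - {exposure_category: D, hazard_category: 1, colour: amber,
         verdict: acceptable, recommendation: accept}
    metal_working_fluid:
      - {exposure_category: B, hazard_category: 1, colour: red,
         verdict: unacceptable, recommendation: refine_exposure}
      - {exposure_category: D, hazard_category: 1, colour: amber,
         verdict: insufficient_confidence, recommendation: escalate_hazard_tier}
      - {exposure_category: D, hazard_category: 1, colour: amber,
         verdict: acceptable, recommendation: accept}
    hobby_glue:
      - {exposure_category: B, hazard_category: 1, colour: red,
         verdict: unacceptable, recommendation: refine_exposure}
      - {exposure_category: C, hazard_category: 1, colour: red,
         verdict: unacceptable, recommendation: escalate_hazard_tier}
      - {exposure_category: C, hazard_category: 1, colour: red,
         verdict: unacceptable, recommendation: reject}
  terminal:
    intermediate: accept
    metal_working_fluid: accept
    hobby_glue: reject
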
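# Worked case study EC2: a benzopyrone with mild non-specific toxicity
# (coumarin). The tier-2 in vitro PoD range (6-60 µM) converts to mg/kg/day
# through the fixed IVIVE factor back-calculated from the published
# input/output pair (36-360 mg/kg). The final published assessments are
# borderline-acceptable for both uses at the tier-2 exposure / tier-2
# hazard comparison; conventional 2-year-study data are carried for the
# hazard-output comparison. Published exposure-category letters for the
# two interval exposures reflect the interval lower end; the engine's
# health-protective upper-end convention yields B where the publication
# printed C (matrix colour and verdict are identical).
name: EC2
display_sigfigs: 2
dossier:
  schema_version: 1
  substance_id: EC2
  name: EC2 (coumarin) — tiered case study
  identifiers:
    cas: "91-64-5"
  ttc:
    genotoxic_alert: false
    op_or_carbamate: false
    cramer_class: III
    in_ttc_domain: true
  pod_records:
    - endpoint: carcinogenicity
      pod_type: NOEL
      value: [6, 60]
      units: µM
      ivive:
        mode: fixed_factor
        factor: 6.0
      tier: tier2_invitro
      study_note: CYP450 induction pathway PoD (panel also flagged MAO
        inhibition 12-40 µM, carbonic anhydrase inhibition 21-62 µM, cellular
        stress 500-800 µM); mild non-specific toxicity with liver
        hypertrophy/hyperplasia, possible hepatocarcinogenicity at high doses
    - endpoint: carcinogenicity
      pod_type: NOEL
      value: [16, 42]
      units: mg/kg/day
      tier: conventional
      study_note: 2-year rat study; mild non-specific toxicity with
        hepatoenlargement, hepatocarcinogenicity at high doses
scenarios:
  schema_version: 1
  substance_id: EC2
  scenarios:
    - scenario_id: drum_filling
      duration: long_term
      population: industrial workers (drum and small-package filling)
      steps:
        - exposure:
            dose: [5, 20]
            units: mg/kg/day
            route: dermal
            estimation_tier: tier1_screening
            population: worst case, aerosol possible, no gloves, 100% absorption
          hazard_tier: tier2_invitro
        - exposure:
            dose: [0.5, 1.45]
            units: mg/kg/day
            route: dermal
            estimation_tier: tier1_refined
            population: reasonable exposure control measures assumed
          hazard_tier: tier2_invitro
        - exposure:
            dose: [0.5, 1.45]
            units: mg/kg/day
            route: dermal
            estimation_tier: tier2_higher
            population: higher-tier occupational exposure model
          hazard_tier: tier2_invitro
    - scenario_id: household_cleaning
      duration: long_term
      population: consumers (dish washing, laundry, all-purpose cleaners,
        trigger sprays)
      steps:
        - exposure:
            dose: [2, 15]
            units: mg/kg/day
            route: dermal
            estimation_tier: tier1_screening
            population: worst case, 100% absorption
          hazard_tier: tier2_invitro
        - exposure:
            dose: [1.2, 12]
            units: mg/kg/day
            route: dermal
            estimation_tier: tier1_refined
            population: specific consumer exposure determinants applied
          hazard_tier: tier2_invitro
        - exposure:
            dose: [0.09, 3.2]
            units: mg/kg/day
            route: dermal
            estimation_tier: tier2_higher
            population: higher-tier consumer exposure model
          hazard_tier: tier2_invitro
expected:
  ttc_ug_per_kg_day: 1.5
  tier0_passes: false
  ivive_handoff:
    conc_um: [6, 60]
    factor: 6.0
    dose_mg_per_kg_day: [36, 360]
  endpoint_categories:
    tier2_invitro: {carcinogenicity: 2}
    conventional: {carcinogenicity: 2}
  dnels:
    tier2_invitro: [0.36, 3.6]
    conventional: [0.16, 0.42]
  dnel_display:
    tier2_invitro: {text: "0.36–3.6", sigfigs: 2}
    conventional: {text: "0.16–0.42", sigfigs: 2}
  trajectory:
    drum_filling:
      - {exposure_category: A, hazard_category: 2, colour: red,
         verdict: unacceptable, recommendation: refine_exposure}
      - {exposure_category: B, hazard_category: 2, colour: amber,
         verdict: borderline, recommendation: refine_exposure}
      - {exposure_category: B, hazard_category: 2, colour: amber,
         verdict: borderline, recommendation: compare_moe}
    household_cleaning:
      - {exposure_category: A, hazard_category: 2, colour: red,
         verdict: unacceptable, recommendation: refine_exposure}
      - {exposure_category: A, hazard_category: 2, colour: red,
         verdict: unacceptable, recommendation: refine_exposure}
      - {exposure_category: B, hazard_category: 2, colour: amber,
         verdict: borderline, recommendation: compare_moe}
  terminal:
    drum_filling: open
    household_cleaning: open
  final_verdict: borderline
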
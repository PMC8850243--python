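# namtier

Tiered hazard/exposure chemical safety assessment as a deterministic,
replayable decision engine.

Regulatory safety assessment under REACH-style systems increasingly uses
new approach methodologies (NAMs): in silico alerts, in vitro
biological-activity panels with in vitro to in vivo extrapolation (IVIVE),
and targeted in vivo studies, arranged in tiers of increasing certainty.
`namtier` implements the decision layer that sits on top of those data
sources, for toxicologists and risk assessors who want its arithmetic
explicit and reproducible:

- **Hazard potency banding** — points of departure (NOAEL, NOEL, ATE, T25,
  ED10, …) are banded into CLP-derived categories 1–4/not-classified per
  endpoint (acute oral, STOT-SE, dermal sensitisation, STOT-RE,
  carcinogenicity, reproductive toxicity), using the SCL potency scheme
  where CLP categories encode evidence rather than potency.
- **DNEL derivation** — DNEL = PoD / UF (default UF = 100 = 10 × 10), from
  the lowest systemic PoD of each tier, on exact intervals.
- **Exposure categories A–E** — duration-specific boundaries *derived*
  from the same band limits, the study limit doses and the substance TTC
  (e.g. long term: A > 10, B 1–10, C 0.01–1 mg/kg/day, D down to the TTC,
  E below it).
- **TTC screening (tier 0)** — 0.0025 / 0.3 / 1.5 / 9.0 / 30 µg/kg/day by
  structural basis with alerts-before-Cramer precedence; a pass ends the
  assessment green.
- **IVIVE** — µM → mg/kg/day via a fixed factor or steady-state reverse
  dosimetry (C · CL · 24 · MW / 1000 / f_abs).
- **Decision matrix** — hazard × exposure → red/amber/green, with amber
  resolved by interval margin-of-exposure comparison and tier-dependent
  confidence multipliers (×10 for in vitro hazard), and recommendations
  (accept / refine exposure / escalate hazard tier / reject).

Dossiers and scenarios are schema-validated YAML/JSON; three published
case studies (EC1–EC3) ship as replayable fixtures; a seeded generator
produces synthetic dossiers for property testing. See `docs/methods.md`
for the full model description and conventions.

## Worked example

The derived exposure-category boundary table for a Cramer class III
substance (TTC 1.5 µg/kg/day):

```
$ namtier boundaries --ttc-ug 1.5
duration    | Cat A (mg/kg) | Cat B (mg/kg) | Cat C (mg/kg) | Cat D (mg/kg) | Cat E (µg/kg)
one_day     | > 50          | 20–50         | 3–20          | 0.0015–3      | < 1.5
short_term  | > 10          | 4–10          | 0.04–4        | 0.0015–0.04   | < 1.5
long_term   | > 10          | 1–10          | 0.01–1        | 0.0015–0.01   | < 1.5
```

Each boundary is a band limit divided by the uncertainty factor — e.g. the
long-term C/D boundary 0.01 mg/kg/day is the carcinogenicity category-1
limit (1 mg/kg/day T25) / 100 — and the command also prints that
derivation trace.

Banding a 90-day NOAEL of 4 mg/kg/day:

```
$ namtier classify --endpoint stot_re --pod 4
endpoint: stot_re
category: 1
bands: <= 10 -> 1, <= 100 -> 2, <= 1000 -> 3, above -> 4
```

Replaying the first packaged case study — an anti-androgenic fungicide
assessed for three uses (chemical intermediate, metal working fluid,
hobby glue):

```
$ namtier fixtures run EC1
# Safety assessment: EC1

TTC basis: cramer_III — 1.5 µg/kg/day

## Hazard categories and DNELs per tier

| | tier2_invitro | tier3_targeted_invivo | conventional |
|---|---|---|---|
| stot_re | 1 | 1 | 1 |
| carcinogenicity | 1* | 2 | 2 |
| reproductive | 1 | 2 | 2* |
| DNEL (mg/kg/day) | 0.006 | 0.04 | 0.024* |

## Scenario: intermediate (long_term)

Tier 0 TTC screen: fail (margin 0.00075)

| step | hazard tier | hazard cat | exposure cat | colour | MoE | verdict | recommendation |
|---|---|---|---|---|---|---|---|
| 1 | tier2_invitro | 1 | B | red | 0.003 | unacceptable | refine_exposure |
| 2 | tier2_invitro | 1 | D | amber | 1.5 | insufficient_confidence | escalate_hazard_tier |
| 3 | tier3_targeted_invivo | 1 | D | amber | 10 | acceptable | accept |

Terminal state: **accept**
...
```

Reading the trajectory: worst-case exposure estimates put every use in
category B against a category-1 hazard (red). Refined exposure moves the
intermediate use to category D (amber), but the margin over the in vitro
DNEL (0.006 mg/kg/day vs 0.004 mg/kg/day exposure, MoE 1.5) is below the
×10 confidence multiplier required of a tier-2 hazard assessment, so the
engine escalates to targeted in vivo. The tier-3 DNEL of 0.04 mg/kg/day
gives MoE 10 at full confidence: accepted. The hobby-glue use stays in
category C/red at every step and is rejected. Starred cells are expert
overrides, disclosed with their provenance at the end of the report.

The same assessment runs on your own files:

```
namtier assess --dossier substance.yaml --scenarios uses.yaml --out report.md --json trace.json
```

(exit code 0 = all uses accepted, 2 = any rejected, 3 = any left open or
borderline). Python API: `namtier.assess`, `namtier.classify_endpoint`,
`namtier.derive_boundaries`, `namtier.moe_verdict`, etc.

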
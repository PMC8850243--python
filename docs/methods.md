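# Methods

`namtier` implements a tiered, exposure-led chemical safety assessment as a
deterministic decision engine. It is aimed at regulatory toxicologists and
risk assessors who want the arithmetic of a next-generation risk assessment
— potency banding, TTC screening, IVIVE, DNEL derivation and a hazard ×
exposure decision matrix — to be explicit, replayable and configurable,
rather than buried in spreadsheets. Everything below is computed by the
package; nothing is asserted that the test suite or `scripts/acceptance.py`
does not itself recompute.

## Hazard potency bands

Six endpoints carry an ordered band table mapping a point of departure
(PoD) to a hazard category (1 most severe). The dose limits come from the
CLP classification system; for carcinogenicity and reproductive toxicity,
whose CLP categories encode strength of evidence rather than potency, the
specific-concentration-limit (SCL) potency scheme is used instead (T25 and
ED10 metrics; high/medium/low potency → categories 1/2/3). All limits are
in mg/kg bw/day from animal studies, except dermal sensitisation
(concentration %):

| endpoint (metric) | cat 1 | cat 2 | cat 3 | cat 4 | cat 5 |
|---|---|---|---|---|---|
| acute oral (ATE) | < 5 | 5–50 | 50–300 | 300–2000 | > 2000 |
| STOT-SE (NOAEL) | < 300 | 300–2000 | 2000–5000 | > 5000 | |
| dermal sens. (conc.) | < 0.1 % | 0.1–10 % | 10–100 % | no response | |
| STOT-RE (NOAEL) | < 10 | 10–100 | 100–1000 | > 1000 | |
| carcinogenicity (T25) | < 1 | 1–100 | > 100 | | |
| reproductive (ED10) | < 4 | 4–400 | > 400 | | |

The STOT categories 3–4 extrapolate the CLP 1–2 ranges so every endpoint
spans four potency bands. Carcinogenicity and reproductive "no response"
yield *not classified*. The tables ship as a versioned constant and can be
replaced through a YAML `bands:` config for future CLP revisions.

Conventions, all health-protective and mirrored on the exposure side:

- an interval PoD is banded by its **lower** end;
- a value exactly on a shared band limit takes the **more severe**
  category (the printed bands are ambiguous at shared limits such as 300);
- NOAEL/NOEL/LOEL values are accepted as conservative surrogates for the
  canonical metric of a dose endpoint (case-study practice bands NOELs
  against the T25/ED10 limits); cross-endpoint metrics and
  concentration-percent values on dose endpoints are rejected.

Expert category overrides are allowed per endpoint and tier, always with a
mandatory provenance note, and are disclosed in every report; they exist
because published category assignments occasionally encode judgement that
no banding rule reproduces.

## DNELs

The derived no-effect level is the PoD interval divided by a single global
uncertainty factor, default 100 (10 interspecies × 10 intraspecies),
configurable. The driving PoD for a tier is the **lowest systemic** PoD at
that tier (dermal sensitisation, being a concentration, never drives;
ties break by a fixed endpoint order). No rounding happens in the
computation core; the report layer displays 2 significant figures by
default, with exact values in the JSON twin.

## Exposure categories A–E

Exposure is described by a duration class — single/1-day, repeat dose up
to 3 months, longer term — and a dose banded into categories A (highest)
to E (lowest). The boundaries are **derived**, not configured:

1. *A lower bound* = duration-appropriate limit dose / UF. One-day uses
   the STOT-SE top band (5000 mg/kg → 50); repeat durations use the
   repeat-dose limit dose (1000 mg/kg → 10).
2. Among the duration-relevant endpoints (1-day: STOT-SE; ≤ 3 months:
   STOT-RE + reproductive; > 3 months: STOT-RE + carcinogenicity +
   reproductive) the endpoint with the **lowest category-1 limit**
   drives the duration.
3. *B/C* = driver's category-2 limit / UF; *C/D* = driver's category-1
   limit / UF.
4. *D/E* = the substance-specific TTC.

With defaults this yields exactly: 1-day A > 50, B 20–50, C 3–20; short
term A > 10, B 4–10, C 0.04–4; long term A > 10, B 1–10, C 0.01–1
(mg/kg/day). A design note: a "take the lowest relevant limit" principle
applied element-wise would give a short-term B/C boundary of 1 (STOT-RE's
category-2 limit / 100), not 4; only the single-driving-endpoint rule
reproduces the published limits, so it is the default, the element-wise
minimum is available as `strategy="elementwise_min"`, and every boundary
records its source in a derivation trace.

An exposure interval is categorised by its **upper** end; a dose exactly
on a boundary takes the higher-exposure category; anything below the TTC
is E. Category A is unbounded above. Dermal and inhalation exposures are
converted to oral-equivalent systemic doses by route absorption fractions
(worst-case 1.0 defaults); inhalation concentrations (mg/m³) are first
converted via inhaled volume / body weight (60 kg default, the TTC basis).

## TTC screening (tier 0)

The substance TTC follows from structural flags with alerts-before-Cramer
precedence: genotoxicity alert 0.0025, organophosphate/carbamate 0.3,
Cramer III 1.5, Cramer II 9.0, Cramer I 30 µg/kg/day. The values already
include uncertainty adjustment and, being anchored to long-term exposure,
are used unchanged for all durations (conservative for short ones). An
unknown Cramer class with no alerts is an error unless the conservative
Cramer-III default is explicitly opted into. A tier-0 pass — the whole
exposure interval strictly below the TTC — terminates assessment with
category E and a green decision.

Corner case the published tables never confront: the Cramer-I TTC
(30 µg/kg/day) exceeds the long-term C/D boundary (10 µg/kg/day). The
standalone derivation treats this as an error; inside the engine the D/E
boundary is clamped at the C/D boundary (category D empties,
health-protectively) and tier 0 screens against the clamped limit, so a
pass still lands in category E.

## IVIVE

In vitro PoD concentrations (µM) reach mg/kg/day through a pluggable
converter. The documented default is one-compartment reverse dosimetry at
steady state — dose = C · CL · 24 · MW / 1000 / f_abs, with
total-concentration matching (an opt-in flag divides by the unbound
fraction for free-concentration matching). The worked-example fixtures
instead carry fixed factors back-calculated from published input/output
pairs, labelled as fixture data, because the studies behind them do not
publish their kinetic models. Both modes are linear and monotone in
concentration.

## Decision matrix and margin of exposure

The matrix crosses hazard categories 1–4/not-classified with exposure
categories A–E. The default cell map — a reconstruction anchored to every
colour statement in the worked case studies, since the published figure is
schematic — is:

| hazard \ exposure | A | B | C | D | E |
|---|---|---|---|---|---|
| 1 | red | red | red | amber | green |
| 2 | red | amber | amber | green | green |
| 3 | amber | amber | green | green | green |
| 4 / n.c. | amber¹ | green | green | green | green |

¹ green only when a tier-3+ limit-dose study confirmed no relevant
toxicity for the duration (`limit_dose_clearance`).

Any user-supplied map is validated monotone along both axes at load time.
Blended published segments ("red/amber") are treated as the more
conservative pure colour.

Amber forces a margin-of-exposure comparison on full intervals: exposure
entirely at or below the DNEL interval is *acceptable*, entirely above is
*unacceptable*, overlap is *borderline*. Tier confidence enters as a
required-margin multiplier (defaults 100 / 10 / 1 / 1 for in silico /
in vitro / targeted in vivo / conventional, reflecting the 1–2 orders of
magnitude of extra uncertainty observed for in vitro PoDs): a comparison
acceptable against the raw DNEL but not against DNEL/multiplier returns
*insufficient confidence* — the signal to escalate the hazard tier rather
than reject. The tier-2 multiplier of 10 is the minimum consistent with
the case-study escalation (a tier-2 margin of 1.5 rejected, a tier-3
margin of 10 accepted) while leaving interval-overlap borderlines intact.

Recommendations follow the cell and verdict: green/acceptable → accept;
insufficient confidence → escalate the hazard tier (or reject if none
remains); red/unacceptable → refine exposure, else escalate, else reject;
borderline → refine whichever side has headroom, else report the
borderline. The engine replays exactly the (exposure estimate × hazard
tier) steps present in the inputs — it recommends refinements but never
fabricates them; refinability is read off the remaining steps.

## Worked case-study fixtures

Three packaged fixtures (EC1 anti-androgenic fungicide, EC2 benzopyrone,
EC3 preservative) carry dossier, stepped scenarios and the published
outcomes as replay oracles. Values not derivable by the engine's rules are
stored as overrides with notes rather than silently derived: EC1's
conventional DNEL (0.024 vs the derivable 0.025) and reproductive category,
EC1's tier-2 carcinogenicity category, EC3's unclassified STOT-RE rows.
EC1's first-step exposures are representative values placed in the
published categories (only the categories, not the doses, were published
for that step). Display precision is stored per fixture: 2 significant
figures generally, 1 for EC3's tier-2 DNEL (matching its published
"0.02–0.03").

## Synthetic dossier generator

`generate_random_dossier(seed)` emulates the *structure* of a dossier —
log-uniform PoDs spanning every potency band (10⁻³–10⁴ mg/kg/day;
0.01–100 % for dermal sensitisation), sampled TTC flags, log-uniform
exposures spanning every category (10⁻⁶–10³ mg/kg/day), sampled durations
and one-or-two-step scenarios — under a reproducibility contract (same
seed, same output). It makes no attempt to emulate correlations found in
real dossiers (endpoint co-occurrence, tier-to-tier PoD concordance,
route-specific exposure patterns), so property tests built on it
demonstrate the engine's internal consistency across the input space, not
predictive performance on real chemicals.

## Numerical choices and scale

All internal doses are mg/kg bw/day (µg/kg/day normalised on input);
intervals are closed, with point values as degenerate intervals; zero
exposure is acceptable with infinite margin, never an error; all
comparisons are exact floating-point with the two boundary tie-break
conventions above — no tolerances are needed because every derivation is
a division of printed constants. The test suite's property checks run
10,000 seeded cases per invariant family, and the full suite plus the
acceptance script complete in well under a minute on one CPU; the
acceptance script additionally replays five seeded synthetic dossiers
end-to-end as a self-check.

## Known limitations

- Exposure estimation itself (TRA, ART, ConsExpo) is out of scope:
  exposures are inputs.
- In silico alert tools, the Cramer decision tree and full PBK modelling
  are out of scope; their outputs enter as flags, PoDs or conversion
  specs.
- Inhalation/dermal-specific CLP band variants are not implemented; all
  banding is on oral-equivalent doses.
- The matrix cell map beyond the cells anchored by the case studies is a
  reconstruction; regulators may legitimately configure it differently.
- Categorising interval exposures by their upper end can place a wide
  published interval one category higher than a central-estimate reading
  would; the matrix colour is usually, but not always, unchanged.
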
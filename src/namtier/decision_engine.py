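"""Red/amber/green hazard x exposure matrix and assessment trajectories.

The matrix crosses the hazard category (1 most severe .. 4/not-classified)
with the exposure category (A highest .. E lowest). Green means an adequate
margin of exposure, amber a borderline margin forcing an explicit
margin-of-exposure (MoE) comparison, red an inadequate margin. The full
cell map is configurable; the default is anchored to the worked case
studies and is monotone along both axes. One special rule: a
category-4/not-classified hazard meets category A exposure as green only
when a limit-dose study at tier 3 or above has confirmed no relevant
toxicity — otherwise the cell is amber.

Amber cells are resolved by comparing the full DNEL interval with the full
exposure interval. A tier-confidence multiplier widens the margin required
before a lower-tier hazard assessment may conclude "acceptable": an
exposure acceptable against the raw DNEL but not against DNEL/multiplier
yields ``insufficient_confidence``, the signal to escalate the hazard tier
rather than to reject.

:func:`assess` replays a dossier against stepped exposure scenarios,
emitting one decision record per refinement step — the trajectory of
positions a use traces through the matrix. The engine recommends the next
refinement but never fabricates one: only the steps present in the inputs
are evaluated.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import TYPE_CHECKING, Mapping, Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .exposure_categories import (
    DURATION_RELEVANT_ENDPOINTS,
    DurationClass,
    ExposureCategory,
    EXPOSURE_TIER_ORDER,
    LimitDoses,
    RouteAbsorption,
    categorise_dose,
    derive_boundaries,
    to_systemic_dose,
)
from .hazard_bands import (
    DEFAULT_BANDS,
    DNEL,
    Category,
    HazardProfile,
    Tier,
    build_hazard_profile,
    severity_rank,
    tier_rank,
)
from .intervals import DoseInterval
from .ttc_screen import Tier0Result, TTCAssignment, assign_ttc

if TYPE_CHECKING:  # pragma: no cover
    from .dossier_io import ScenarioSet, SubstanceDossier


class Colour(str, Enum):
    green = "green"
    amber = "amber"
    red = "red"


_COLOUR_RANK = {Colour.green: 0, Colour.amber: 1, Colour.red: 2}


def hazard_row(category: Optional[Category]) -> int:
    """Matrix row for a hazard category; 4 and not-classified share a row."""
    if isinstance(category, int) and 1 <= category <= 3:
        return category
    return 4


_DEFAULT_CELLS = {
    1: {"A": "red", "B": "red", "C": "red", "D": "amber", "E": "green"},
    2: {"A": "red", "B": "amber", "C": "amber", "D": "green", "E": "green"},
    3: {"A": "amber", "B": "amber", "C": "green", "D": "green", "E": "green"},
    4: {"A": "amber", "B": "green", "C": "green", "D": "green", "E": "green"},
}


class MatrixConfig(BaseModel):
    """Hazard-row x exposure-category -> colour map, validated monotone."""

    model_config = ConfigDict(frozen=True)

    cells: Mapping[int, Mapping[ExposureCategory, Colour]]
    #: row 4 x category A turns green when a tier-3+ limit-dose study
    #: confirmed no relevant toxicity for the scenario's duration
    limit_dose_rule: bool = True

    @model_validator(mode="after")
    def _check(self) -> "MatrixConfig":
        rows = set(self.cells)
        if rows != {1, 2, 3, 4}:
            raise ValueError("matrix needs exactly hazard rows 1-4")
        for row in (1, 2, 3, 4):
            if set(self.cells[row]) != set(ExposureCategory):
                raise ValueError(f"row {row} must cover exposure categories A-E")
        for row in (1, 2, 3, 4):
            for a, b in zip(tuple(ExposureCategory), tuple(ExposureCategory)[1:]):
                if _COLOUR_RANK[self.cells[row][b]] > _COLOUR_RANK[self.cells[row][a]]:
                    raise ValueError(
                        f"not monotone: row {row} worsens from {a.value} to {b.value}"
                    )
        for cat in ExposureCategory:
            for row in (1, 2, 3):
                if (
                    _COLOUR_RANK[self.cells[row + 1][cat]]
                    > _COLOUR_RANK[self.cells[row][cat]]
                ):
                    raise ValueError(
                        f"not monotone: column {cat.value} worsens from hazard "
                        f"{row} to {row + 1}"
                    )
        return self


DEFAULT_MATRIX = MatrixConfig(cells=_DEFAULT_CELLS)


def matrix_lookup(
    hazard_category: Optional[Category],
    exposure_category: ExposureCategory,
    config: MatrixConfig = DEFAULT_MATRIX,
    limit_dose_cleared: bool = False,
) -> Colour:
    row = hazard_row(hazard_category)
    colour = config.cells[row][exposure_category]
    if (
        config.limit_dose_rule
        and row == 4
        and exposure_category == ExposureCategory.A
        and limit_dose_cleared
    ):
        return Colour.green
    return colour


class TierConfidence(BaseModel):
    """Margin multiplier required before a tier's DNEL supports
    "acceptable" (>= 1; lower tiers carry more uncertainty)."""

    model_config = ConfigDict(frozen=True)

    multipliers: Mapping[Tier, float] = {
        Tier.tier1_insilico: 100.0,
        Tier.tier2_invitro: 10.0,
        Tier.tier3_targeted_invivo: 1.0,
        Tier.conventional: 1.0,
    }

    @model_validator(mode="after")
    def _check(self) -> "TierConfidence":
        if any(m < 1 for m in self.multipliers.values()):
            raise ValueError("confidence multipliers must be >= 1")
        return self

    def multiplier(self, tier: Tier) -> float:
        return self.multipliers.get(tier, 1.0)


DEFAULT_CONFIDENCE = TierConfidence()


class Verdict(str, Enum):
    acceptable = "acceptable"
    borderline = "borderline"
    unacceptable = "unacceptable"
    insufficient_confidence = "insufficient_confidence"
    not_evaluated = "not_evaluated"


class Recommendation(str, Enum):
    accept = "accept"
    reject = "reject"
    refine_exposure = "refine_exposure"
    escalate_hazard_tier = "escalate_hazard_tier"
    compare_moe = "compare_moe"


class MoEResult(BaseModel):
    model_config = ConfigDict(frozen=True, ser_json_inf_nan="constants")

    moe: float
    verdict: Verdict


def _trichotomy(safe: DoseInterval, exposure: DoseInterval) -> Verdict:
    if exposure.hi <= safe.lo:
        return Verdict.acceptable
    if exposure.lo > safe.hi:
        return Verdict.unacceptable
    return Verdict.borderline


def moe_verdict(
    dnel: DoseInterval,
    exposure: DoseInterval,
    multiplier: float = 1.0,
) -> MoEResult:
    """Interval margin-of-exposure comparison.

    The raw DNEL/exposure interval trichotomy gives acceptable, borderline
    or unacceptable; an acceptable raw comparison that fails once the DNEL
    is divided by the tier-confidence multiplier becomes
    ``insufficient_confidence``. MoE = DNEL.lo / exposure.hi.
    """
    if multiplier < 1:
        raise ValueError("confidence multiplier must be >= 1")
    if exposure.hi == 0:
        return MoEResult(moe=math.inf, verdict=Verdict.acceptable)
    if dnel.lo <= 0:
        raise ValueError("DNEL must be positive")
    moe = dnel.lo / exposure.hi
    raw = _trichotomy(dnel, exposure)
    adjusted = _trichotomy(dnel / multiplier, exposure)
    if adjusted == Verdict.acceptable:
        verdict = Verdict.acceptable
    elif raw == Verdict.acceptable:
        verdict = Verdict.insufficient_confidence
    else:
        verdict = raw
    return MoEResult(moe=moe, verdict=verdict)


def recommend_next(
    colour: Colour,
    verdict: Verdict,
    exposure_refinable: bool,
    hazard_escalatable: bool,
) -> Recommendation:
    """Next step from a cell colour, its MoE verdict and what refinements
    remain available."""
    if colour == Colour.green or verdict == Verdict.acceptable:
        return Recommendation.accept
    if verdict == Verdict.insufficient_confidence:
        return (
            Recommendation.escalate_hazard_tier
            if hazard_escalatable
            else Recommendation.reject
        )
    if colour == Colour.red or verdict == Verdict.unacceptable:
        if exposure_refinable:
            return Recommendation.refine_exposure
        if hazard_escalatable:
            return Recommendation.escalate_hazard_tier
        return Recommendation.reject
    # amber / borderline: refine whichever side has headroom, else report
    if exposure_refinable:
        return Recommendation.refine_exposure
    if hazard_escalatable:
        return Recommendation.escalate_hazard_tier
    return Recommendation.compare_moe


class DecisionRecord(BaseModel):
    model_config = ConfigDict(frozen=True, ser_json_inf_nan="constants")

    scenario_id: str
    refinement_step: int
    hazard_tier: Optional[Tier] = None
    hazard_category: Optional[Category] = None
    exposure_category: Optional[ExposureCategory] = None
    colour: Optional[Colour] = None
    moe: Optional[float] = None
    verdict: Verdict
    recommendation: Recommendation
    dnel: Optional[DoseInterval] = None
    systemic_dose: Optional[DoseInterval] = None
    notes: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "DecisionRecord":
        if self.colour == Colour.amber and self.verdict == Verdict.not_evaluated:
            raise ValueError("an amber cell forces an MoE comparison")
        return self


class ScenarioTrajectory(BaseModel):
    model_config = ConfigDict(frozen=True)

    scenario_id: str
    duration: DurationClass
    tier0: Tier0Result
    records: tuple[DecisionRecord, ...] = ()
    terminal_state: str = "open"  # accept | reject | open
    recommended_next: Optional[Recommendation] = None


class AssessmentTrajectory(BaseModel):
    model_config = ConfigDict(frozen=True)

    substance_id: str
    ttc: TTCAssignment
    hazard_profiles: tuple[HazardProfile, ...] = ()
    scenarios: tuple[ScenarioTrajectory, ...] = ()

    def profile_for(self, tier: Tier) -> Optional[HazardProfile]:
        for p in self.hazard_profiles:
            if p.tier == tier:
                return p
        return None

    def scenario(self, scenario_id: str) -> ScenarioTrajectory:
        for s in self.scenarios:
            if s.scenario_id == scenario_id:
                return s
        raise KeyError(scenario_id)


def _duration_hazard_category(
    profile: HazardProfile, duration: DurationClass
) -> Optional[Category]:
    """Most severe category among endpoints relevant to the duration."""
    relevant = DURATION_RELEVANT_ENDPOINTS[duration]
    cats = [
        r.category
        for r in profile.endpoint_results
        if r.endpoint in relevant and r.category is not None
    ]
    if not cats:
        return None
    return min(cats, key=severity_rank)


def assess(
    dossier: "SubstanceDossier",
    scenarios: "ScenarioSet",
    matrix: MatrixConfig = DEFAULT_MATRIX,
    confidence: TierConfidence = DEFAULT_CONFIDENCE,
    bands=None,
    limits: Optional[LimitDoses] = None,
    uncertainty_factor: float = 100.0,
    body_weight_kg: float = 60.0,
    assume_cramer_iii: bool = False,
) -> AssessmentTrajectory:
    """Replay a dossier against stepped exposure scenarios.

    Per scenario: a tier-0 TTC screen on the first exposure estimate (a
    pass terminates with category E / green / accept); then one decision
    record per (exposure estimate, hazard tier) step present in the
    inputs. A scenario duration with no relevant endpoint data at a step's
    tier is reported as a data gap, not raised.
    """
    if not scenarios.scenarios:
        raise ValueError("at least one exposure scenario is required")
    bands = bands or DEFAULT_BANDS
    ttc = assign_ttc(dossier.ttc_flags, assume_cramer_iii=assume_cramer_iii)

    tiers_with_data = sorted(
        {r.tier for r in dossier.pod_records}
        | {a.tier for a in dossier.potency_assignments}
        | {o.tier for o in dossier.overrides},
        key=tier_rank,
    )
    profiles = {
        tier: build_hazard_profile(
            dossier.substance_id,
            tier,
            dossier.pod_records,
            potency_assignments=dossier.potency_assignments,
            overrides=dossier.overrides,
            dnel_overrides=dossier.dnel_overrides,
            bands=bands,
            uncertainty_factor=uncertainty_factor,
        )
        for tier in tiers_with_data
    }
    absorption = dossier.absorption or RouteAbsorption()

    trajectories = []
    for scenario in scenarios.scenarios:
        boundaries = derive_boundaries(
            scenario.duration,
            bands=bands,
            limits=limits,
            ttc=ttc.mg_per_kg_day,
            uncertainty_factor=uncertainty_factor,
            clamp_ttc=True,
        )
        doses = [
            to_systemic_dose(
                step.exposure, absorption=absorption, body_weight_kg=body_weight_kg
            )
            for step in scenario.steps
        ]
        # screen against the duration's effective D/E boundary (the TTC,
        # unless clamped at the C/D boundary) so that a pass always lands
        # in category E
        limit = boundaries.ttc
        if doses[0].hi == 0:
            t0 = Tier0Result(passes=True, margin=math.inf)
        else:
            t0 = Tier0Result(
                passes=doses[0].hi < limit, margin=limit / doses[0].hi
            )
        records = []
        if t0.passes:
            records.append(
                DecisionRecord(
                    scenario_id=scenario.scenario_id,
                    refinement_step=0,
                    exposure_category=ExposureCategory.E,
                    colour=Colour.green,
                    moe=t0.margin,
                    verdict=Verdict.acceptable,
                    recommendation=Recommendation.accept,
                    systemic_dose=doses[0],
                    notes=("tier-0 TTC screen passed",),
                )
            )
        else:
            for i, (step, dose) in enumerate(zip(scenario.steps, doses), start=1):
                later = scenario.steps[i:]
                exposure_refinable = any(
                    s.exposure.external_dose != step.exposure.external_dose
                    or EXPOSURE_TIER_ORDER.index(s.exposure.estimation_tier)
                    > EXPOSURE_TIER_ORDER.index(step.exposure.estimation_tier)
                    for s in later
                )
                hazard_escalatable = any(
                    tier_rank(s.hazard_tier) > tier_rank(step.hazard_tier)
                    for s in later
                )
                exp_result = categorise_dose(dose, boundaries, scenario.scenario_id)
                profile = profiles.get(step.hazard_tier)
                hazard_cat = (
                    _duration_hazard_category(profile, scenario.duration)
                    if profile
                    else None
                )
                notes = []
                if profile is None or hazard_cat is None:
                    records.append(
                        DecisionRecord(
                            scenario_id=scenario.scenario_id,
                            refinement_step=i,
                            hazard_tier=step.hazard_tier,
                            exposure_category=exp_result.category,
                            verdict=Verdict.not_evaluated,
                            recommendation=Recommendation.escalate_hazard_tier,
                            systemic_dose=dose,
                            notes=(
                                "data gap: no endpoint data at "
                                f"{step.hazard_tier.value} relevant to "
                                f"{scenario.duration.value}",
                            ),
                        )
                    )
                    continue
                cleared = dossier.limit_dose_clearance.get(scenario.duration, False)
                colour = matrix_lookup(
                    hazard_cat, exp_result.category, matrix, limit_dose_cleared=cleared
                )
                dnel: Optional[DNEL] = profile.dnel
                moe = None
                if colour == Colour.green:
                    verdict = Verdict.acceptable
                    if dnel is not None and dose.hi > 0:
                        moe = dnel.value.lo / dose.hi
                elif colour == Colour.red:
                    verdict = Verdict.unacceptable
                    if dnel is not None and dose.hi > 0:
                        moe = dnel.value.lo / dose.hi
                else:  # amber forces the MoE comparison
                    if dnel is None:
                        verdict = Verdict.insufficient_confidence
                        notes.append("amber cell without a DNEL at this tier")
                    else:
                        result = moe_verdict(
                            dnel.value, dose, confidence.multiplier(step.hazard_tier)
                        )
                        moe, verdict = result.moe, result.verdict
                recommendation = recommend_next(
                    colour, verdict, exposure_refinable, hazard_escalatable
                )
                records.append(
                    DecisionRecord(
                        scenario_id=scenario.scenario_id,
                        refinement_step=i,
                        hazard_tier=step.hazard_tier,
                        hazard_category=hazard_cat,
                        exposure_category=exp_result.category,
                        colour=colour,
                        moe=moe,
                        verdict=verdict,
                        recommendation=recommendation,
                        dnel=dnel.value if dnel else None,
                        systemic_dose=dose,
                        notes=tuple(notes),
                    )
                )
        last = records[-1]
        if last.recommendation == Recommendation.accept:
            terminal = "accept"
        elif last.recommendation == Recommendation.reject:
            terminal = "reject"
        else:
            terminal = "open"
        trajectories.append(
            ScenarioTrajectory(
                scenario_id=scenario.scenario_id,
                duration=scenario.duration,
                tier0=t0,
                records=tuple(records),
                terminal_state=terminal,
                recommended_next=None if terminal != "open" else last.recommendation,
            )
        )
    return AssessmentTrajectory(
        substance_id=dossier.substance_id,
        ttc=ttc,
        hazard_profiles=tuple(profiles[t] for t in tiers_with_data),
        scenarios=tuple(trajectories),
    )
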
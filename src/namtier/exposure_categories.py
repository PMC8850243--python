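"""Duration-specific exposure categories A-E and their derived boundaries.

Exposure doses are banded into five categories per exposure-duration class
(single/1-day, repeat dose up to 3 months, longer term). The boundaries are
not free parameters: they are derived from the CLP potency band limits,
the study limit doses and the substance-specific TTC, all divided by the
same uncertainty factor (default 100) used on the hazard side, so that
exposure and hazard categories cross-reference.

Derivation (reconstructs the published category limits exactly):

1. Category A lower bound = duration-appropriate limit dose / UF
   (1-day uses the top STOT-SE band, 5000 mg/kg; repeat durations use the
   repeat-dose limit dose, 1000 mg/kg).
2. Among the duration-relevant endpoints (1-day: STOT-SE; up to 3 months:
   STOT-RE + reproductive; over 3 months: STOT-RE + carcinogenicity +
   reproductive), take the endpoint with the lowest category-1 limit — the
   hazard with the lowest indicative values drives the duration.
3. B/C boundary = that endpoint's category-2 upper limit / UF;
   C/D boundary = its category-1 upper limit / UF.
4. D/E boundary = the substance TTC.

An element-wise-minimum variant (minimum over all relevant endpoints at
each band, rather than one driving endpoint) is available via
``strategy="elementwise_min"``; it is more conservative for the
up-to-3-month B/C boundary.

Categorisation conventions: an exposure interval is categorised by its
upper end; a dose exactly on a boundary takes the higher-exposure
category; any dose below the TTC is category E.
"""

from __future__ import annotations

from enum import Enum
from typing import Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from .hazard_bands import DEFAULT_BANDS, Endpoint, PotencyBandTable
from .intervals import DoseInterval


class DurationClass(str, Enum):
    one_day = "one_day"            # single or 1-day exposure
    short_term = "short_term"      # repeat dosing up to 3 months
    long_term = "long_term"        # repeat dosing beyond 3 months


class ExposureCategory(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"


EXPOSURE_ORDER: Sequence[ExposureCategory] = tuple(ExposureCategory)


def exposure_rank(category: ExposureCategory) -> int:
    """0 for A (highest exposure) .. 4 for E (lowest)."""
    return EXPOSURE_ORDER.index(category)


class LimitDoses(BaseModel):
    """Study limit doses (mg/kg/day) anchoring the Category A boundary."""

    model_config = ConfigDict(frozen=True)

    single_dose_limit: float = 2000.0
    repeat_dose_limit: float = 1000.0
    stot_se_top_band: float = 5000.0


#: endpoints whose bands are relevant to each exposure duration
DURATION_RELEVANT_ENDPOINTS: Mapping[DurationClass, tuple] = {
    DurationClass.one_day: (Endpoint.stot_se,),
    DurationClass.short_term: (Endpoint.stot_re, Endpoint.reproductive),
    DurationClass.long_term: (
        Endpoint.stot_re,
        Endpoint.carcinogenicity,
        Endpoint.reproductive,
    ),
}


class ExposureBoundarySet(BaseModel):
    """The A/B, B/C, C/D and D/E (= TTC) boundaries for one duration.

    Boundaries are strictly decreasing; ``derivation_trace`` records the
    source limit and factor behind every boundary.
    """

    model_config = ConfigDict(frozen=True)

    duration: DurationClass
    a_lower: float
    bc_boundary: float
    cd_boundary: float
    ttc: float  # mg/kg/day; the D/E boundary and Category E upper bound
    derivation_trace: tuple = ()

    @model_validator(mode="after")
    def _check(self) -> "ExposureBoundarySet":
        chain = (self.a_lower, self.bc_boundary, self.cd_boundary, self.ttc)
        # D/E may coincide with C/D when a high TTC was clamped (D empty)
        if (
            not self.a_lower > self.bc_boundary > self.cd_boundary >= self.ttc
            or self.ttc <= 0
        ):
            raise ValueError(
                f"boundaries must be decreasing and positive: {chain}"
            )
        return self

    @property
    def b_interval(self) -> DoseInterval:
        return DoseInterval(lo=self.bc_boundary, hi=self.a_lower)

    @property
    def c_interval(self) -> DoseInterval:
        return DoseInterval(lo=self.cd_boundary, hi=self.bc_boundary)

    @property
    def d_interval(self) -> DoseInterval:
        return DoseInterval(lo=self.ttc, hi=self.cd_boundary)

    @property
    def e_upper(self) -> float:
        return self.ttc


class ExposureTier(str, Enum):
    tier1_screening = "tier1_screening"
    tier1_refined = "tier1_refined"
    tier2_higher = "tier2_higher"


EXPOSURE_TIER_ORDER: Sequence[ExposureTier] = tuple(ExposureTier)


class Route(str, Enum):
    oral = "oral"
    dermal = "dermal"
    inhalation = "inhalation"


class ExposureEstimate(BaseModel):
    """An externally estimated exposure for one scenario (the estimation
    models themselves — TRA, ART, ConsExpo — are upstream of this tool)."""

    model_config = ConfigDict(frozen=True)

    scenario_id: str = ""
    route: Route = Route.oral
    external_dose: DoseInterval
    units: str = "mg/kg/day"  # or "mg/m3" with conversion inputs
    duration: DurationClass = DurationClass.long_term
    estimation_tier: ExposureTier = ExposureTier.tier1_screening
    population: str = ""
    inhaled_volume_m3_day: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "ExposureEstimate":
        if self.units not in ("mg/kg/day", "mg/m3"):
            raise ValueError(
                "exposure estimates carry mg/kg/day (normalise µg/kg/day on "
                "input) or mg/m3 with conversion inputs"
            )
        return self


class ExposureCategoryResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    scenario_id: str
    category: ExposureCategory
    boundary_set_used: ExposureBoundarySet
    systemic_dose: DoseInterval


def derive_boundaries(
    duration: DurationClass,
    bands: Optional[Mapping[Endpoint, PotencyBandTable]] = None,
    limits: Optional[LimitDoses] = None,
    ttc: float = 0.0025e-3,
    uncertainty_factor: float = 100.0,
    strategy: str = "driving_endpoint",
    clamp_ttc: bool = False,
) -> ExposureBoundarySet:
    """Derive the exposure category boundaries for one duration class.

    ``ttc`` is the substance-specific TTC in mg/kg/day (the default is the
    most conservative value, the genotoxicity-alert TTC). A TTC at or
    above the C/D boundary (possible for Cramer class I against the
    long-term limits) is an error unless ``clamp_ttc`` caps the D/E
    boundary at the C/D boundary, health-protectively emptying category D.
    """
    if uncertainty_factor <= 0:
        raise ValueError("uncertainty factor must be positive")
    bands = bands or DEFAULT_BANDS
    limits = limits or LimitDoses()
    trace = []

    if duration == DurationClass.one_day:
        limit, source = limits.stot_se_top_band, "STOT-SE top band limit"
    else:
        limit, source = limits.repeat_dose_limit, "repeat-dose limit dose"
    a_lower = limit / uncertainty_factor
    trace.append(
        {"boundary": "A_lower", "source": source, "limit": limit,
         "factor": uncertainty_factor, "value": a_lower}
    )

    relevant = DURATION_RELEVANT_ENDPOINTS[duration]
    for endpoint in relevant:
        if endpoint not in bands:
            raise ValueError(f"missing band table for {endpoint.value}")

    def cat1_limit(e: Endpoint) -> float:
        return bands[e].thresholds[0][0]

    def cat2_limit(e: Endpoint) -> float:
        return bands[e].thresholds[1][0]

    if strategy == "driving_endpoint":
        driver = min(relevant, key=cat1_limit)
        bc_src, cd_src = driver, driver
        bc_limit, cd_limit = cat2_limit(driver), cat1_limit(driver)
    elif strategy == "elementwise_min":
        bc_src = min(relevant, key=cat2_limit)
        cd_src = min(relevant, key=cat1_limit)
        bc_limit, cd_limit = cat2_limit(bc_src), cat1_limit(cd_src)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    bc = bc_limit / uncertainty_factor
    cd = cd_limit / uncertainty_factor
    trace.append(
        {"boundary": "B/C", "source": f"{bc_src.value} category-2 limit",
         "limit": bc_limit, "factor": uncertainty_factor, "value": bc}
    )
    trace.append(
        {"boundary": "C/D", "source": f"{cd_src.value} category-1 limit",
         "limit": cd_limit, "factor": uncertainty_factor, "value": cd}
    )
    source = "substance TTC"
    if ttc >= cd:
        if not clamp_ttc:
            raise ValueError(
                f"TTC {ttc} mg/kg/day must lie below the C/D boundary {cd}"
            )
        source = f"substance TTC {ttc:g} clamped to the C/D boundary"
        ttc = cd
    trace.append(
        {"boundary": "D/E", "source": source, "limit": ttc,
         "factor": 1.0, "value": ttc}
    )
    return ExposureBoundarySet(
        duration=duration, a_lower=a_lower, bc_boundary=bc, cd_boundary=cd,
        ttc=ttc, derivation_trace=tuple(trace),
    )


def categorise_dose(
    systemic_dose: DoseInterval,
    boundaries: ExposureBoundarySet,
    scenario_id: str = "",
) -> ExposureCategoryResult:
    """Assign an exposure category from the upper end of the dose interval
    (health-protective); boundary ties take the higher-exposure category."""
    h = systemic_dose.hi
    if h >= boundaries.a_lower:
        category = ExposureCategory.A
    elif h >= boundaries.bc_boundary:
        category = ExposureCategory.B
    elif h >= boundaries.cd_boundary:
        category = ExposureCategory.C
    elif h >= boundaries.ttc:
        category = ExposureCategory.D
    else:
        category = ExposureCategory.E
    return ExposureCategoryResult(
        scenario_id=scenario_id,
        category=category,
        boundary_set_used=boundaries,
        systemic_dose=systemic_dose,
    )


class RouteAbsorption(BaseModel):
    """Route-to-systemic absorption fractions; worst-case 1.0 defaults."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    oral: float = 1.0
    dermal: float = 1.0
    inhalation: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "RouteAbsorption":
        for name in ("oral", "dermal", "inhalation"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} absorption fraction must be in [0, 1]")
        return self

    def fraction(self, route: Route) -> float:
        return getattr(self, route.value)


def to_systemic_dose(
    estimate: ExposureEstimate,
    absorption: Optional[RouteAbsorption] = None,
    body_weight_kg: float = 60.0,
    inhaled_volume_m3_day: Optional[float] = None,
) -> DoseInterval:
    """Oral-equivalent systemic dose = external dose x route absorption.

    An inhalation estimate in mg/m³ is first converted to an external dose
    via inhaled volume / body weight (60 kg default, the TTC basis).
    """
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    absorption = absorption or RouteAbsorption()
    dose = estimate.external_dose
    if estimate.units == "mg/m3":
        if estimate.route != Route.inhalation:
            raise ValueError("mg/m³ exposures are inhalation exposures")
        volume = inhaled_volume_m3_day or estimate.inhaled_volume_m3_day
        if volume is None:
            raise ValueError(
                "inhalation concentration given without an inhaled volume"
            )
        dose = dose.scale(volume / body_weight_kg)
    return dose.scale(absorption.fraction(estimate.route))
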
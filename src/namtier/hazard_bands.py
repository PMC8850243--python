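"""CLP-derived potency banding of hazard endpoints and DNEL derivation.

Six health endpoints are banded into severity/potency categories using the
dose-level limits that the CLP system (and its specific-concentration-limit
potency scheme for carcinogenicity and reproductive toxicity) attaches to
each hazard class. A point of departure (PoD) from any assessment tier —
in silico, in vitro + IVIVE, targeted in vivo, or a conventional study — is
compared against the ordered band limits of its endpoint; the derived
no-effect level (DNEL) is the PoD divided by an uncertainty factor
(default 100 = 10 interspecies x 10 intraspecies).

Conventions (health-protective throughout):

* an interval PoD is classified by its *lower* end;
* a PoD exactly on a shared band boundary takes the more hazardous
  (lower-numbered) category;
* NOAEL/NOEL/LOEL values are accepted as conservative surrogates for the
  canonical band metric of dose endpoints (e.g. a NOEL banded against the
  ED10 limits); cross-endpoint metrics are rejected.
"""

from __future__ import annotations

from enum import Enum
from typing import Mapping, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .intervals import DoseInterval

NOT_CLASSIFIED = "not_classified"

Category = Union[int, str]  # 1..5 or NOT_CLASSIFIED


class Endpoint(str, Enum):
    """Hazard endpoints carrying a potency band table.

    Declaration order is the deterministic tie-break order when two
    endpoints share the same driving PoD.
    """

    acute_oral = "acute_oral"
    stot_se = "stot_se"
    dermal_sens = "dermal_sens"
    stot_re = "stot_re"
    carcinogenicity = "carcinogenicity"
    reproductive = "reproductive"


ENDPOINT_ORDER: Sequence[Endpoint] = tuple(Endpoint)


class PodType(str, Enum):
    NOAEL = "NOAEL"
    NOEL = "NOEL"
    LOEL = "LOEL"
    ATE = "ATE"
    T25 = "T25"
    ED10 = "ED10"
    concentration_percent = "concentration_percent"


class Tier(str, Enum):
    tier1_insilico = "tier1_insilico"
    tier2_invitro = "tier2_invitro"
    tier3_targeted_invivo = "tier3_targeted_invivo"
    conventional = "conventional"


TIER_ORDER: Sequence[Tier] = tuple(Tier)


def tier_rank(tier: Tier) -> int:
    return TIER_ORDER.index(tier)


class PodUnits(str, Enum):
    mg_per_kg_day = "mg/kg/day"
    percent = "%"
    micromolar = "uM"


#: canonical PoD metric per endpoint
CANONICAL_METRIC: Mapping[Endpoint, PodType] = {
    Endpoint.acute_oral: PodType.ATE,
    Endpoint.stot_se: PodType.NOAEL,
    Endpoint.dermal_sens: PodType.concentration_percent,
    Endpoint.stot_re: PodType.NOAEL,
    Endpoint.carcinogenicity: PodType.T25,
    Endpoint.reproductive: PodType.ED10,
}

_NO_EFFECT_SURROGATES = {PodType.NOAEL, PodType.NOEL, PodType.LOEL}

#: metrics accepted for classification per endpoint (canonical + surrogates)
ACCEPTED_METRICS: Mapping[Endpoint, frozenset] = {
    Endpoint.acute_oral: frozenset({PodType.ATE}),
    Endpoint.stot_se: frozenset(_NO_EFFECT_SURROGATES),
    Endpoint.dermal_sens: frozenset({PodType.concentration_percent}),
    Endpoint.stot_re: frozenset(_NO_EFFECT_SURROGATES),
    Endpoint.carcinogenicity: frozenset({PodType.T25} | _NO_EFFECT_SURROGATES),
    Endpoint.reproductive: frozenset({PodType.ED10} | _NO_EFFECT_SURROGATES),
}


class MetricMismatchError(ValueError):
    """PoD metric or endpoint incompatible with the requested band table."""


class PoDRecord(BaseModel):
    """A point of departure for one endpoint at one assessment tier.

    ``no_response`` marks a study that found no relevant effect up to the
    top of its dose range (never encoded as a zero dose). ``units`` other
    than mg/kg/day flag values that cannot enter DNEL arithmetic: percent
    (dermal sensitisation) and µM (in vitro, pre-IVIVE).
    """

    model_config = ConfigDict(frozen=True)

    endpoint: Endpoint
    pod_type: PodType
    value: Optional[DoseInterval] = None
    no_response: bool = False
    units: PodUnits = PodUnits.mg_per_kg_day
    tier: Tier
    study_note: str = ""

    @model_validator(mode="after")
    def _check(self) -> "PoDRecord":
        if self.no_response:
            if self.value is not None:
                raise ValueError("a no-response record carries no dose value")
        else:
            if self.value is None:
                raise ValueError("a PoD needs either a value or the no_response flag")
            if self.value.lo <= 0:
                raise ValueError("PoD values must be positive")
        return self


class PotencyBandTable(BaseModel):
    """Ordered dose thresholds mapping PoD values to hazard categories.

    ``thresholds`` are (upper_limit, category) pairs, strictly increasing
    in both coordinates; ``above_top_category`` applies to values above the
    last limit, ``no_response_category`` to no-response records.
    """

    model_config = ConfigDict(frozen=True)

    endpoint: Endpoint
    thresholds: tuple
    above_top_category: Optional[int] = None
    no_response_category: Optional[Category] = None

    @model_validator(mode="after")
    def _check(self) -> "PotencyBandTable":
        if not self.thresholds:
            raise ValueError("band table needs at least one threshold")
        limits = [t[0] for t in self.thresholds]
        cats = [t[1] for t in self.thresholds]
        if any(b <= a for a, b in zip(limits, limits[1:])):
            raise ValueError("band upper limits must be strictly increasing")
        if any(b <= a for a, b in zip(cats, cats[1:])):
            raise ValueError("band categories must be strictly increasing")
        return self

    def band_for(self, value: float) -> Category:
        """Band containing ``value``; boundary ties go to the more
        hazardous (lower-numbered) category."""
        if value <= 0:
            raise ValueError("cannot band a non-positive PoD")
        for limit, category in self.thresholds:
            if value <= limit:
                return category
        if self.above_top_category is None:
            raise ValueError(
                f"{self.endpoint.value}: value {value} above top band limit"
            )
        return self.above_top_category


def _table(endpoint, thresholds, above_top=None, no_response=None) -> PotencyBandTable:
    return PotencyBandTable(
        endpoint=endpoint,
        thresholds=tuple(thresholds),
        above_top_category=above_top,
        no_response_category=no_response,
    )


#: Built-in CLP-derived band constants (dose limits in mg/kg/day from
#: laboratory animal studies; dermal sensitisation in concentration %).
#: STOT-SE/STOT-RE categories 3 and 4 extrapolate the CLP category-1/2
#: ranges; carcinogenicity and reproductive toxicity use the SCL potency
#: limits (T25 and ED10 respectively).
DEFAULT_BANDS: Mapping[Endpoint, PotencyBandTable] = {
    Endpoint.acute_oral: _table(
        Endpoint.acute_oral, [(5, 1), (50, 2), (300, 3), (2000, 4)], above_top=5
    ),
    Endpoint.stot_se: _table(
        Endpoint.stot_se, [(300, 1), (2000, 2), (5000, 3)], above_top=4
    ),
    Endpoint.dermal_sens: _table(
        Endpoint.dermal_sens, [(0.1, 1), (10, 2), (100, 3)], no_response=4
    ),
    Endpoint.stot_re: _table(
        Endpoint.stot_re, [(10, 1), (100, 2), (1000, 3)], above_top=4
    ),
    Endpoint.carcinogenicity: _table(
        Endpoint.carcinogenicity, [(1, 1), (100, 2)], above_top=3,
        no_response=NOT_CLASSIFIED,
    ),
    Endpoint.reproductive: _table(
        Endpoint.reproductive, [(4, 1), (400, 2)], above_top=3,
        no_response=NOT_CLASSIFIED,
    ),
}

BAND_TABLE_VERSION = "clp-2008-scl"


def bands_from_config(config: Mapping) -> Mapping[Endpoint, PotencyBandTable]:
    """Merge a ``bands:`` config section over the built-in constants.

    Each entry: ``{endpoint: {thresholds: [[limit, cat], ...],
    above_top: int|null, no_response: cat|null}}``.
    """
    merged = dict(DEFAULT_BANDS)
    for key, payload in (config or {}).items():
        endpoint = Endpoint(key)
        merged[endpoint] = _table(
            endpoint,
            [tuple(t) for t in payload["thresholds"]],
            above_top=payload.get("above_top"),
            no_response=payload.get("no_response"),
        )
    return merged


class HazardEndpointResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    endpoint: Endpoint
    category: Optional[Category]
    driving_pod: Optional[PoDRecord] = None
    override_applied: bool = False
    basis: str = "banding"  # banding | potency_band | override | data_gap
    note: str = ""


def severity_rank(category: Optional[Category]) -> int:
    """Lower rank = more severe; NOT_CLASSIFIED/None rank least severe."""
    if isinstance(category, int):
        return category
    return 99


class DNEL(BaseModel):
    """Derived no-effect level: PoD interval / uncertainty factor."""

    model_config = ConfigDict(frozen=True)

    value: DoseInterval
    uncertainty_factor: float = 100.0
    source_pod: Optional[PoDRecord] = None
    tier: Tier
    note: str = ""

    @model_validator(mode="after")
    def _check(self) -> "DNEL":
        if self.uncertainty_factor <= 0:
            raise ValueError("uncertainty factor must be positive")
        if self.source_pod is not None and self.source_pod.value is not None:
            expect = self.source_pod.value / self.uncertainty_factor
            for got, want in ((self.value.lo, expect.lo), (self.value.hi, expect.hi)):
                if abs(got - want) > 1e-12 * max(1.0, abs(want)):
                    raise ValueError("DNEL must equal source PoD / uncertainty factor")
        return self


class HazardProfile(BaseModel):
    """Endpoint categories and DNEL for one substance at one tier."""

    model_config = ConfigDict(frozen=True)

    substance_id: str
    tier: Tier
    endpoint_results: tuple[HazardEndpointResult, ...] = ()
    dnel: Optional[DNEL] = None

    @model_validator(mode="after")
    def _check(self) -> "HazardProfile":
        seen = [r.endpoint for r in self.endpoint_results]
        if len(seen) != len(set(seen)):
            raise ValueError("at most one result per endpoint per tier")
        return self

    def result_for(self, endpoint: Endpoint) -> Optional[HazardEndpointResult]:
        for r in self.endpoint_results:
            if r.endpoint == endpoint:
                return r
        return None


def _base_record(pod: PoDRecord) -> PoDRecord:
    """Strip any dossier-layer extras so results carry the core PoD fields
    (keeps results serialisable and comparable across layers)."""
    if type(pod) is PoDRecord:
        return pod
    return PoDRecord(
        **{name: getattr(pod, name) for name in PoDRecord.model_fields}
    )


def classify_endpoint(
    band_table: PotencyBandTable, pod: PoDRecord
) -> HazardEndpointResult:
    """Band a PoD into its endpoint's hazard category.

    The health-protective lower end of an interval PoD is banded; a
    boundary tie takes the more hazardous category; a no-response record
    returns the table's no-response category.
    """
    if pod.endpoint != band_table.endpoint:
        raise MetricMismatchError(
            f"PoD for {pod.endpoint.value} classified against the "
            f"{band_table.endpoint.value} band table"
        )
    if pod.pod_type not in ACCEPTED_METRICS[pod.endpoint]:
        raise MetricMismatchError(
            f"{pod.pod_type.value} is not an accepted metric for "
            f"{pod.endpoint.value} (canonical: "
            f"{CANONICAL_METRIC[pod.endpoint].value})"
        )
    expected_units = (
        PodUnits.percent if pod.endpoint == Endpoint.dermal_sens
        else PodUnits.mg_per_kg_day
    )
    if not pod.no_response and pod.units != expected_units:
        raise MetricMismatchError(
            f"{pod.endpoint.value} PoD must be in {expected_units.value}; "
            f"got {pod.units.value}"
            + (" (apply IVIVE first)" if pod.units == PodUnits.micromolar else "")
        )
    if pod.no_response:
        if band_table.no_response_category is None:
            raise ValueError(
                f"{pod.endpoint.value} has no defined no-response category"
            )
        return HazardEndpointResult(
            endpoint=pod.endpoint,
            category=band_table.no_response_category,
            driving_pod=_base_record(pod),
            basis="banding",
        )
    category = band_table.band_for(pod.value.lo)
    return HazardEndpointResult(
        endpoint=pod.endpoint,
        category=category,
        driving_pod=_base_record(pod),
        basis="banding",
    )


class PotencyBand(str, Enum):
    high = "high"
    medium = "medium"
    low = "low"


def potency_to_category(potency_band: Union[PotencyBand, str]) -> int:
    """SCL potency band -> hazard category (high 1, medium 2, low 3)."""
    mapping = {PotencyBand.high: 1, PotencyBand.medium: 2, PotencyBand.low: 3}
    try:
        return mapping[PotencyBand(potency_band)]
    except ValueError:
        raise ValueError(f"unknown potency band {potency_band!r}") from None


def derive_dnel(pod: PoDRecord, uncertainty_factor: float = 100.0) -> DNEL:
    """DNEL = PoD interval / uncertainty factor, units preserved in
    mg/kg/day. No display rounding is applied here."""
    if uncertainty_factor <= 0:
        raise ValueError("uncertainty factor must be positive")
    if pod.no_response:
        raise ValueError("no DNEL derivable from a no-response PoD")
    if pod.units == PodUnits.micromolar:
        raise ValueError("µM PoD must be IVIVE-converted before DNEL derivation")
    if pod.units == PodUnits.percent:
        raise ValueError("a concentration-percent PoD has no dose-based DNEL")
    return DNEL(
        value=pod.value / uncertainty_factor,
        uncertainty_factor=uncertainty_factor,
        source_pod=_base_record(pod),
        tier=pod.tier,
    )


def _is_systemic(record: PoDRecord) -> bool:
    return (
        record.endpoint != Endpoint.dermal_sens
        and record.units == PodUnits.mg_per_kg_day
        and not record.no_response
    )


def select_driving_pod(records: Sequence[PoDRecord], tier: Tier) -> PoDRecord:
    """The systemic PoD with the smallest lower bound at ``tier``; ties
    break deterministically by endpoint declaration order."""
    candidates = [r for r in records if r.tier == tier and _is_systemic(r)]
    if not candidates:
        raise ValueError(f"no systemic PoD records at tier {tier.value}")
    return min(
        candidates,
        key=lambda r: (r.value.lo, ENDPOINT_ORDER.index(r.endpoint)),
    )


class CategoryOverride(BaseModel):
    """Expert-assigned endpoint category with mandatory provenance note."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    endpoint: Endpoint
    tier: Tier
    category: Optional[Category]
    note: str = Field(min_length=1)


class PotencyAssignment(BaseModel):
    """High/medium/low potency judgement for an endpoint at a tier (used
    where the evidence is a potency narrative rather than a numeric PoD)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    endpoint: Endpoint
    tier: Tier
    band: PotencyBand
    note: str = ""


class DnelOverride(BaseModel):
    """Expert-assigned DNEL replacing derivation, with provenance."""

    model_config = ConfigDict(frozen=True)

    tier: Tier
    value: DoseInterval
    note: str = Field(min_length=1)


def build_hazard_profile(
    substance_id: str,
    tier: Tier,
    pod_records: Sequence[PoDRecord],
    potency_assignments: Sequence[PotencyAssignment] = (),
    overrides: Sequence[CategoryOverride] = (),
    dnel_overrides: Sequence[DnelOverride] = (),
    bands: Optional[Mapping[Endpoint, PotencyBandTable]] = None,
    uncertainty_factor: float = 100.0,
) -> HazardProfile:
    """Classify every endpoint with data at ``tier`` and derive the DNEL.

    Several records on the same endpoint are reduced health-protectively to
    the one with the lowest lower bound. Expert overrides replace the
    banded category (disclosed via ``override_applied``); a DNEL override
    replaces the driving-PoD derivation.
    """
    bands = dict(bands) if bands else dict(DEFAULT_BANDS)
    results: dict = {}
    at_tier = [r for r in pod_records if r.tier == tier]
    for endpoint in Endpoint:
        here = [r for r in at_tier if r.endpoint == endpoint]
        if not here:
            continue
        with_value = [r for r in here if not r.no_response]
        pod = (
            min(with_value, key=lambda r: r.value.lo) if with_value else here[0]
        )
        results[endpoint] = classify_endpoint(bands[endpoint], pod)
    for assignment in potency_assignments:
        if assignment.tier != tier:
            continue
        results[assignment.endpoint] = HazardEndpointResult(
            endpoint=assignment.endpoint,
            category=potency_to_category(assignment.band),
            basis="potency_band",
            note=assignment.note,
        )
    for override in overrides:
        if override.tier != tier:
            continue
        prior = results.get(override.endpoint)
        results[override.endpoint] = HazardEndpointResult(
            endpoint=override.endpoint,
            category=override.category,
            driving_pod=prior.driving_pod if prior else None,
            override_applied=True,
            basis="override",
            note=override.note,
        )

    dnel: Optional[DNEL] = None
    for d_override in dnel_overrides:
        if d_override.tier == tier:
            dnel = DNEL(
                value=d_override.value,
                uncertainty_factor=uncertainty_factor,
                tier=tier,
                note=d_override.note,
            )
            break
    if dnel is None:
        try:
            driving = select_driving_pod(at_tier, tier)
        except ValueError:
            driving = None
        if driving is not None:
            dnel = derive_dnel(driving, uncertainty_factor)

    ordered = tuple(results[e] for e in Endpoint if e in results)
    return HazardProfile(
        substance_id=substance_id, tier=tier, endpoint_results=ordered, dnel=dnel
    )
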
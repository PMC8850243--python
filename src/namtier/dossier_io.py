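"""Dossier / scenario / config I/O, worked-example fixtures, synthetic
dossier generation and report rendering.

A substance dossier aggregates everything the decision engine consumes:
identity, TTC structural flags, per-tier PoD records (with optional IVIVE
conversion specs for in vitro concentrations), expert category/DNEL
overrides (each with a mandatory provenance note) and limit-dose clearance
flags. Scenario files carry stepped exposure estimates per use. Both are
YAML (canonical) or JSON, schema-versioned, with unknown fields rejected.

Units accepted on input: mg/kg/day, µg/kg/day (normalised to mg/kg/day),
µM (pre-IVIVE concentrations, converted on read via the attached spec),
% (dermal sensitisation) and mg/m³ (inhalation, with conversion inputs).
"""

from __future__ import annotations

import json
import math
import random
from pathlib import Path
from typing import Any, Mapping, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .decision_engine import AssessmentTrajectory
from .exposure_categories import (
    DurationClass,
    ExposureEstimate,
    ExposureTier,
    Route,
    RouteAbsorption,
    derive_boundaries,
)
from .hazard_bands import (
    CANONICAL_METRIC,
    CategoryOverride,
    DnelOverride,
    Endpoint,
    PoDRecord,
    PodUnits,
    PotencyAssignment,
    Tier,
)
from .intervals import DoseInterval, format_interval, format_sig
from .ivive import ConversionSpec, oral_equivalent_dose
from .ttc_screen import CramerClass, TTCFlags

SCHEMA_VERSION = 1

_UNIT_ALIASES = {
    "mg/kg/day": ("mg/kg/day", 1.0),
    "ug/kg/day": ("mg/kg/day", 1e-3),
    "um": ("uM", 1.0),
    "%": ("%", 1.0),
    "percent": ("%", 1.0),
    "mg/m3": ("mg/m3", 1.0),
}


def parse_dose_units(units: str, allowed: frozenset) -> Tuple[str, float]:
    """Canonical unit and scale-to-canonical factor; rejects anything
    outside the schema's unit vocabulary."""
    units = getattr(units, "value", units)  # accept unit enums
    key = str(units).replace("µ", "u").replace("³", "3").strip()
    if key != "%":
        key = key.lower()
    if key not in _UNIT_ALIASES:
        raise ValueError(
            f"unsupported units {units!r}; allowed: mg/kg/day, µg/kg/day, µM, %, mg/m3"
        )
    canon, scale = _UNIT_ALIASES[key]
    if canon not in allowed:
        raise ValueError(f"units {units!r} not allowed here (allowed: {sorted(allowed)})")
    return canon, scale


class DossierPoD(PoDRecord):
    """A dossier PoD entry: a :class:`PoDRecord` plus unit normalisation
    and the optional IVIVE hand-off for µM in vitro concentrations (the
    original concentration is preserved in ``source_concentration``)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    source_concentration: Optional[DoseInterval] = None  # µM, pre-IVIVE
    ivive: Optional[ConversionSpec] = None

    @model_validator(mode="before")
    @classmethod
    def _normalise(cls, data: Any) -> Any:
        if not isinstance(data, Mapping):
            return data
        data = dict(data)
        canon, scale = parse_dose_units(
            data.get("units", "mg/kg/day"), frozenset({"mg/kg/day", "uM", "%"})
        )
        value = data.get("value")
        if value is not None:
            interval = DoseInterval.model_validate(value)
            if scale != 1.0:
                interval = interval.scale(scale)
            if canon == "uM":
                spec = data.get("ivive")
                if spec is None:
                    raise ValueError(
                        "a µM PoD requires an ivive conversion spec to reach mg/kg/day"
                    )
                spec = ConversionSpec.model_validate(spec)
                data["ivive"] = spec
                data["source_concentration"] = interval
                interval = oral_equivalent_dose(interval, spec)
                canon = "mg/kg/day"
            data["value"] = interval
        data["units"] = canon
        return data


class DossierDnelOverride(DnelOverride):
    model_config = ConfigDict(frozen=True, extra="forbid")

    @model_validator(mode="before")
    @classmethod
    def _normalise(cls, data: Any) -> Any:
        if not isinstance(data, Mapping):
            return data
        data = dict(data)
        canon, scale = parse_dose_units(
            data.pop("units", "mg/kg/day"), frozenset({"mg/kg/day"})
        )
        if "value" in data:
            interval = DoseInterval.model_validate(data["value"])
            data["value"] = interval.scale(scale) if scale != 1.0 else interval
        return data


class SubstanceDossier(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid", populate_by_name=True)

    schema_version: int = SCHEMA_VERSION
    substance_id: str
    name: str = ""
    #: opaque identifiers (CAS, SMILES, ...) — stored, never parsed
    identifiers: Mapping[str, str] = {}
    ttc_flags: TTCFlags = Field(alias="ttc")
    pod_records: Tuple[DossierPoD, ...] = ()
    potency_assignments: Tuple[PotencyAssignment, ...] = ()
    overrides: Tuple[CategoryOverride, ...] = ()
    dnel_overrides: Tuple[DossierDnelOverride, ...] = ()
    #: per-duration flag: a tier-3+ limit-dose study found no relevant toxicity
    limit_dose_clearance: Mapping[DurationClass, bool] = {}
    absorption: Optional[RouteAbsorption] = None

    @model_validator(mode="after")
    def _check(self) -> "SubstanceDossier":
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {self.schema_version}")
        return self


class ScenarioExposure(ExposureEstimate):
    model_config = ConfigDict(frozen=True, extra="forbid")

    @model_validator(mode="before")
    @classmethod
    def _normalise(cls, data: Any) -> Any:
        if not isinstance(data, Mapping):
            return data
        data = dict(data)
        if "dose" in data:
            data["external_dose"] = data.pop("dose")
        canon, scale = parse_dose_units(
            data.get("units", "mg/kg/day"), frozenset({"mg/kg/day", "mg/m3"})
        )
        if "external_dose" in data:
            interval = DoseInterval.model_validate(data["external_dose"])
            data["external_dose"] = (
                interval.scale(scale) if scale != 1.0 else interval
            )
        data["units"] = canon
        return data


class AssessmentStep(BaseModel):
    """One refinement step: an exposure estimate paired with the hazard
    tier whose profile it is judged against."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    exposure: ScenarioExposure
    hazard_tier: Tier


class Scenario(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    scenario_id: str
    duration: DurationClass
    population: str = ""
    steps: Tuple[AssessmentStep, ...] = Field(min_length=1)

    @model_validator(mode="after")
    def _propagate(self) -> "Scenario":
        steps = tuple(
            step.model_copy(
                update={
                    "exposure": step.exposure.model_copy(
                        update={
                            "scenario_id": self.scenario_id,
                            "duration": self.duration,
                        }
                    )
                }
            )
            for step in self.steps
        )
        object.__setattr__(self, "steps", steps)
        return self


class ScenarioSet(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    schema_version: int = SCHEMA_VERSION
    substance_id: str = ""
    scenarios: Tuple[Scenario, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "ScenarioSet":
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {self.schema_version}")
        return self


def _load_raw(path) -> Any:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _dump_raw(payload: Any, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))


def read_dossier(path) -> SubstanceDossier:
    """Read and validate a dossier from YAML or JSON (by extension)."""
    return SubstanceDossier.model_validate(_load_raw(path))


def write_dossier(dossier: SubstanceDossier, path) -> None:
    """Write a dossier in canonical form (units normalised to mg/kg/day);
    write then read is the identity on the canonical form."""
    _dump_raw(dossier.model_dump(mode="json", by_alias=True), path)


def read_scenarios(path) -> ScenarioSet:
    return ScenarioSet.model_validate(_load_raw(path))


def write_scenarios(scenarios: ScenarioSet, path) -> None:
    _dump_raw(scenarios.model_dump(mode="json"), path)


# ---------------------------------------------------------------------------
# Worked-example fixtures


class Fixture(BaseModel):
    """A worked case study: dossier + stepped scenarios + the printed
    expected outcomes used as the replay oracle."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str
    display_sigfigs: int = 2
    dossier: SubstanceDossier
    scenarios: Optional[ScenarioSet] = None
    expected: Mapping[str, Any] = {}


FIXTURE_NAMES = ("EC1", "EC2", "EC3")


def load_fixture(name: str) -> Fixture:
    """Load one of the packaged case-study fixtures (EC1, EC2, EC3)."""
    key = name.upper()
    if key not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    from importlib.resources import files

    text = (files("namtier") / "data" / f"{key.lower()}.yaml").read_text()
    return Fixture.model_validate(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Synthetic dossier generation (property-test input source)


class GeneratorConfig(BaseModel):
    """Ranges for the synthetic dossier generator. PoDs and exposures are
    drawn log-uniformly so every potency band and exposure category is
    reachable; defaults span all built-in band limits."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    pod_range: Tuple[float, float] = (1e-3, 1e4)       # mg/kg/day
    dermal_range: Tuple[float, float] = (0.01, 100.0)  # concentration %
    exposure_range: Tuple[float, float] = (1e-6, 1e3)  # mg/kg/day
    n_scenarios: int = 3
    p_endpoint: float = 0.7
    p_genotox: float = 0.15
    p_op: float = 0.15
    p_no_response: float = 0.1

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        for lo, hi in (self.pod_range, self.dermal_range, self.exposure_range):
            if not (0 < lo < hi):
                raise ValueError("generator ranges must be positive and non-degenerate")
        if self.n_scenarios < 1:
            raise ValueError("need at least one scenario")
        return self


_NO_RESPONSE_OK = {Endpoint.dermal_sens, Endpoint.carcinogenicity, Endpoint.reproductive}


def generate_random_dossier(
    seed: int, config: Optional[GeneratorConfig] = None
) -> Tuple[SubstanceDossier, ScenarioSet]:
    """Deterministic synthetic dossier + scenarios for a seed."""
    config = config or GeneratorConfig()
    rng = random.Random(seed)

    def logu(lo: float, hi: float) -> float:
        return math.exp(rng.uniform(math.log(lo), math.log(hi)))

    tiers = [Tier.tier2_invitro]
    if rng.random() < 0.5:
        tiers.append(Tier.tier3_targeted_invivo)
    if rng.random() < 0.5:
        tiers.append(Tier.conventional)

    pods = []
    for tier in tiers:
        for endpoint in Endpoint:
            if rng.random() > config.p_endpoint:
                continue
            if endpoint in _NO_RESPONSE_OK and rng.random() < config.p_no_response:
                pods.append(
                    DossierPoD(
                        endpoint=endpoint,
                        pod_type=CANONICAL_METRIC[endpoint],
                        no_response=True,
                        units=(
                            PodUnits.percent
                            if endpoint == Endpoint.dermal_sens
                            else PodUnits.mg_per_kg_day
                        ),
                        tier=tier,
                    )
                )
                continue
            if endpoint == Endpoint.dermal_sens:
                value, units = logu(*config.dermal_range), "%"
            else:
                value, units = logu(*config.pod_range), "mg/kg/day"
            pods.append(
                DossierPoD(
                    endpoint=endpoint,
                    pod_type=CANONICAL_METRIC[endpoint],
                    value=DoseInterval.point(value),
                    units=units,
                    tier=tier,
                )
            )

    flags = TTCFlags(
        genotoxic_alert=rng.random() < config.p_genotox,
        op_or_carbamate=rng.random() < config.p_op,
        cramer_class=rng.choice([CramerClass.I, CramerClass.II, CramerClass.III]),
        in_ttc_domain=True,
    )
    dossier = SubstanceDossier(
        substance_id=f"SYN-{seed}",
        name=f"synthetic substance (seed {seed})",
        ttc_flags=flags,
        pod_records=tuple(pods),
    )

    scenarios = []
    for k in range(config.n_scenarios):
        duration = rng.choice(list(DurationClass))
        dose = logu(*config.exposure_range)
        steps = [
            AssessmentStep(
                exposure=ScenarioExposure(
                    external_dose=DoseInterval.point(dose),
                    route=Route.oral,
                    duration=duration,
                    estimation_tier=ExposureTier.tier1_screening,
                ),
                hazard_tier=tiers[0],
            )
        ]
        if rng.random() < 0.6:
            steps.append(
                AssessmentStep(
                    exposure=ScenarioExposure(
                        external_dose=DoseInterval.point(
                            dose * rng.uniform(0.05, 0.8)
                        ),
                        route=Route.oral,
                        duration=duration,
                        estimation_tier=ExposureTier.tier2_higher,
                    ),
                    hazard_tier=tiers[-1],
                )
            )
        scenarios.append(
            Scenario(
                scenario_id=f"use-{k + 1}", duration=duration, steps=tuple(steps)
            )
        )
    scenario_set = ScenarioSet(
        substance_id=dossier.substance_id, scenarios=tuple(scenarios)
    )
    return dossier, scenario_set


# ---------------------------------------------------------------------------
# Report rendering


def _format_category(category) -> str:
    if category is None:
        return "—"
    return str(category)


def render_report(
    trajectory: AssessmentTrajectory,
    format: str = "markdown",
    sigfigs: int = 2,
) -> str:
    """Render an assessment trajectory.

    ``markdown`` gives the human report: per-tier endpoint categories and
    DNELs (2 significant figures by default), per-scenario matrix
    positions per refinement step, boundary derivation traces and override
    disclosures. ``json`` is the exact-value twin that re-parses to the
    in-memory trajectory.
    """
    if not trajectory.scenarios:
        raise ValueError("cannot render an empty trajectory")
    if format == "json":
        return json.dumps(trajectory.model_dump(mode="json"), indent=2)
    if format != "markdown":
        raise ValueError(f"unknown report format {format!r}")

    lines = [f"# Safety assessment: {trajectory.substance_id}", ""]
    lines.append(
        f"TTC basis: {trajectory.ttc.basis.value} — "
        f"{format_sig(trajectory.ttc.ttc_value, sigfigs)} µg/kg/day"
    )
    lines.append("")

    if trajectory.hazard_profiles:
        tiers = [p.tier for p in trajectory.hazard_profiles]
        lines.append("## Hazard categories and DNELs per tier")
        lines.append("")
        header = "| | " + " | ".join(t.value for t in tiers) + " |"
        lines.append(header)
        lines.append("|---" * (len(tiers) + 1) + "|")
        endpoints = sorted(
            {r.endpoint for p in trajectory.hazard_profiles for r in p.endpoint_results},
            key=list(Endpoint).index,
        )
        for endpoint in endpoints:
            row = [endpoint.value]
            for profile in trajectory.hazard_profiles:
                result = profile.result_for(endpoint)
                if result is None:
                    row.append("—")
                else:
                    text = _format_category(result.category)
                    if result.override_applied:
                        text += "*"
                    row.append(text)
            lines.append("| " + " | ".join(row) + " |")
        row = ["DNEL (mg/kg/day)"]
        for profile in trajectory.hazard_profiles:
            if profile.dnel is None:
                row.append("—")
            else:
                text = format_interval(profile.dnel.value, sigfigs)
                if profile.dnel.note:
                    text += "*"
                row.append(text)
        lines.append("| " + " | ".join(row) + " |")
        lines.append("")

    for scenario in trajectory.scenarios:
        lines.append(f"## Scenario: {scenario.scenario_id} ({scenario.duration.value})")
        lines.append("")
        t0 = scenario.tier0
        margin = "∞" if math.isinf(t0.margin) else format_sig(t0.margin, sigfigs)
        lines.append(
            f"Tier 0 TTC screen: {'pass' if t0.passes else 'fail'} (margin {margin})"
        )
        lines.append("")
        lines.append(
            "| step | hazard tier | hazard cat | exposure cat | colour | MoE |"
            " verdict | recommendation |"
        )
        lines.append("|---|---|---|---|---|---|---|---|")
        for record in scenario.records:
            moe = (
                "—"
                if record.moe is None
                else ("∞" if math.isinf(record.moe) else format_sig(record.moe, sigfigs))
            )
            lines.append(
                "| {step} | {tier} | {hc} | {ec} | {colour} | {moe} | {verdict} |"
                " {rec} |".format(
                    step=record.refinement_step,
                    tier=record.hazard_tier.value if record.hazard_tier else "—",
                    hc=_format_category(record.hazard_category),
                    ec=record.exposure_category.value if record.exposure_category else "—",
                    colour=record.colour.value if record.colour else "—",
                    moe=moe,
                    verdict=record.verdict.value,
                    rec=record.recommendation.value,
                )
            )
        lines.append("")
        lines.append(f"Terminal state: **{scenario.terminal_state}**")
        if scenario.recommended_next:
            lines.append(f"Recommended next step: {scenario.recommended_next.value}")
        lines.append("")

    durations = sorted(
        {s.duration for s in trajectory.scenarios}, key=list(DurationClass).index
    )
    if durations:
        lines.append("## Exposure boundary derivation")
        lines.append("")
        for duration in durations:
            bounds = derive_boundaries(
                duration, ttc=trajectory.ttc.mg_per_kg_day
            )
            lines.append(f"### {duration.value}")
            lines.append("")
            for entry in bounds.derivation_trace:
                lines.append(
                    f"- {entry['boundary']}: {format_sig(entry['value'], sigfigs)}"
                    f" mg/kg/day = {entry['source']} {entry['limit']:g}"
                    f" / {entry['factor']:g}"
                )
            lines.append("")

    disclosures = [
        (profile.tier, result)
        for profile in trajectory.hazard_profiles
        for result in profile.endpoint_results
        if result.override_applied
    ] + [
        (profile.tier, profile.dnel)
        for profile in trajectory.hazard_profiles
        if profile.dnel is not None and profile.dnel.note
    ]
    if disclosures:
        lines.append("## Expert overrides applied")
        lines.append("")
        for tier, item in disclosures:
            if hasattr(item, "endpoint"):
                lines.append(
                    f"- {tier.value} / {item.endpoint.value} -> "
                    f"{_format_category(item.category)}: {item.note}"
                )
            else:
                lines.append(
                    f"- {tier.value} DNEL {format_interval(item.value, sigfigs)}"
                    f" mg/kg/day: {item.note}"
                )
        lines.append("")
    return "\n".join(lines)
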